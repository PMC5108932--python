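"""Monodomain fiber: a chain of cells coupled by linear gap junctions.

Each cell i obeys

    C_m dV_i/dt = I_gj[i-1] - I_gj[i] - I_ion,i - I_stim,i
    I_gj[i] = G_gj (V_i - V_{i+1})

with sealed (no-flux/Neumann) ends: no axial current flows past the first
or last cell.  All non-voltage states evolve cell-locally.  The fiber
state is the cell-major flattening of the per-cell state vectors (all 22
states of cell 1, then cell 2, ...), so a 100-cell chain is a system of
2200 simultaneous ODEs and the Jacobian is block-tridiagonal with
bandwidth 22 on either side of the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from . import _kernel
from .cell_model import CellParameters, CellState, resting_state
from .constants import N_STATES

__all__ = ["FiberConfig", "gap_currents", "fiber_derivatives",
           "jac_sparsity", "resting_fiber_state", "System"]

#: cell length in um; with the 74 um reference geometry, 50 cells span
#: 0.37 cm — the distance used for conduction-velocity measurements
DEFAULT_CELL_LENGTH_UM = 74.0


@dataclass(frozen=True)
class FiberConfig:
    """Uniform fiber of ``n_cells`` identical cells (no spatial parameter
    variation) coupled with interface conductance ``G_gj``."""

    n_cells: int = 100
    G_gj: float = 10.0                     # uS per cell-cell interface
    L_c: float = DEFAULT_CELL_LENGTH_UM    # um
    cell_params: CellParameters = field(default_factory=CellParameters)

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValueError("a fiber needs at least 2 cells")
        if self.G_gj < 0:
            raise ValueError("G_gj must be non-negative")
        if self.L_c <= 0:
            raise ValueError("cell length must be positive")

    @property
    def n_states(self) -> int:
        return self.n_cells * N_STATES

    def replace(self, **kw) -> "FiberConfig":
        d = dict(n_cells=self.n_cells, G_gj=self.G_gj, L_c=self.L_c,
                 cell_params=self.cell_params)
        d.update(kw)
        return FiberConfig(**d)


def gap_currents(V: np.ndarray, G_gj: float) -> np.ndarray:
    """Interface currents I_gj[i] = G_gj (V_i - V_{i+1}) in nA.

    Returns the n_cells - 1 currents flowing from each cell into its
    right-hand neighbour; sealed ends carry no flux past cells 1 and n.
    The currents into cell i are I_gj[i-1] - I_gj[i], so the net coupling
    current summed over all cells is identically zero.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 1 or V.size < 2:
        raise ValueError("need the voltages of at least 2 cells")
    if not np.all(np.isfinite(V)):
        raise ValueError("V must be finite")
    return G_gj * (V[:-1] - V[1:])


class System:
    """Internal adapter: one RHS surface for a cell, a fiber, or a
    passive fixture, consumable by the simulation engine.

    ``kind`` is "ionic" or "passive"; ``n_cells`` may be 1 (isolated
    cell).  The flattened layout is always cell-major with 22 slots per
    cell, also for the passive membrane (21 frozen states), so every code
    path of the engine is exercised identically.
    """

    def __init__(self, *, n_cells: int, G_gj: float, params=None,
                 passive=None, L_c: float = DEFAULT_CELL_LENGTH_UM):
        self.n_cells = int(n_cells)
        self.G_gj = float(G_gj)
        self.L_c = float(L_c)
        self.kind = "passive" if passive is not None else "ionic"
        self.params = params
        self.passive = passive
        if self.kind == "ionic":
            self._P = params.to_vector()
        self._scratch = np.empty(_kernel.N_CURRENTS)
        self._dy = np.empty(self.n_cells * N_STATES)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_cell(cls, params: CellParameters) -> "System":
        return cls(n_cells=1, G_gj=0.0, params=params)

    @classmethod
    def from_fiber(cls, config: FiberConfig) -> "System":
        return cls(n_cells=config.n_cells, G_gj=config.G_gj,
                   params=config.cell_params, L_c=config.L_c)

    # -- dynamics ---------------------------------------------------------
    def rhs(self, y: np.ndarray, stim: np.ndarray) -> np.ndarray:
        if self.kind == "ionic":
            _kernel.fiber_rhs_flat(y, self._P, self.G_gj, stim,
                                   self._dy, self._scratch)
        else:
            p = self.passive
            _kernel.passive_rhs_flat(y, p.g_m, p.E_rest, p.C_m,
                                     self.G_gj, stim, self._dy)
        return self._dy

    def resting_vector(self) -> np.ndarray:
        if self.kind == "ionic":
            rest = resting_state(self.params)
            return np.tile(rest.vector, self.n_cells)
        y = np.zeros(self.n_cells * N_STATES)
        y[::N_STATES] = self.passive.E_rest
        return y

    @property
    def band(self) -> tuple[int, int] | None:
        """(ml, mu) of the banded Jacobian, or None for a single cell."""
        if self.n_cells == 1:
            return None
        return (N_STATES, N_STATES)


def as_system(obj) -> System:
    if isinstance(obj, System):
        return obj
    if isinstance(obj, CellParameters):
        return System.from_cell(obj)
    if isinstance(obj, FiberConfig):
        return System.from_fiber(obj)
    raise TypeError(f"cannot build a simulation system from {type(obj)!r}")


def fiber_derivatives(state, t: float, config: FiberConfig,
                      stim: np.ndarray | None = None) -> np.ndarray:
    """Full flattened RHS of the fiber (length n_cells x 22).

    ``stim`` is the per-cell external stimulus current in nA (inward
    negative), zero where absent.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (config.n_states,):
        raise ValueError(
            f"fiber state must have length {config.n_states}, got {y.shape}")
    if stim is None:
        stim = np.zeros(config.n_cells)
    stim = np.asarray(stim, dtype=float)
    if stim.shape != (config.n_cells,):
        raise ValueError("stim vector length must equal n_cells")
    return as_system(config).rhs(y, stim).copy()


def jac_sparsity(n_cells: int) -> sparse.csr_matrix:
    """Block-tridiagonal sparsity pattern of the fiber Jacobian.

    Dense 22 x 22 diagonal blocks (intra-cell coupling) plus the
    voltage-voltage entries of neighbouring cells.
    """
    n = n_cells * N_STATES
    block = np.ones((N_STATES, N_STATES), dtype=np.int8)
    diag = sparse.block_diag([block] * n_cells, format="lil")
    for i in range(n_cells - 1):
        diag[i * N_STATES, (i + 1) * N_STATES] = 1
        diag[(i + 1) * N_STATES, i * N_STATES] = 1
    return sparse.csr_matrix(diag[:n, :n])


def resting_fiber_state(config: FiberConfig) -> np.ndarray:
    """Uniform resting fiber: the single-cell rest broadcast to all cells
    (a fixed point of the coupled system, since uniform V carries no
    gap-junction current)."""
    rest = resting_state(config.cell_params)
    return np.tile(rest.vector, config.n_cells)
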