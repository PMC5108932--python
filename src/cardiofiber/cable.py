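"""Passive-cable fixtures and closed-form oracles.

A fiber of cells with *linear* membrane conductance g_m coupled by gap
junctions G_gj is a resistive ladder.  Its steady subthreshold voltage
profile decays per cell by a factor 1/r where r > 1 solves

    r + 1/r = 2 + g_m / G_gj,

giving a discrete space constant lambda = 1/ln(r) in cell lengths; in
the continuum limit g_m/G_gj -> 0 this approaches the familiar
sqrt(G_gj/g_m).  These closed forms, together with a direct dense linear
solve of the ladder equations, validate the space-constant machinery
independently of the ionic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fiber_model import System

__all__ = ["PassiveFiberSpec", "analytic_discrete_space_constant",
           "passive_fiber_fixture", "passive_steady_state"]


@dataclass(frozen=True)
class PassiveFiberSpec:
    """Linearised-membrane fiber: membrane current is exactly
    g_m (V - E_rest) — no gates, no rectification."""

    g_m: float = 0.05       # uS, linear membrane conductance per cell
    E_rest: float = -85.0   # mV
    C_m: float = 0.095      # nF
    G_gj: float = 10.0      # uS
    n_cells: int = 100

    def __post_init__(self):
        if not (self.g_m > 0 and self.C_m > 0 and self.G_gj > 0):
            raise ValueError("g_m, C_m and G_gj must be positive")
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")

    @property
    def time_constant(self) -> float:
        """Membrane time constant C_m/g_m of the space-clamped fiber, ms."""
        return self.C_m / self.g_m


def analytic_discrete_space_constant(g_m: float, G_gj: float) -> float:
    """Space constant of the discrete resistive ladder, in cell lengths.

    lambda = 1/ln(r) with r the root > 1 of r + 1/r = 2 + g_m/G_gj.
    Strictly decreasing in g_m, strictly increasing in G_gj, and
    approaching sqrt(G_gj/g_m) as g_m/G_gj -> 0.
    """
    if g_m <= 0 or G_gj <= 0:
        raise ValueError("g_m and G_gj must be positive")
    x = g_m / G_gj
    r = 1.0 + 0.5 * x + math.sqrt(x + 0.25 * x * x)
    return 1.0 / math.log(r)


def passive_fiber_fixture(spec: PassiveFiberSpec) -> System:
    """Drop-in fiber system with a linear membrane.

    Usable unchanged by :func:`cardiofiber.engine.simulate` and
    :func:`cardiofiber.protocols.measure_space_constant`; the 21
    non-voltage state slots are carried as frozen constants so the fiber
    assembly and integrator run the production code paths bit-identically.
    """
    return System(n_cells=spec.n_cells, G_gj=spec.G_gj, passive=spec)


def passive_steady_state(spec: PassiveFiberSpec,
                         stim: np.ndarray) -> np.ndarray:
    """Steady voltage deviations of the ladder by direct linear solve.

    ``stim`` is the per-cell injected current (nA, inward negative).
    Solves (g_m I + G_gj L) dV = -stim with L the sealed-end graph
    Laplacian of the chain; the independent dense-algebra oracle for the
    simulated steady state.
    """
    stim = np.asarray(stim, dtype=float)
    n = spec.n_cells
    if stim.shape != (n,):
        raise ValueError("stim must have one entry per cell")
    lap = np.diag(np.r_[1.0, 2.0 * np.ones(n - 2), 1.0])
    lap -= np.diag(np.ones(n - 1), 1) + np.diag(np.ones(n - 1), -1)
    G = spec.g_m * np.eye(n) + spec.G_gj * lap
    return np.linalg.solve(G, -stim)
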