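# Methods

## The scientific question

Ventricular myocytes co-regulate the channel densities of the inward
rectifier potassium current (I_K1, Kir2.1) and the fast sodium current
(I_Na, Nav1.5): upregulating one upregulates the other ("reciprocal
modulation").  This package asks what that coupling does to tissue
excitability.  It simulates a guinea-pig ventricular cell and a
one-dimensional monodomain fiber of gap-junction-coupled cells, and
measures four things as the maximal conductances G_K1, G_Na and the
coupling conductance G_gj are varied independently or in tandem:

* the stimulus-current threshold of an isolated cell,
* the propagation threshold of a 100-cell fiber,
* the conduction velocity (CV) of the propagating AP, and
* the passive fiber space constant lambda.

## Cell model

The membrane model is the 22-state guinea-pig ventricular myocyte of
Noble, Varghese, Kohl & Noble (1998) ("basic" variant: fast sodium with
m^3 h gating, persistent and background sodium, L-type calcium with a
diadic space, rapid/slow delayed rectifiers, transient outward current,
inward rectifier, Na/K pump, Na/Ca exchanger, SR calcium cycling with
calmodulin/troponin buffering, and dynamic Na_i, K_i and four calcium
compartments).  All constants live in one versioned bundle
(`cardiofiber.constants.CellParameters`, serialised in
`src/cardiofiber/data/cell_constants.yaml`).  The unit system is
mV/ms/nA/uS/nF/mM throughout (uS x mV = nA, nF x mV/ms = nA).

The two currents under study are exposed explicitly:

    I_K1 = G_K1 * [K]_o/([K]_o + k_mK1) * (V - E_K) /
           (1 + exp((V - E_K - 10) * s * F/RT)),     k_mK1 = 10 mM

    I_Na = G_Na * m^3 * h * (V - E_Na),
    E_Na = RT/F ln((Na_o + 0.12 [K]_o)/(Na_i + 0.12 K_i))

with defaults G_K1 = G_Na = 0.5 uS.  Three formulation choices deserve
comment, because published dialects of this model family differ and the
choices were fixed by requiring the emergent physiology (threshold,
conduction velocity, fiber excitability boundary, APD trends) to be
self-consistent:

* **Rectification steepness** `s = K1_steepness = 1.25` (slope
  RT/1.25F ~ 21 mV at 310 K).  A steeper RT/2F reading removes I_K1
  from plateau potentials entirely; the plateau then has no
  G_K1-dependent repolarisation path and — decisively — fibers never
  lose excitability at high G_K1, abolishing the central phenomenon.
* **Sodium reversal** is the mixed Na/K reversal (P_mh = 0.12) of the
  reference model rather than the pure sodium Nernst potential; with
  the pure Nernst reversal (~+86 mV) the AP overshoots to +64 mV and
  the persistent sodium current pins the plateau permanently.
* **External potassium** K_o = 5.4 mM (physiological Tyrode), giving a
  resting potential of -85.4 mV.  With the 4 mM sometimes used in
  encodings of this model, rest sits at -93 mV, the cell threshold
  rises to -22 nA and the fiber excitability boundary moves ~0.15 uS
  higher.

All three are ordinary `CellParameters` fields, so either reading of
each can be recovered explicitly.

The resting state is computed per parameter set by integrating the
unstimulated cell for 20 s and polishing the end point with a scaled
Newton (hybr) solve of the full 22-dimensional right-hand side; the
accepted rest point has a residual max-norm below 1e-6 in model units
and is a genuine fixed point (the model's pump/leak fluxes balance).
No pre-pacing to a 1 Hz limit cycle is applied; all protocols start
from quiescent rest.

## Fiber model

`n_cells` identical cells (no spatial parameter variation) form a chain
with linear gap-junction coupling: cell i obeys

    C_m dV_i/dt = G_gj (V_{i-1} - V_i) - G_gj (V_i - V_{i+1}) - I_ion,i - I_stim,i

with sealed (no-flux) ends and all non-voltage states cell-local.
Defaults: 100 cells (2200 ODEs), G_gj = 10 uS, cell length 74 um.  The
state is flattened cell-major (22 slots per cell), making the Jacobian
block-tridiagonal with bandwidth 22 — the structure the integrator
exploits.  Stimulus current is delivered per targeted cell (the
reported amplitude is the per-cell amplitude, matching the single-cell
protocol's units; the study's wording does not fix whether the fiber
amplitude is total or per cell).

## Numerics

The right-hand side is one numba-compiled kernel shared by the single
cell, the fiber, and the passive fixture.  Integration uses LSODA
(variable-order, variable-step; BDF in the stiff regime — the same
stiff-solver family as classic cardiac practice) with rtol = atol =
1e-6 and a banded finite-difference Jacobian (ml = mu = 22).  The
robustness of the tolerance choice is asserted in the test suite:
halving both tolerances moves the AP peak by < 0.5 mV and the peak time
by < 0.1 ms on a default fiber run.  Integration restarts exactly at
every pulse edge so square pulses are never smoothed; sampling is
0.01 ms inside pulses, 0.02 ms through the post-pulse upstroke window
and 1 ms elsewhere.  Singular points of the rate equations (alpha_m at
V = -41 mV, the L-type constant-field factors at V = +50 mV) are
guarded by their analytic limits.  The engine contains no randomness;
identical inputs reproduce traces bit-for-bit.

## Protocols and their conventions

Where the study's verbal description leaves a quantity open, the choice
made here is listed; each is a documented constant in
`cardiofiber.protocols`.

* **AP detection**: peak V_m > 0 mV within 50 ms of the pulse (cell) or
  250 ms (fiber propagation; covers slow waves at G_gj = 0.1 uS).  A
  pulse only counts if the cell had repolarised below -40 mV at pulse
  onset, so a still-depolarised plateau is never scored as a new AP.
* **Thresholds**: 0.2 ms square pulses at 1 Hz on a 0.5 nA amplitude
  grid; threshold = smallest-magnitude grid amplitude for which two
  consecutive pulses both elicit APs (fiber: both propagate to the
  probe cell at 3/4 of the chain, cell 75 of 100).  The default search
  brackets/bisects the first-pulse response and then verifies the
  two-pulse criterion; the tests assert it returns exactly the value of
  the literal incremental scan.  Inexcitability is declared at an
  amplitude cap of about 100x the default-parameter threshold
  magnitude (-2000 nA for cells, -6500 nA for fibers).
* **Conduction velocity**: stimulus 1.5x the fiber threshold to cells
  1-4; CV = 50 cell lengths / (t_act(75) - t_act(25)), with activation
  time the instant of maximum dV/dt on the dense sampling (earliest
  sample on ties).
* **Space constant**: one 100 ms pulse to cells 1-4 at 95% of the
  separately measured long-pulse threshold ("within 10% below"), with
  automatic 5% back-off if the 0.5 nA threshold grid leaves that value
  marginally suprathreshold.  The end-of-pulse depolarisations of cells
  5 .. n-5 (stimulated cells and the sealed-end zone excluded, plus a
  floor cutting cells whose deflection is below 1e-6 of the maximum)
  are fitted to A exp(-i/lambda) by nonlinear least squares seeded from
  the log-linear slope; the rms residual is always reported.  For
  *comparisons across conductances* (lambda vs G_Na, lambda sqrt(G_K1))
  a common fixed amplitude (-5 nA) is used instead of per-point
  scaling: near-threshold pulses recruit subthreshold sodium current,
  whose contribution varies with the pulse size and would otherwise
  confound the comparison.
* **APD**: APD90 (time from maximum upstroke to 90% repolarisation
  toward the pre-stimulus rest).  The regime claims are insensitive to
  the level; APD50 is also computed in tests.  When a trace never
  reaches 90% repolarisation the measurement returns infinity, bounding
  the APD from below by the trace length.

## Sweeps

`cardiofiber.sweeps` drives the parameter sweeps: independent-G_Na,
independent-G_K1, and reciprocal modes with G_K1:G_Na ratios 1:2, 1:1
and 2:1 (ratio a:b maps grid value g to (G_K1, G_Na) = (g, g b/a); the
grid always indexes G_K1).  Default grids span G_Na 0.2-5 uS,
G_K1 0.3-5 uS (0.1 uS steps near the excitability boundary, 0.25 uS
elsewhere) and eight G_gj values over 0.1-20 uS.  The curve-shape
classifier counts sign changes of successive differences above a noise
floor equal to the threshold-search resolution (0.5 nA), so
quantisation wiggles are never classified as extrema.  Per-point
failures are recorded in the output table and the sweep continues;
records are flushed to CSV as computed.

## Passive fixture and oracles

A linearised-membrane fiber (membrane current exactly g_m (V - E_rest),
21 frozen state slots for bit-identical engine paths) provides ground
truth: the steady profile of the discrete resistive ladder decays per
cell by 1/r with r + 1/r = 2 + g_m/G_gj, giving lambda = 1/ln(r)
exactly.  The test suite closes the oracle chain — simulated steady
state, dense linear solve of the ladder, closed-form lambda — to
better than 2% over five (g_m, G_gj) combinations, and checks the
space-clamped RC time constant C_m/g_m.  The 2% tolerance reflects
sealed-end truncation of the ideal infinite cable at finite fiber
length.

## Problem sizes

The headline measurements (thresholds, baseline CV, excitability
boundary, reciprocal rescue, lambda) run on the full 100-cell fiber.
The CV-scaling slope checks use 80-cell fibers with activation read at
cells 20/60, and the figure-level sweep drivers under `analysis/` use
coarse conductance grids; both choices trade grid density, not
protocol fidelity, and the monotone/shape conclusions are unchanged on
denser grids.

## What the model reproduces, and known residuals

Reproduced at the stated tolerances: single-cell threshold -20.0 nA
(reported: approximately -19); baseline CV 67.8 cm/s at G_gj = 10 uS
(reported: 70); fiber thresholds larger than cell thresholds; the
just-subthreshold fiber response peaking near -60 mV; loss of fiber
excitability under independent G_K1 increase and its rescue by 1:1
tandem modulation up to at least G_K1 = 5 uS; |threshold| monotone
decreasing in G_Na, increasing in G_K1, increasing under all three
reciprocal ratios; CV ~ sqrt(G_Na) and ~ sqrt(G_gj) (log-log slopes
0.5-0.65 and ~0.5); lambda flat in G_Na, ~ 1/sqrt(G_K1) within 7%,
increasing in G_gj.

Known residuals (documented, not patched): the fiber excitability
boundary falls between 1.25 and 1.3 uS here versus 1.3-1.4 reported —
one 0.1 uS grid step low; the AP peak is ~+40 mV (this model family
peaks near +40 at G_Na = 0.5 uS for any of the dialect readings above)
versus the reported ~+20 mV; and the G_K1 = 0.25 uS regime gives
APD90 ~ 210 ms rather than > 1 s.  No parameter set of the reference
model reproduces those three numbers simultaneously with the threshold
and CV; the defaults here favour the threshold/conduction/excitability
results that the study's conclusions rest on.

## Limitations

One-dimensional, uniform, monodomain tissue only: no ephaptic/cleft
coupling, no bidomain formulation, no subcellular discretisation, no
heterogeneity, no temperature scaling (fixed 310 K), and quiescent
initial conditions rather than a paced limit cycle.  The passive
fixture validates the measurement machinery, not cardiac biology; the
ionic simulations inherit every simplification of the 1998 reference
model.
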