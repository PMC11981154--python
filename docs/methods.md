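# Methods

## Model structure

The spindle assembly checkpoint is modeled as a well-mixed reaction network
of eight molecular species in the yeast nucleus: free Cdc20 (C), free APC/C
(A), the active ligase APC/C^Cdc20 (AC), active and inactive Mad pools
(Mad_a, Mad_i), the kinase Mps1, free MCC (MC) and the inhibited assembly
APC/C^MCC (ACMC).  Unattached kinetochores (n_UK) are an external signal in
the deterministic analyses and a decaying stochastic species in washout
simulations.  The wiring combines two inhibitions into one positive loop:
MCC (made from active Mad plus Cdc20) sequesters APC/C^Cdc20, and
APC/C^Cdc20 degrades Mps1, which is the kinase activating Mad.  With enough
kinetochore signal both a checkpoint-ON state (low AC, high Mps1) and a
checkpoint-OFF state (high AC, low Mps1) are locally stable.

Bookkeeping conventions that the published totals force:

* APC/C^MCC carries **two** Cdc20 moieties (one APC-bound, one inside the
  MCC); total Cdc20 is C + MC + AC + 2·ACMC.
* The main APC/C^MCC degradation channel (rate `kdeg`) destroys one Cdc20
  and releases the other together with APC/C and Mad; background turnover
  of ACMC destroys both Cdc20.
* Mad released by complex turnover returns to the **active** pool.  Routing
  it to the inactive pool makes the arrest steady state infeasible (the
  required inactivation flux would be negative).
* APC total (A + AC + ACMC = 100 molecules = 40 nM) and Mad total
  (Mad_i + Mad_a + MC + ACMC = 175 molecules = 70 nM) are exactly conserved;
  both engines preserve them to 1e-6 relative (ODE) or exactly (SSA).

## Rate laws and the reconstructed Mad-inactivation law

All assembly/disassembly steps are mass action, with dissociation rates
derived as KD × k_ass.  Mad activation is Michaelis–Menten in inactive Mad
and linear in Mps1 and in the saturating kinetochore signal
s(n_UK) = k'·n_UK/(J_n + n_UK).

The Mad *inactivation* step is modeled as a zero-order (constant-capacity)
Michaelis–Menten flux,

    V_inact · Mad_a / (J_inact + Mad_a),

i.e. a constitutive phosphatase-like activity working near saturation.
This functional form was reconstructed by flux balance against the two
published steady-state columns: a capacity V_inact ≈ 33 molecules/min
(numerically `kinact` × 4900 in each unit column's own units) is the unique
value balancing the arrest (ON) column, and J_inact = 1.15 molecules
(0.46 nM) is pinned by the post-checkpoint (OFF) column, where the model
then reproduces the published Mad_a ≈ 2, ACMC ≈ 15–16 and AC ≈ 82–83
molecules.  Mass-action alternatives (`kinact·Mad_a·(J+Mad_a)`,
`kinact·Mad_a²/(J+Mad_a)`, bilinear forms in other species) fail those
balances by 30–300% of the largest flux and/or abolish the OFF branch at
ten unattached kinetochores.  The zero-order form is also the standard
kinase/phosphatase ultrasensitivity motif that gives the switch its
threshold behavior.

## Unit systems

The canonical parameterization is in molecules per nucleus (2.5 molecules
per nM, i.e. ≈ 4.15 fL); it balances the published molecule-unit steady
states to within rounding.  The deterministic engine runs the mean field of
this system; a dynamically equivalent nanomolar set
(`ModelParameters.nanomolar()`) is obtained by the exact volume rescaling,
and nanomolar results (e.g. free Cdc20, total Cdc20) are reported through
the same factor.  The separately published nanomolar column
(`ModelParameters.nanomolar_printed()`) is retained for serialization
completeness but is **not** used by the analyses: its bimolecular constants
are not volume-consistent with the molecule column (they differ by the
squared volume factor), its Mps1 synthesis exceeds total Mps1 degradation
at the arrest state about four-fold, and integrated as printed it loses
bistability altogether.  The volume factor is used only for state/threshold
conversion (80 molecules ↔ 32 nM), never to convert rate constants of that
printed column.

Deterministic synthesis uses the full synthesis rates with no promoter
duty-cycle factor; this matches the printed arrest state (Mps1 = 17
molecules against 16.6 predicted).  An optional duty-cycle multiplier
(kon/(kon+koff) = 0.909) is exposed on `ModelParameters` for sensitivity
checks.

## Deterministic analyses

Steady states are found by settling long integrations (LSODA, rtol = atol =
1e-9) started from the published ON and OFF states and their midpoint, then
polishing with Newton iterations in reduced coordinates (the two conserved
moieties eliminated, removing the exact zero modes of the Jacobian).
Stability is judged from the reduced 6×6 Jacobian.  When two stable states
coexist, the separating unstable state is located by bisecting the basin
boundary along the ON–OFF segment in state space and polishing from there.
Published initial-condition columns carry rounding-level inconsistencies in
the conserved totals (e.g. APC total 99 vs 100 molecules); steady-state
seeds are projected onto the canonical conserved leaf so that fixed points
from different seeds are comparable.

The saddle-node position is found by bisection on the existence of the
checkpoint-ON attractor (settling from the ON state and asking whether AC
stays below half the anaphase threshold), to a default bracket of 0.01
kinetochores, reported to 0.1.  n_UK is continuous here; fractional values
are meaningful as signal strengths (e.g. residual lack-of-tension
signaling).

The transient Mps1-overexpression protocol starts from the OFF state at a
nonzero tension-free signal (default 10 n_UK-equivalents; the value is a
design choice, any signal inside the bistable window behaves the same),
triples Mps1 synthesis for 60 minutes, and reports whether the system is
captured by the ON attractor and remains there afterwards.

## Stochastic engine

The direct-method SSA (statistically exact; copy numbers are ~10², so no
leaping) simulates the 22-reaction network including two-state promoters
for Cdc20 and Mps1 (kon = 1/min, koff = 0.1/min, duty cycle 0.909).
Promoters start ON; initial conditions are the published integer states.
First passage of AC ≥ 80 molecules is recorded at exact event times
together with the current n_UK; adaptation means crossing with n_UK > 0,
exit means crossing at n_UK = 0, arrest means no crossing within the
horizon (defaults: 700 min for fixed-n_UK arrest, 960 min for washout).
Washout enables the first-order attachment channel (katt = 0.03/min) from
t = 0 with n_UK(0) = 10.  Ensembles use consecutive seeds from a single
`seed0`; every summary stores per-run seeds, so any run can be replayed.
The kernel is a numba-compiled loop; its exactness is checked against the
birth–death closed form (stationary mean ksyn·duty/kdeg, Poisson variance
without bursting) and the sequential-attachment closed form
E[T] = H₁₀/katt ≈ 97.6 min.

Crossing-time ensembles are summarized by a maximum-likelihood exponential
fit (delay 0 by default — simulations start with APC/C^Cdc20 already
formed, so unlike experiments they show no initial delay) and the
coefficient of variation as a memorylessness diagnostic.

## Trace analysis

* **Localization Index**: maximum of the fixed 3×3 Laplacian-of-Gaussian
  filter response over the segmented cell; the per-cell threshold is 110%
  of the maximum index during the first 20 minutes (G1).  Threshold
  comparisons are strict.
* **Kinetochore signal**: 5×5-pixel sum on the non-deconvolved average
  projection (deconvolution does not preserve total intensity);
  border-clipped windows are area-renormalized and flagged.
* **Clb2 degradation onset**: Savitzky–Golay smoothing (window 7 frames,
  order 2 — the filter's parameters are a design choice) followed by a
  three-step rule: a post-budding local maximum with two consecutive lower
  smoothed frames, confirmation that the smoothed signal drops below 90% of
  the candidate level within four frames (rejecting filter-overshoot
  artifacts at the rise–plateau corner, which never develop into a fall),
  and refinement of the onset on the raw trace (polynomial smoothing leaks
  the decline a few frames backwards; the onset advances while the raw
  signal remains within 10% of the local plateau).  A candidate on a steep
  rise (smoothed gain > 10% over the two preceding frames) is rejected as
  an overshoot artifact.  On noise-free rise–plateau–fall traces the rule
  recovers the breakpoint exactly; at 2% Gaussian noise it is within one
  frame in ≥ 95% of seeds.
* **Degradation rate**: log-linear least squares on four frames from the
  onset, sign-flipped so decay is positive.  Cells with rate < 0.01/min or
  losing < 50% of their Clb2 within 90 minutes are *partial*; cells with no
  onset are *arrested*.
* **Adaptation call**: only fully degrading cells are scored; a cell is
  *adapted* when Mad2 is still localized at the degradation-onset frame and
  *exited* otherwise.
* **Missegregation predictor**: 1 − (1−p)^n with n = 16 chromosomes.

## Synthetic data generator

Cohorts emulate the statistical structure of the time-lapse experiments:
10-minute frames; Clb2 rises over 30 minutes after budding (30 min), holds
a plateau (100 a.u.) for a random arrest length drawn as 100 min +
Exp(150 min) — the delay-plus-exponential shape of measured arrest
durations — then falls exponentially at 0.05/min (full), 0.005/min
(partial, deliberately below the 0.01 cutoff) or never (arrested).  The
Mad2 index sits at a G1 baseline, rises three-fold during the arrest, and
delocalizes 30 minutes before the Clb2 fall (exited) or after it
(adapted).  Additive Gaussian noise defaults to 2% of the plateau.  The
SSA-to-observable mapping holds the Clb2 proxy at plateau until the first
AC-threshold crossing, then decays it at 0.05/min, and renders the Mad2
index as a saturating function of the current n_UK (baseline at zero); a
G1 stretch is prepended for threshold calibration.

What passing round-trip tests show: the classification rules invert this
generator (and the SSA mapping) essentially perfectly at realistic noise.
What they do not show: robustness to segmentation errors, photobleaching,
focal drift, partial Mad2 dilution by overexpression, or any real-imaging
artifact — real-microscopy ingestion is out of scope.

## Problem sizes and numerical choices

Stochastic ensembles default to n = 100 runs (the size used for the
correlation analyses); the test suite uses 60-run ensembles for shared
fixtures.  ODE tolerances are rtol = atol = 1e-9 (1e-10 for conservation
checks); steady-state residuals are required below 1e-8 of the largest
single reaction flux.  Saddle bisection brackets to 0.01 kinetochores.
All randomness flows from named integer seeds; SSA ensembles use
`seed0 + run_index`.

## Known limitations

* The wild-type saddle node computes to ≈ 0.6 unattached kinetochores with
  this reconstruction, lower than the ≈ 0.9 of the original analysis; the
  mutant saddle positions (≈ 0.3 APC-A, ≈ 0.4 GAL1-MAD2) and both
  published steady-state columns are reproduced.  The discrepancy traces to
  the irrecoverable parts of the inactivation law: moving the activation
  Michaelis constant far enough to place the wild-type saddle at 0.9
  simultaneously misplaces the Mad2-overexpression saddle, so the printed
  constant is kept.
* Escape from a ten-kinetochore arrest has mean ≈ 340 min here, so the
  slowest of 100 trajectories crosses well after 600 min.  A faster escape
  (obtainable only by pushing the inactivation capacity beyond what the
  steady-state balances allow) overshoots the washout adaptation fraction;
  the parameterization sits on the washout-consistent side of that
  trade-off.
* While the checkpoint signal persists (n_UK > 0), the high-AC state is a
  shallow stochastic attractor: after a threshold crossing, fluctuations can
  re-engage the checkpoint (the Mad activation flux at the OFF state,
  ~21/min, sits close to the saturated inactivation capacity of 33/min).
  Biologically the crossing commits the cell to anaphase, so simulations
  report first-passage quantities and by default stop at the crossing; the
  post-crossing behavior of the unmodified network is not meaningful.  Once
  all kinetochores are attached the OFF state is genuinely absorbing.
* Tension and attachment are a single signal; no kinetochore geometry,
  error correction or re-detachment.
* No securin/Pds1, Clb2/Cdk1 or PP2A species: Clb2 exists only as a derived
  observable proxy.
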