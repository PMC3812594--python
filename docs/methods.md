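# Methods

This note documents the models, algorithms and design choices behind
`ebis`, in the spirit of a statistical-software methods appendix.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cole model and the conductance domain

A single-dispersion Cole model describes each sweep:
`Z(f) = R∞ + (R0 − R∞)/(1 + (j f/fc)^α)`, with `R0 > R∞ > 0`,
`α ∈ (0, 1]`, `fc > 0`.  The complex power uses the principal branch.  The
conductance form implemented in `ebis.cole.cole_conductance` is the
algebraic expansion in `Y0 = 1/R0`, `Y∞ = 1/R∞` and `cos(απ/2)`; it is
identical to `Re(1/Z)` (a tested invariant, agreement to ~1e-15 relative),
monotone non-decreasing in frequency and bounded in `[Y0, Y∞]`.

Two closed forms used throughout: at `f = fc` the Cole impedance has
`Rc = (R0 + R∞)/2` exactly (independent of `α`) and
`Xc = (R0 − R∞)·tan(απ/4)/2`, so the phase ratio is
`Rc/Xc = (R0 + R∞) / ((R0 − R∞)·tan(απ/4)) ≥ (R0 + R∞)/(R0 − R∞) > 1`.
The lower bound at `α = 1` constrains what the synthetic generator can do
(see below).

A capacitance `c_p` in parallel with the load maps `1/Z → 1/Z + j2πf c_p`:
susceptance shifts, conductance is untouched.  Fitting on the conductance
therefore yields leakage-free Cole parameters; this is the reason the
estimator works in the admittance real part rather than on `|Z|` or the
reactance.

Reactance is stored signed (`Im Z`, negative across a Cole dispersion);
frequencies are handled in Hz everywhere in memory and in files.

## Parameter estimation

`ebis.fitting.fit_cole_conductance` minimises the unweighted residual
between measured conductance `Re(1/Z)` and the model, over the internal
parameterisation `(r_inf, r0 − r_inf, α, log fc)` — box bounds then enforce
ordering and positivity smoothly (`α ∈ [1e-3, 1]`,
`fc ∈ [f_min/10, f_max·10]` relative to the measured grid).  The solver is
scipy's bounded trust-region-reflective least squares with a
finite-difference Jacobian, no random restarts, so results are
deterministic.  Tolerances default to machine epsilon: with the more usual
1e-10 the gradient criterion stops ~1e-4 short of the optimum when the true
`α` sits on its upper bound, while machine-epsilon tolerances reach ~1e-7
at a cost of a handful of extra iterations.  Non-convergence within the
iteration budget is flagged on the result, never raised.

The starting point takes `R0` from the lowest-frequency resistance (+5%),
`R∞` from the highest (−5%), `α = 0.7`, and `fc` from the reactance-
magnitude peak, falling back to the geometric mean of the grid endpoints
when the peak sits on a boundary.  Inputs need at least 8 points spanning a
decade.

## Features, tree, cross-validation

Features are computed per hemisphere from central/lateral fit pairs matched
by repeat index (the two montages are recorded consecutively, making index
pairing the natural bijection; pairs with an unconverged fit are skipped
with a warning).  Exact identities tested: identical sides give (1, 1, 1);
swapping sides inverts each feature; `f3` is invariant under joint scaling
of both resistances on one side.

The classifier is a fixed chain of single-feature threshold nodes — by
default `f2` at 1.01 (below exits healthy), then `f3` at 0.4 (below exits
damaged), then a final split on `f1` at 0.9 (below damaged, above
healthy).  Ties continue down the tree, keeping exits strict inequalities.
The first node's 1.01 is the primary default; 1.10 is an equally citable
alternative for the `f2` cut and can be configured through the tree JSON.
Node directions and leaf labels are configurable skeleton inputs rather
than fixed constants.

Threshold tuning (`tune_thresholds`) is greedy and per-node, mirroring the
tree's hierarchical construction: candidates are midpoints between
consecutive sorted training values of the node's feature; the candidate
minimising the node's stump error (exit side scored against the exit
label, continue side against the complementary label) wins, with ties
broken towards the skeleton default and then towards the smaller value.
Records exiting a tuned node are removed before the next node is tuned.  A
node whose remaining records are single-class carries no information about
its cut and keeps the skeleton default — in practice this happens at nodes
2 and 3 whenever node 1 already separates the classes, so the downstream
defaults must themselves be valid for the data at hand (a constraint the
synthetic generator honours by construction).  Training sets containing a
single class raise a tuning error.

Cross-validation leaves out one **subject** at a time — both hemispheres,
all 40 feature vectors — tunes on the remainder, and averages the
per-subject misclassification percentages with equal weights (`E = mean
E_i`).  A fold whose training set degenerates to one class is marked
invalid, excluded from the mean, and still counted as an iteration.

## Synthetic study generator

The generator emulates the study design end to end: 6 healthy subjects and
3 unilateral-stroke patients (two left-sided, one right-sided), 2 montages
× 20 repeats per hemisphere, 256 log-spaced frequencies over
3.096 kHz–1 MHz; 720 spectra in total, 120 from stroke hemispheres.

Parameters are drawn hierarchically: a subject-level Cole template
(log-normal around `R0 = 100 Ω`, `R∞ = 40 Ω`, `α = 0.75`, `fc = 35 kHz`;
log-sds 0.08 for the resistances, 0.05 for `α`, 0.10 for `fc`), a mild
left/right asymmetry (log-sd 0.02), and a central/lateral ratio
perturbation of log-sd 0.005 for healthy tissue.  The template scale is
arbitrary — no absolute head-impedance values are available to anchor it —
but `α ≈ 0.75` matters: with much broader dispersions (lower `α`) the
infinite-frequency limit is unconstrained by a 1 MHz sweep and fitted `R∞`
ratios become too noisy to resolve the sub-percent asymmetries the method
relies on.  Each measurement repeat adds independent Gaussian noise of
standard deviation `0.005·|Z(f)|` to resistance and reactance, emulating
relative instrument noise; an optional stray capacitance loads every
spectrum.  All randomness flows from one integer seed through
per-(subject, purpose) substreams, so a subject's data are invariant to
cohort-size changes.

Damage is injected at the feature level on the stroke hemisphere, not
through a lesion model (none is available): multiplicative effects set the
central/lateral `R0` and `R∞` ratios directly, and an optional phase-ratio
target sets `f3` through the central `α`.  The `Rc/Xc` lower bound above
makes strong downward `f3` targets unreachable by `α` alone, so the
generator first enlarges the central dispersion (raises `R0`, keeping
`R∞/R0 ≥ 0.06` — below that floor the fitted `R∞` becomes unusably noisy)
and, for subjects whose drawn lateral dispersion is too shallow, deepens
the lateral shape (lowers the lateral `α`, which stays in the
well-conditioned ≥ 0.65 range) until the target holds exactly.  A
consequence worth knowing: an `f3`-targeted patient's realised `R0` ratio
lands well above its configured floor (values of 3–8 are typical), i.e.
the three features are not independently controllable — a genuine property
of the single-dispersion Cole model, not an implementation limit.

The default per-patient effects exercise every node of the default tree:
patients 1 and 3 (`f2` ×1.15 / ×1.20, `f3` targets 0.33 / 0.35) exit at the
phase-ratio node, patient 2 (`f1` ×0.70, `f2` ×1.30) at the final `R0`
split; every patient's `f2` stays above the first node's healthy exit.
Effect sizes are deliberately large relative to the healthy spread so that
the cohort is separable — the end-to-end zero cross-validation error the
tests assert is a calibration property of the generator, verified across
seeds, and says nothing about clinical performance on real measurements.

## What the synthetic data do not emulate

Electrode-skin interface effects, instrument artefacts other than parallel
stray capacitance, multi-dispersion (bimodal) tissue behaviour,
lesion-geometry and volume-conductor physics, and between-montage
correlations beyond the shared hemisphere parameters.  Passing tests
demonstrate the correctness and internal consistency of the pipeline under
the stated generative assumptions, not diagnostic accuracy on patients.

## Numerical and I/O choices

Degenerate inputs fail loudly: zero-magnitude impedance points,
dispersion-free parameter sets (undefined `f3`), single-class training
sets, mismatched pairing lists.  Tabular artifacts are CSV written with
`%.17g` and read with round-trip float parsing, so file-chained CLI runs
are bit-identical to in-memory runs (tested).  Problem sizes in the test
suite: the full 720-spectrum default cohort is fitted once per session and
shared across tests; model-consistency checks use 100 random parameter
sets; the noisy-recovery study uses 50 replicates at 1% noise.
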