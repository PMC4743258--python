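# Methods

## Model

`dnacyc` treats double-stranded DNA as a chain of rigid base pairs.  Each
step between consecutive base pairs is described by six helicoidal
coordinates in the canonical order (tilt, roll, twist, shift, slide, rise):
angles in degrees and displacements in Å at every public interface, radians
internally (converted exactly once, in `params.profile_radians`).

**Sequence dependence.**  A `ParameterSet` maps local sequence contexts
(k-mers of width 2, 3 or 5) to equilibrium step coordinates.  Coordinates a
table omits fall back to canonical B-DNA defaults: tilt = roll = 0°, twist
= 34.30°, shift = slide = 0 Å, rise = 3.40 Å.  Two validation sets ship as
builtins: a sequence-independent *straight* model (twist 34.28°, rise
3.40 Å, all else zero) and an intrinsically *curved* model over the
artificial alphabet {X, Z} (XX/XZ: twist 36.00°, no bend; ZZ/ZX: twist
35.57°, roll 7.41°), whose 5X/5Z repeat bends 150 bp into a near-circle
(minimum-energy end-to-end distance 3.65 Å, 0.7 % of the contour length).

**Context assignment.**  Step *k* (1-based, between bases *k* and *k*+1)
takes the parameters of the window anchored on its 5′ base: bases
*k*..*k*+1 (width 2), *k*−1..*k*+1 (width 3), *k*−2..*k*+2 (width 5).  No
convention for centering odd windows on a step is universal; this one is a
single declared choice, implemented in one place.  In linear mode a window
that overruns either sequence end falls back to the defaults (chains are
generated as linear molecules); a `circular` flag wraps the window instead.
A context absent from an A/C/G/T table resolves through its reverse
complement with tilt and shift negated — the standard strand-exchange
symmetry of the step coordinates — so tables listing only unique steps
still cover all contexts.  Whether published tables were already
symmetrized cannot be settled here; loading a fully enumerated table makes
the fallback moot.

**Elasticity.**  Fluctuations around Θ⁰ are harmonic with a symmetric
positive-semidefinite 6×6 matrix of elastic moduli stored pre-divided by
kT, so energies are in kT units and temperature never appears explicitly.
The headline analyses use the diagonal isotropic-bending shorthand: RMS
tilt = roll = 4.84°, RMS twist = 4.09°, displacements frozen (σ = 0).  A
zero stiffness eigenvalue is treated as a *frozen* direction (deviation
identically zero), matching the σ = 0 shorthand; the general coupled-matrix
path is implemented and tested but not exercised by the defaults.  The RMS
bend of 4.84° per step gives a tangent-correlation decay length of
−1/ln(1 − σ²) ≈ 140 steps (≈ 147 bp is the conventionally quoted
persistence length for this stiffness; the test window 130–155 bp covers
both).

**Geometry.**  Step transforms use the mid-step triad construction: the
bend Γ = √(tilt² + roll²) is applied about an in-plane axis at phase
φ = atan2(tilt, roll) from the roll axis, twist is split symmetrically
around the bend, and displacements are expressed in the half-way triad.
This is the de facto standard rebuild algebra for these six coordinates; it
reproduces the exact checks (10 × 36.00° twist = identity; a single
nonzero angle rotates by exactly that angle; pure twist translates by the
rise).  The plain-numpy implementation in `geometry` is the reference; the
numba batch kernels in `_kernels` reimplement the same algebra and are
cross-checked against it to 1e-10 in the tests.

## J-factor estimation

A chain of N base pairs is sampled by drawing each step's deviations along
the principal axes of βF (σᵢ = 1/√Dᵢᵢ) and composing the step transforms.
Closure is a nested test with the standard thresholds: end-to-end distance
r < 30 Å; then alignment of terminal normals cos γ > 0.86; then torsional
register cos φ > 0.86, where φ is the rotation about the *average* terminal
normal carrying the first short axis onto the last (well-conditioned
whenever γ is small, the only regime in which φ is evaluated).

The J factor is the product of three empirical densities, each normalized
over its acceptance window:

    W  = (n_r / n_total) / V_cap              [Å⁻³],  V_cap = (4/3)π·30³
    Γ  = (n_γ / n_r) / (1 − 0.86)             [per unit cos γ]
    Φ  = (n_φ / n_γ) / (2·arccos 0.86)        [per radian]
    J  = 4π · W · Γ · Φ · (10²⁷/N_A)          [mol/L]

With this bookkeeping no further calibration constant is needed: for an
ensemble with uniform end density and isotropic terminal frames the formula
returns exactly the molar concentration of one end in the sampling volume
(`fixtures.make_known_density_ensemble` verifies all three factors and the
product against their closed forms), and in the long-chain limit it
converges to the Gaussian-coil contact concentration
(3/(2π⟨r²⟩))^{3/2}·10²⁷/N_A (verified at 4000 bp within sampling error).
Whether the torsional window should be measured in radians or in cos φ is a
genuine ambiguity of the decomposition; the radian convention is declared
here and validated by those two oracles.

**Convergence.**  Because the conditional ratios telescope, the estimate is
proportional to n_φ/n_total; the relative standard error of that rate,
computed from the variance of per-batch estimates (≥ 20 equal-size batches
by default), is the convergence criterion.  Sampling stops at 5 % relative
error or at the chain budget (default 10¹⁰ effective chains at desk scale;
the published cap of 5×10¹⁵ is configurable).  Fragments with no closures
at the budget are reported at the 10⁻¹⁵ M floor and flagged.  The error
estimator is a declared choice — the three factors are correlated ratios,
so batch variance is used rather than error propagation.

**Half-chain enhancement.**  M first halves are built forward from the
canonical frame and M second halves are sampled independently; rigid
composition of pair (i, j) has terminal origin o_i + R_i p_j and triad
R_i T_j, so the pair closes iff p_j lies within the capture radius of
−R_iᵀ o_i.  All M² ordered pairs are evaluated through a uniform grid (cell
= capture radius, 27-neighbour search — an exact prefilter, verified
against exhaustive pairing).  n_total = M² per batch; the estimator's
expectation equals the naive one's, and pairs sharing a half are
correlated, which the between-batch error estimate absorbs.  Randomness
comes from one seeded generator split deterministically into the two
half-chain streams (`Generator.spawn`).

## Synthetic data

The fixture generators stand in for data that cannot ship with the package:

* `make_synthetic_parameter_set` — full-coverage tables with twist
  ~ U(30°, 40°) and roll/tilt ~ U(−8°, 8°), displacements at defaults;
  realistic magnitudes for B-DNA step tables, not literature values.
* `make_synthetic_benchmark` — random equal-probability sequences whose
  pseudo-experimental J is the straight-model J at the sequence's length
  times 10^(noise·z), z standard normal.  The default noise of 0.5 decades
  is a synthetic choice of the same order as the scatter between simulated
  and measured J factors for >100 bp fragments; it is not an estimate of
  any particular dataset.  Records carry the noiseless generating value so
  recovery tests can count exactly.
* `make_known_density_ensemble` — the normalization oracle described above.

What passing these tests shows: the estimator, normalization and
concordance machinery are correct for the model as specified.  What they do
not show: that any particular parameter table reproduces *measured* J
factors — synthetic benchmarks have no sequence-specific bendability, no
experimental error structure beyond lognormal noise, and no base-composition
bias.

## Problem sizes and numerical choices

Test and example budgets are chosen so the full suite runs in a few minutes
on one CPU: equipartition at 10⁵ samples; persistence length from 4×10³
chains of 400 steps; estimator equivalence at 1.6×10⁵ naive chains vs
2–3×10⁸ half-chain pairs; the torsional-oscillation scan of straight-model
J(L) at 1 bp resolution over 340–381 bp (4 helical repeats, ~5×10⁸
effective chains per length), where closures are observable at desk scale —
below ~250 bp the straight model needs >10¹² effective chains per length;
the Gaussian-limit check at 4000 bp uses a 60 Å capture radius purely for
counting efficiency (the end density is flat over any window much smaller
than the ~3500 Å coil).  Peak positions for the oscillation period are
taken from a 3-point moving average with parabolic refinement.

Other numerics: orthonormality of triads is validated at 1e-9; stiffness
eigenvalues below −1e-10 are rejected, small negatives clipped to zero;
closure thresholds are strict inequalities (r = 31 Å with a 30 Å radius is
a miss); all geometry is double precision and no equality test is
tolerance-free.  Degenerate inputs fail loudly: empty profiles, chains
shorter than 2 bp (4 bp for half-chain sampling), non-PSD elastic matrices,
non-positive J factors in concordance inputs.

## Limitations

* Harmonic, uncoupled-by-default elasticity with one fluctuation model for
  all steps; no sequence-dependent force constants (the per-step interface
  exists but the default is uniform), no twist–bend coupling unless a full
  matrix is supplied.
* No kinkable or meltable chain variants, which are the leading candidate
  explanations for the systematic under-prediction of sub-100 bp
  cyclization by rigid-step models.
* Parameter tables are inputs; the package does not estimate them from
  structural or nucleosome data.
* The ligation-kinetics route to experimental J factors
  (J = 2 M₀ lim C(t)/D(t)) is documented for context only and never
  computed.
* The closure thresholds (30 Å, cos > 0.86) are part of the estimator
  definition; J values at small counts depend on them, and comparisons
  should hold them fixed.
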