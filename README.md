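# dnacyc

Sequence-dependent Monte Carlo estimation of DNA cyclization **J factors**
from rigid base-pair-step parameters.

## The problem

How easily a DNA fragment bends into a closed ring is quantified by the
Jacobson–Stockmayer J factor — the ratio of the equilibrium constants for
cyclization and bimolecular association, with units of concentration
(mol/L).  For long DNA the wormlike chain with a ~150 bp persistence length
describes cyclization well, but it ignores both the double helix's
three-dimensional structure (torsional register) and its sequence-dependent
intrinsic curvature.  `dnacyc` implements a coarse-grained rigid
base-pair-step model for researchers who want to compute J factors for
specific sequences under different published (or synthetic) tables of
equilibrium step parameters and compare them with experimental
measurements.

## The model

Each base-pair step *k* carries six helicoidal coordinates
Θ = (tilt, roll, twist, shift, slide, rise), with sequence-dependent
equilibrium values Θ⁰ taken from a context-keyed parameter table (di-, tri-
or pentanucleotide) and canonical B-DNA defaults (twist 34.30°, rise
3.40 Å) wherever a table is silent.  Thermal fluctuations are harmonic,

&nbsp;&nbsp;&nbsp;&nbsp;G_k = ½ ΔΘᵀ (βF) ΔΘ,&nbsp;&nbsp;&nbsp;&nbsp;P_k(Θ) ∝ e^(−G_k),

with the elastic matrix βF normalized to kT.  Diagonalizing βF gives
independent normal coordinates sampled with σᵢ = 1/√Dᵢᵢ; the headline model
is isotropic bending with RMS tilt = roll = 4.84° (persistence length
≈ 147 bp) and RMS twist = 4.09°, displacements frozen.  Sampled steps are
composed as rigid transforms (mid-step triad convention) and a chain counts
as cyclized when its ends coincide (r < 30 Å), its terminal normals align
(cos γ > 0.86) and its torsional register matches (cos φ > 0.86).  The J
factor is the product of the three nested empirical densities,

&nbsp;&nbsp;&nbsp;&nbsp;J = (4π / N_A) · W(r ≈ 0) · Γ_r(cos γ ≈ 1) · Φ_{r,cos γ}(φ ≈ 0),

converted to mol/L.  Sampling runs until the between-batch relative error
drops below 5 % or the chain budget is exhausted; fragments with no
closures are reported at the 10⁻¹⁵ M floor.  Besides the naive estimator, a
half-chain enhancement samples M half-chains from each end and evaluates
all M² implied full chains through an exact spatial-grid prefilter, making
10⁹–10¹⁰ effective samples affordable on one CPU.

## Worked example

```python
from dnacyc import (SamplerConfig, builtin_curved, curved_sequence,
                    default_fluctuations, equilibrium_profile,
                    estimate_j_halfchain)

fluct = default_fluctuations()                       # 4.84deg bend, 4.09deg twist RMS
cfg = SamplerConfig(seed=0, batch_size=1024, min_batches=20,
                    max_chains=20 * 1024**2)
profile = equilibrium_profile(curved_sequence(150), builtin_curved())
est = estimate_j_halfchain(profile, fluct, cfg,
                           parameter_set="curved", sequence_id="X5Z5_150bp")
print(f"{est.sequence_id}: J = {est.j:.2e} M  (rel. error {est.rel_error:.1%}, "
      f"{est.counts.n_phi} closures in {est.counts.n_total:.1e} chains)")
```

prints

```
X5Z5_150bp: J = 1.59e-03 M  (rel. error 1.6%, 27038 closures in 2.1e+07 chains)
```

The intrinsically curved validation model (5X/5Z dinucleotide repeat, whose
minimum-energy 150 bp chain closes to within 3.7 Å) cyclizes at an
effective end concentration of ~1.6 mM.  The same fragment length under the
straight model yields **zero** closures in 3.4×10⁸ chains and is reported
at the 10⁻¹⁵ M floor — intrinsic curvature raises the cyclization rate of a
one-persistence-length fragment by many orders of magnitude.

The same functionality is available from the shell:

```bash
dnacyc generate --n-per-length 10 --lengths 350,400 --seed 1 --out random.fa
dnacyc simulate --seq random.fa --params straight --seed 1 --out j.tsv
dnacyc baseline --lengths 340:380:2 --seed 1 --out baseline.tsv
```

plus `dnacyc evaluate` (benchmark table × parameter sets) and
`dnacyc concordance` (order-of-magnitude agreement curves).

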