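"""Synthetic data with known answers, for tests and demonstrations.

Everything here is generated, seed-reproducible and clearly synthetic:

* full-coverage parameter tables with angles drawn from realistic uniform
  ranges (twist 30-40°, roll/tilt within ±8°),
* benchmark records whose "experimental" J is the straight-model J at the
  sequence's length perturbed by lognormal noise of known width — the
  noiseless generating value travels with each record so recovery tests can
  count exactly,
* an end-frame ensemble with *uniform* end-to-end density in a box and
  isotropic terminal frames, for which all three closure factors have
  closed forms (W = 1/V_box, Gamma -> 1/2 per unit cos gamma, Phi -> 1/(2 pi)
  per radian) — the oracle that pins the J normalization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import special_ortho_group

from .montecarlo import SamplerConfig, estimate_j_halfchain
from .params import (
    DNA_ALPHABET,
    FluctuationModel,
    ParameterSet,
    builtin_straight,
    default_fluctuations,
    equilibrium_profile,
)
from .pipeline import BenchmarkRecord, generate_random_sequences

__all__ = [
    "FixtureSpec",
    "make_synthetic_parameter_set",
    "make_synthetic_benchmark",
    "make_known_density_ensemble",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Bookkeeping for a reproducible fixture: seed, sizes, noise width."""

    seed: int = 0
    n: int = 10
    lengths: tuple[int, ...] = (200,)
    noise: float = 0.5  # lognormal sigma of pseudo-experimental J, log10 units


def make_synthetic_parameter_set(
    context_width: int,
    seed: int | None = None,
    name: str | None = None,
) -> ParameterSet:
    """Full-coverage random parameter table (synthetic, not literature values).

    Twist ~ U(30°, 40°), roll and tilt ~ U(-8°, 8°); displacements fall back
    to the canonical defaults.  Covers all 4^width contexts.
    """
    if context_width not in (2, 3, 5):
        raise ValueError("context_width must be 2, 3 or 5")
    rng = np.random.default_rng(seed)
    table = {}
    for kmer_tuple in itertools.product(DNA_ALPHABET, repeat=context_width):
        kmer = "".join(kmer_tuple)
        table[kmer] = {
            "tilt": float(rng.uniform(-8.0, 8.0)),
            "roll": float(rng.uniform(-8.0, 8.0)),
            "twist": float(rng.uniform(30.0, 40.0)),
        }
    return ParameterSet(
        name=name or f"synthetic_w{context_width}",
        context_width=context_width,
        table=table,
    )


def make_synthetic_benchmark(
    n: int,
    length_range: tuple[int, int],
    cfg: SamplerConfig,
    noise: float = 0.5,
    seed: int | None = None,
    fluct: FluctuationModel | None = None,
) -> list[BenchmarkRecord]:
    """Random sequences with pseudo-experimental J factors (synthetic stand-in
    for a curated benchmark).

    Pseudo-experimental J = straight-model J(length) * 10^(noise * z) with z
    standard normal; the straight-model baseline is computed once per unique
    length with the half-chain estimator under ``cfg`` and carried on each
    record as ``j_baseline``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 4 or hi < lo:
        raise ValueError("length_range must satisfy 4 <= lo <= hi")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n)
    seqs = []
    for i, length in enumerate(lengths):
        pairs = generate_random_sequences(1, [int(length)], seed=int(rng.integers(2**31)))
        seqs.append((f"synth_{i + 1:04d}", pairs[0][1]))

    fluct = fluct or default_fluctuations()
    straight = builtin_straight()
    baseline: dict[int, float] = {}
    for length in sorted(set(int(l) for l in lengths)):
        profile = equilibrium_profile("A" * length, straight)
        baseline[length] = estimate_j_halfchain(
            profile, fluct, cfg, parameter_set="straight", sequence_id=f"L{length}"
        ).j

    z = rng.standard_normal(n)
    records = []
    for (name, seq), zi in zip(seqs, z):
        base = baseline[len(seq)]
        records.append(
            BenchmarkRecord(
                sequence_id=name,
                sequence=seq,
                j_experimental=base * 10.0 ** (noise * zi),
                j_baseline=base,
            )
        )
    return records


def make_known_density_ensemble(
    n: int,
    box: float,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Terminal frames with uniform end density and isotropic orientations.

    Returns ``(origins, triads)``: ``n`` end origins uniform in the cube of
    side ``box`` centred on the start of the chain, and ``n`` Haar-random
    rotation triads.  Relative to the closure thresholds (r_c, c):
    ``E[n_r/n] = V_cap/box^3``, ``E[n_gamma/n_r] = (1 - c)/2`` and
    ``E[n_phi/n_gamma] = arccos(c)/pi``, so every closure factor — and the
    J normalization itself — has a closed form.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if box <= 0:
        raise ValueError("box must be positive")
    rng = np.random.default_rng(seed)
    origins = rng.uniform(-box / 2.0, box / 2.0, size=(n, 3))
    triads = special_ortho_group.rvs(3, size=n, random_state=rng)
    if n == 1:
        triads = triads.reshape(1, 3, 3)
    return origins, triads
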