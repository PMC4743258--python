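"""Closure counting, J-factor normalization and the two estimators."""

import math
from dataclasses import replace

import numpy as np
import pytest

from dnacyc.fixtures import make_known_density_ensemble
from dnacyc.geometry import ChainConfiguration, build_chain
from dnacyc.montecarlo import (
    ClosureCounts,
    JEstimate,
    SamplerConfig,
    _sampling_transform,
    count_closures,
    estimate_j_halfchain,
    estimate_j_naive,
    evaluate_closure,
    j_from_counts,
    sample_chain,
)
from dnacyc.params import (
    FluctuationModel,
    builtin_curved,
    builtin_straight,
    curved_sequence,
    equilibrium_profile,
)


def _two_frame_chain(offset, triad2):
    return ChainConfiguration(
        np.stack([np.zeros(3), np.asarray(offset, dtype=float)]),
        np.stack([np.eye(3), np.asarray(triad2, dtype=float)]),
    )


class TestEvaluateClosure:
    def test_r_miss_short_circuits(self):
        cfg = SamplerConfig()
        flags = evaluate_closure(_two_frame_chain([31.0, 0, 0], np.eye(3)), cfg)
        assert (flags.r_hit, flags.gamma_hit, flags.phi_hit) == (False, None, None)

    def test_perfect_closure(self):
        cfg = SamplerConfig()
        flags = evaluate_closure(_two_frame_chain([0, 0, 0], np.eye(3)), cfg)
        assert (flags.r_hit, flags.gamma_hit, flags.phi_hit) == (True, True, True)

    def test_gamma_miss_skips_phi(self):
        from dnacyc.geometry import _rot_y

        cfg = SamplerConfig()
        bent = _rot_y(math.acos(0.80))  # cos gamma = 0.80 < 0.86
        flags = evaluate_closure(_two_frame_chain([10.0, 0, 0], bent), cfg)
        assert (flags.r_hit, flags.gamma_hit, flags.phi_hit) == (True, False, None)


class TestClosureCounts:
    def test_monotone_nesting_enforced(self):
        with pytest.raises(ValueError):
            ClosureCounts(10, 5, 6, 0)
        with pytest.raises(ValueError):
            ClosureCounts(10, 5, 3, 4)

    def test_addition_pools_tallies(self):
        a = ClosureCounts(100, 10, 5, 2) + ClosureCounts(50, 5, 3, 1)
        assert a == ClosureCounts(150, 15, 8, 3)


class TestJFromCounts:
    def test_no_closures_returns_floor(self):
        cfg = SamplerConfig()
        assert j_from_counts(ClosureCounts(1000, 5, 2, 0), cfg) == 1e-15

    def test_doubling_total_halves_j(self):
        cfg = SamplerConfig()
        j1 = j_from_counts(ClosureCounts(1000, 100, 10, 4), cfg)
        j2 = j_from_counts(ClosureCounts(2000, 100, 10, 4), cfg)
        assert j2 == pytest.approx(j1 / 2, rel=1e-12)

    def test_uniform_density_closed_form(self):
        """An ensemble with perfectly uniform window occupancies must return
        the molar concentration of one end in the box: (1e27/N_A) / V_box."""
        cfg = SamplerConfig()
        v_cap = 4.0 / 3.0 * math.pi * 30.0**3
        box = 200.0**3
        n = 10**9
        n_r = round(n * v_cap / box)
        n_g = round(n_r * (1 - 0.86) / 2.0)
        n_p = round(n_g * math.acos(0.86) / math.pi)
        j = j_from_counts(ClosureCounts(n, n_r, n_g, n_p), cfg)
        from scipy.constants import Avogadro

        assert j == pytest.approx(1e27 / Avogadro / box, rel=2e-3)

    def test_requires_positive_total(self):
        with pytest.raises(ValueError):
            j_from_counts(ClosureCounts(0, 0, 0, 0), SamplerConfig())


class TestCountClosures:
    def test_matches_per_chain_evaluation(self):
        """Vectorized tallies against the scalar closure test, chain by chain
        (two independent code paths)."""
        cfg = SamplerConfig()
        origins, triads = make_known_density_ensemble(3000, box=120.0, seed=42)
        fast = count_closures(origins, triads, cfg)
        n_r = n_g = n_p = 0
        for o, t in zip(origins, triads):
            flags = evaluate_closure(_two_frame_chain(o, t), cfg)
            n_r += flags.r_hit
            n_g += bool(flags.gamma_hit)
            n_p += bool(flags.phi_hit)
        assert (fast.n_r, fast.n_gamma, fast.n_phi) == (n_r, n_g, n_p)

    def test_threshold_monotonicity(self):
        origins, triads = make_known_density_ensemble(20000, box=100.0, seed=7)
        base = count_closures(origins, triads, SamplerConfig())
        wider = count_closures(origins, triads, SamplerConfig(capture_radius=45.0))
        assert wider.n_r >= base.n_r
        stricter = count_closures(
            origins, triads, SamplerConfig(cos_gamma_min=0.95, cos_phi_min=0.95)
        )
        assert stricter.n_gamma <= base.n_gamma and stricter.n_phi <= base.n_phi


class TestSampleChain:
    def test_zero_sigmas_return_minimum_energy_chain(self, straight, rng):
        profile = equilibrium_profile("A" * 40, straight)
        frozen = FluctuationModel.from_sigmas(0, 0, 0)
        chain = sample_chain(profile, frozen, rng)
        ref = build_chain(profile)
        assert np.allclose(chain.origins, ref.origins, atol=1e-12)

    def test_per_step_models_accepted(self, straight, fluct, rng):
        profile = equilibrium_profile("A" * 10, straight)
        chain = sample_chain(profile, [fluct] * len(profile), rng)
        assert chain.n_bp == 10

    def test_sampled_deviations_recover_sigmas(self, fluct, rng):
        """Moment recovery: deviations drawn through the principal-axis
        transform have the prescribed per-coordinate RMS (3 SE at n=1e5)."""
        S = _sampling_transform(fluct)
        n = 100_000
        dev = rng.standard_normal((n, 6)) @ S.T
        sd = dev.std(axis=0)
        target = np.radians([4.84, 4.84, 4.09])
        se = target / math.sqrt(2 * n)
        assert np.all(np.abs(sd[:3] - target) < 3 * se)
        assert np.all(dev[:, 3:] == 0.0)
        assert np.abs(dev.mean(axis=0)[:3]).max() < 3 * target.max() / math.sqrt(n)


class TestEstimators:
    def test_naive_is_deterministic_under_seed(self, straight, fluct):
        profile = equilibrium_profile("A" * 30, straight)
        cfg = SamplerConfig(seed=9, batch_size=500, min_batches=2, max_chains=1000)
        a = estimate_j_naive(profile, fluct, cfg)
        b = estimate_j_naive(profile, fluct, cfg)
        assert a == b

    def test_halfchain_is_deterministic_under_seed(self, curved, fluct):
        profile = equilibrium_profile(curved_sequence(60), curved)
        cfg = SamplerConfig(seed=9, batch_size=128, min_batches=2, max_chains=2 * 128**2)
        a = estimate_j_halfchain(profile, fluct, cfg)
        b = estimate_j_halfchain(profile, fluct, cfg)
        assert a == b

    def test_budget_is_respected_and_floored_when_no_closures(self, straight, fluct):
        profile = equilibrium_profile("A" * 100, straight)
        cfg = SamplerConfig(seed=1, batch_size=200, min_batches=2, max_chains=400)
        est = estimate_j_naive(profile, fluct, cfg)
        assert est.counts.n_total == 400
        assert est.floored and est.j == cfg.floor_j
        assert math.isinf(est.rel_error)

    def test_grid_prefilter_is_exact(self, curved, fluct):
        """Grid-prefiltered and exhaustive pairings count identical closures
        for identical samples."""
        profile = equilibrium_profile(curved_sequence(150), curved)
        cfg = SamplerConfig(seed=4, batch_size=256, min_batches=2, max_chains=2 * 256**2)
        on = estimate_j_halfchain(profile, fluct, cfg, use_grid=True)
        off = estimate_j_halfchain(profile, fluct, cfg, use_grid=False)
        assert on.counts == off.counts

    def test_single_halfchain_pair_degenerates_to_one_chain(self, curved, fluct):
        profile = equilibrium_profile(curved_sequence(20), curved)
        cfg = SamplerConfig(seed=4, batch_size=1, min_batches=2, max_chains=2)
        est = estimate_j_halfchain(profile, fluct, cfg)
        assert est.counts.n_total == 2  # two batches of one pair each

    def test_halfchain_needs_four_bp(self, straight, fluct):
        with pytest.raises(ValueError):
            estimate_j_halfchain(
                equilibrium_profile("AC", straight), fluct, SamplerConfig()
            )

    def test_monotone_counts_invariant(self, curved, fluct):
        profile = equilibrium_profile(curved_sequence(100), curved)
        cfg = SamplerConfig(seed=2, batch_size=512, min_batches=2, max_chains=2 * 512**2)
        est = estimate_j_halfchain(profile, fluct, cfg)
        c = est.counts
        assert c.n_total >= c.n_r >= c.n_gamma >= c.n_phi >= 0


class TestJEstimate:
    def test_floored_estimates_must_have_no_closures(self):
        counts = ClosureCounts(10, 1, 1, 1)
        with pytest.raises(ValueError):
            JEstimate(j=1e-15, rel_error=1.0, counts=counts, floored=True)
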