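"""Ensemble (EOM-style) fitting against the conformer pool."""

import numpy as np
import pytest

from ncsaxs import (Solvent, asymmetric_fraction, chi2, classify_symmetry,
                    debye_profile, default_qgrid, select_ensemble)
from ncsaxs.ensemble import EnsembleFit
from ncsaxs.scatter import ScatteringProfile


@pytest.fixture(scope="module")
def pool_profiles(pool):
    q = default_qgrid(120)
    solvent = Solvent(sucrose=0.5, nacl=1.0)
    profs = []
    for c in pool:
        p = debye_profile(c, q, solvent, smear_sigma=1.5)
        p.sigma = np.zeros_like(p.I)
        profs.append(p)
    return profs


def noisy(profile, rel, rng):
    I = profile.I * (1 + rel * rng.standard_normal(len(profile.I)))
    return ScatteringProfile(profile.q, I, rel * profile.I,
                             meta=dict(profile.meta))


class TestChi2:
    def test_self_is_zero(self, pool_profiles):
        data = pool_profiles[0]
        ref = ScatteringProfile(data.q, data.I, 0.01 * data.I)
        assert chi2(data, ref) == pytest.approx(0.0, abs=1e-12)

    def test_scaled_model_fits_exactly(self, pool_profiles):
        data = pool_profiles[0]
        ref = ScatteringProfile(data.q, data.I, 0.01 * data.I)
        assert chi2(data.scaled(2.0), ref) == pytest.approx(0.0, abs=1e-9)
        assert chi2(data.scaled(2.0), ref, fit_scale=False) > 1.0

    def test_wrong_model_rejected_right_model_fits(self, pool, pool_profiles,
                                                   rng):
        names = [c.name for c in pool]
        j = names.index("released_L74_R0")
        w = names.index("released_L0_R0")
        data = noisy(pool_profiles[j], 0.01, rng)
        assert chi2(pool_profiles[j], data) < 2.0
        assert chi2(pool_profiles[w], data) > 10.0

    def test_disjoint_grids_rejected(self):
        a = ScatteringProfile([0.01, 0.02], [1, 1], [0.1, 0.1])
        b = ScatteringProfile([1.0, 2.0], [1, 1], [0.1, 0.1])
        with pytest.raises(ValueError):
            chi2(a, b)


class TestSelectEnsemble:
    def test_exact_member_recovered(self, pool, pool_profiles):
        k = 11
        data = ScatteringProfile(pool_profiles[k].q, pool_profiles[k].I,
                                 0.01 * pool_profiles[k].I)
        fit = select_ensemble(pool_profiles, data, max_members=4, pool=pool)
        assert fit.weights[k] == pytest.approx(1.0, abs=0.02)
        assert fit.chi2 < 0.1

    def test_mixture_weights_recovered(self, pool, pool_profiles, rng):
        # 50/50 mixture of two distinct members, 1% noise, 20 seeds:
        # recovered weights within +-10 percentage points
        names = [c.name for c in pool]
        a = names.index("released_L0_R0")
        b = names.index("released_L92_R0")
        bm = names.index("released_L0_R92")  # indistinguishable mirror
        mix = ScatteringProfile(
            pool_profiles[a].q,
            0.5 * pool_profiles[a].I + 0.5 * pool_profiles[b].I,
            np.zeros_like(pool_profiles[a].I))
        for _ in range(20):
            data = noisy(mix, 0.01, rng)
            fit = select_ensemble(pool_profiles, data, max_members=4,
                                  pool=pool)
            assert fit.weights[a] == pytest.approx(0.5, abs=0.10)
            assert fit.weights[b] + fit.weights[bm] == pytest.approx(
                0.5, abs=0.10)

    def test_ensemble_never_worse_than_single_member(self, pool_profiles,
                                                     rng):
        mix = ScatteringProfile(
            pool_profiles[2].q,
            0.6 * pool_profiles[2].I + 0.4 * pool_profiles[20].I,
            np.zeros_like(pool_profiles[2].I))
        data = noisy(mix, 0.01, rng)
        fit = select_ensemble(pool_profiles, data, max_members=6)
        singles = [chi2(p, data) for p in pool_profiles]
        assert fit.chi2 <= min(singles) + 1e-9

    def test_asymmetric_construction_yields_high_asym_fraction(
            self, pool, pool_profiles, rng):
        # mostly-asymmetric generating ensemble (the 1.0 M-like state)
        names = [c.name for c in pool]
        comp = [("released_L55_R0", 0.45), ("released_L74_R0", 0.35),
                ("released_L28_R28", 0.20)]
        I = sum(w * pool_profiles[names.index(n)].I for n, w in comp)
        data = noisy(ScatteringProfile(pool_profiles[0].q, I,
                                       np.zeros_like(I)), 0.01, rng)
        fit = select_ensemble(pool_profiles, data, max_members=6, pool=pool)
        assert fit.asym_fraction > 0.75

    def test_ga_solver_agrees_with_nnls(self, pool, pool_profiles, rng):
        # the seeded GA is approximate and the pool is highly
        # degenerate, so parity is judged on fit quality, not on
        # recovering the identical member set
        names = [c.name for c in pool]
        k = names.index("released_L0_R74")
        data = noisy(pool_profiles[k], 0.01, rng)
        nnls_fit = select_ensemble(pool_profiles, data, max_members=3)
        ga = select_ensemble(pool_profiles, data, max_members=3,
                             method="ga", seed=4)
        assert ga.chi2 < max(2.0, 3.0 * nnls_fit.chi2)

    def test_bad_max_members_rejected(self, pool_profiles):
        data = ScatteringProfile(pool_profiles[0].q, pool_profiles[0].I,
                                 0.01 * pool_profiles[0].I)
        with pytest.raises(ValueError):
            select_ensemble(pool_profiles, data, max_members=0)


class TestAsymmetricFraction:
    def test_all_weight_on_one_asymmetric_member(self, pool):
        ids = [c.name for c in pool]
        k = ids.index("released_L74_R0")
        w = np.zeros(len(pool))
        w[k] = 1.0
        fit = EnsembleFit(member_ids=ids, weights=w, chi2=0.0, scale=1.0)
        assert asymmetric_fraction(fit, pool) == 1.0

    def test_even_symmetric_asymmetric_split(self, pool):
        ids = [c.name for c in pool]
        w = np.zeros(len(pool))
        w[ids.index("released_L37_R37")] = 0.5
        w[ids.index("released_L74_R0")] = 0.5
        fit = EnsembleFit(member_ids=ids, weights=w, chi2=0.0, scale=1.0)
        assert asymmetric_fraction(fit, pool) == pytest.approx(0.5)

    def test_zero_weights_rejected(self, pool):
        ids = [c.name for c in pool]
        fit = EnsembleFit(member_ids=ids, weights=np.zeros(len(pool)),
                          chi2=0.0, scale=1.0)
        with pytest.raises(ValueError):
            asymmetric_fraction(fit, pool)

    def test_unknown_member_rejected(self, pool):
        w = np.zeros(3)
        w[0] = 1.0
        fit = EnsembleFit(member_ids=["nope", "a", "b"], weights=w,
                          chi2=0.0, scale=1.0)
        with pytest.raises(ValueError, match="unknown"):
            asymmetric_fraction(fit, pool)

    def test_mirror_degeneracy_is_warned(self, pool, pool_profiles, rng):
        # left/right mirror releases have identical profiles; fitting
        # their mixture must surface the identifiability caveat
        names = [c.name for c in pool]
        a = names.index("released_L74_R0")
        b = names.index("released_L0_R74")
        mix = ScatteringProfile(
            pool_profiles[a].q,
            0.5 * pool_profiles[a].I + 0.5 * pool_profiles[b].I,
            np.zeros_like(pool_profiles[a].I))
        data = noisy(mix, 0.01, rng)
        with pytest.warns(UserWarning, match="near-degenerate"):
            select_ensemble(pool_profiles, data, max_members=4, pool=pool,
                            degeneracy_noise=1.0)
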