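"""Chemical-shift perturbation profiling and PFG diffusion analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paibind.nmr import (
    GradientAttenuation,
    DiffusionResult,
    PeakList,
    classify_oligomer,
    fit_diffusion,
    select_active_residues,
    weighted_csp,
)
from paibind.synthetic import SimScenario, gen_gradient_series, gen_peaklists


def peaklist(rows):
    return PeakList(pd.DataFrame(rows, columns=["residue", "dH_ppm", "dN_ppm"]))


class TestWeightedCsp:
    def test_identical_lists_give_zero(self):
        a = peaklist([(1, 8.0, 120.0), (2, 7.5, 115.0), (3, 8.2, 118.0)])
        prof = weighted_csp(a, a)
        np.testing.assert_allclose(prof.delta, 0.0)

    @pytest.mark.parametrize("dh,dn,expect", [
        (0.1, 0.5, np.sqrt(0.01 + 0.15 * 0.25)),   # ~0.21794
        (0.0, 1.0, np.sqrt(0.15)),                 # ~0.38730
    ])
    def test_hand_evaluated_weighting(self, dh, dn, expect):
        free = peaklist([(1, 8.0, 120.0), (2, 8.0, 120.0)])
        bound = peaklist([(1, 8.0 + dh, 120.0 + dn), (2, 8.0, 120.0)])
        prof = weighted_csp(free, bound)
        assert prof.delta[0] == pytest.approx(expect, rel=1e-12)

    def test_sign_symmetry_and_referencing_invariance(self):
        free = peaklist([(1, 8.0, 120.0), (2, 7.0, 110.0)])
        up = peaklist([(1, 8.1, 120.5), (2, 7.0, 110.0)])
        down = peaklist([(1, 7.9, 119.5), (2, 7.0, 110.0)])
        assert weighted_csp(free, up).delta[0] == pytest.approx(
            weighted_csp(free, down).delta[0])
        # a global referencing offset applied to both lists cancels
        off = lambda pl, d: peaklist(
            [(r, h + d, n + d) for r, h, n in
             pl.table[["residue", "dH_ppm", "dN_ppm"]].itertuples(index=False)])
        a = weighted_csp(off(free, 0.3), off(up, 0.3))
        np.testing.assert_allclose(a.delta, weighted_csp(free, up).delta)

    def test_missing_residues_reported_not_zero(self):
        free = peaklist([(1, 8.0, 120.0), (2, 7.0, 110.0), (3, 8.5, 125.0)])
        bound = peaklist([(1, 8.0, 120.0), (3, 8.6, 125.0)])
        prof = weighted_csp(free, bound)
        assert prof.missing_in_bound == (2,)
        assert not np.isfinite(prof.delta[list(prof.residues).index(2)])

    def test_disjoint_lists_rejected(self):
        with pytest.raises(ValueError, match="no common"):
            weighted_csp(peaklist([(1, 8.0, 120.0)]),
                         peaklist([(2, 8.0, 120.0)]))


class TestActiveResidues:
    @staticmethod
    def planted_profile():
        interface = {r: (0.15, 0.8) for r in (10, 20, 30, 40, 50)}
        free, bound = gen_peaklists(SimScenario(
            "peaklists", {"interface": interface}, {"jitter_ppm": 0.003},
            seed=2))
        return weighted_csp(free, bound)

    def test_uniform_profile_selects_nothing(self):
        free, bound = gen_peaklists(SimScenario(
            "peaklists", {"interface": {}}, {"jitter_ppm": 0.0}, seed=1))
        prof = weighted_csp(free, bound)
        acc = {int(r): 1.0 for r in prof.residues}
        with pytest.warns(UserWarning):
            active = select_active_residues(prof, acc)
        assert active == set()

    def test_planted_exposed_residues_selected_exactly(self):
        prof = self.planted_profile()
        acc = {int(r): 1.0 for r in prof.residues}
        assert select_active_residues(prof, acc) == {10, 20, 30, 40, 50}

    def test_buried_high_csp_residue_excluded(self):
        prof = self.planted_profile()
        acc = {int(r): 1.0 for r in prof.residues}
        acc[30] = 0.2
        assert select_active_residues(prof, acc) == {10, 20, 40, 50}

    @settings(max_examples=20, deadline=None)
    @given(n_sd=st.floats(1.0, 4.0), min_acc=st.floats(0.1, 0.9))
    def test_selection_monotone_in_thresholds(self, n_sd, min_acc):
        prof = self.planted_profile()
        rng = np.random.default_rng(7)
        acc = {int(r): float(rng.random()) for r in prof.residues}
        base = select_active_residues(prof, acc, n_sd=1.0,
                                      min_accessibility=0.1)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tighter = select_active_residues(prof, acc, n_sd=n_sd,
                                             min_accessibility=min_acc)
        assert tighter <= base


class TestDiffusion:
    def test_noiseless_recovery_exact(self):
        att = gen_gradient_series(SimScenario(
            "gradient_series", {"d_m2_s": 1.86e-10}, {"sigma_frac": 0.0}, 0))
        res = fit_diffusion(att)
        assert res.d_m2_s == pytest.approx(1.86e-10, rel=1e-9)

    def test_nonlinear_matches_linearized_on_noiseless_data(self):
        att = gen_gradient_series(SimScenario(
            "gradient_series", {"d_m2_s": 1.5e-10}, {"sigma_frac": 0.0}, 0))
        res = fit_diffusion(att)
        assert res.d_m2_s == pytest.approx(res.d_linearized, rel=1e-9)

    def test_fitted_curve_passes_through_i0_at_zero_gradient(self):
        att = gen_gradient_series(SimScenario(
            "gradient_series", {"i0": 2.5}, {"sigma_frac": 0.0}, 0))
        res = fit_diffusion(att)
        assert res.i0 == pytest.approx(2.5, rel=1e-9)

    def test_weak_attenuation_flagged(self):
        with pytest.warns(UserWarning, match="not measurable"):
            att = gen_gradient_series(SimScenario(
                "gradient_series", {"d_m2_s": 1e-13}, {"sigma_frac": 0.0}, 0))
        res = fit_diffusion(att)
        assert "weak-attenuation" in res.flags


class TestOligomerCall:
    refs = dict(d_monomer=1.9e-10, d_dimer=1.3e-10)

    def make(self, d, se=0.05e-10):
        return DiffusionResult(d_m2_s=d, d_se=se, i0=1.0, d_linearized=d)

    def test_measured_value_calls_monomer(self):
        assert classify_oligomer(self.make(1.86e-10), **self.refs) == "monomer"

    def test_dimer_reference_calls_dimer(self):
        assert classify_oligomer(self.make(1.3e-10), **self.refs) == "dimer"

    def test_far_from_both_is_ambiguous(self):
        assert classify_oligomer(self.make(0.5e-10, se=1e-13),
                                 **self.refs) == "ambiguous"

    def test_equal_references_rejected(self):
        with pytest.raises(ValueError):
            classify_oligomer(self.make(1.5e-10), 1.5e-10, 1.5e-10)


class TestGradientAttenuationContract:
    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            GradientAttenuation(np.linspace(0.01, 0.5, 5), np.ones(5),
                                0.06, 0.004)

    def test_non_increasing_gradients_rejected(self):
        g = np.array([0.01, 0.02, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07])
        with pytest.raises(ValueError, match="strictly increasing"):
            GradientAttenuation(g, np.ones(8), 0.06, 0.004)
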