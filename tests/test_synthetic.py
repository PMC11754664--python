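"""Generators are pure functions of (parameters, seed) and reproduce the
statistical structure the downstream fits assume."""

import numpy as np
import pytest

from paibind.binding import hill
from paibind.cd_folding import ph_model
from paibind.nmr import weighted_csp
from paibind.structure import read_structure, write_structure
from paibind.synthetic import (
    SimScenario,
    gen_decay_set,
    gen_gradient_series,
    gen_peaklists,
    gen_ph_series,
    gen_titration,
    gen_toy_complex,
    simulate,
)


@pytest.mark.parametrize("kind,params", [
    ("titration", {"kd_nM": 25.3}),
    ("ph_series", {}),
    ("decay_set", {}),
    ("gradient_series", {}),
    ("peaklists", {"interface": {10: (0.1, 0.5)}}),
])
def test_generators_are_deterministic(kind, params):
    a = simulate(SimScenario(kind, params, {}, seed=1))
    b = simulate(SimScenario(kind, params, {}, seed=1))

    def flat(x):
        if isinstance(x, (list, tuple)):
            return np.concatenate([flat(y) for y in x])
        for attr in ("observable", "value", "counts", "intensity"):
            if hasattr(x, attr):
                return np.asarray(getattr(x, attr), float)
        return x.table[["dH_ppm", "dN_ppm"]].to_numpy().ravel()

    np.testing.assert_array_equal(flat(a), flat(b))


class TestTitration:
    def test_half_saturation_at_kd(self):
        ts = gen_titration(SimScenario(
            "titration", {"kd_nM": 10.0, "conc_min_nM": 0.1,
                          "conc_max_nM": 1000.0, "n_points": 41,
                          "baseline": 0.2, "amplitude": 0.8},
            {"sigma": 0.0, "replicates": 1}, seed=0))
        at_kd = np.interp(10.0, ts.conc_nM, ts.observable)
        assert at_kd == pytest.approx(0.2 + 0.8 / 2, abs=1e-9)

    def test_biphasic_replicate_mean_matches_model(self):
        """Law of large numbers: with 1e4 replicates the per-point mean sits
        within 3 SEM of the two-mode Hill curve."""
        kd1, kd2 = 20.0, 2000.0
        sc = SimScenario(
            "titration",
            {"kd_nM": [kd1, kd2], "amplitude": [0.5, 0.5],
             "conc_min_nM": 1.0, "conc_max_nM": 2e4, "n_points": 16},
            {"sigma": 0.02, "replicates": 10000}, seed=7)
        ts = gen_titration(sc)
        truth = 0.5 * hill(ts.conc_nM, kd1, 1.0) + 0.5 * hill(ts.conc_nM, kd2, 1.0)
        assert np.all(np.abs(ts.observable - truth) < 3 * ts.sem + 1e-12)

    def test_replicate_sem_scales_as_inverse_sqrt_n(self):
        sems = {}
        for n in (10, 1000):
            ts = gen_titration(SimScenario(
                "titration", {"kd_nM": 25.3},
                {"sigma": 0.02, "replicates": n}, seed=5))
            sems[n] = np.median(ts.sem)
        ratio = sems[10] / sems[1000]
        assert ratio == pytest.approx(np.sqrt(100), rel=0.25)

    def test_unresolvable_modes_warn(self):
        with pytest.warns(UserWarning, match="not resolvable"):
            gen_titration(SimScenario(
                "titration", {"kd_nM": [10.0, 30.0]}, {}, seed=0))


class TestPhSeries:
    def test_midpoint_and_plateau(self):
        sc = SimScenario("ph_series",
                         {"pka": 6.0, "f_acid": 0.1, "f_basic": 0.35,
                          "ph_min": 4.0, "ph_max": 12.0, "ph_step": 0.5},
                         {"sigma": 0.0}, seed=0)
        ps = gen_ph_series(sc)
        at_pka = ps.value[np.argmin(np.abs(ps.ph - 6.0))]
        assert at_pka == pytest.approx((0.1 + 0.35) / 2, abs=1e-12)
        assert ps.value[-1] == pytest.approx(0.35, abs=1e-4)  # high-pH plateau

    def test_degenerate_hill_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gen_ph_series(SimScenario("ph_series", {"hill_n": 0.0}, {}, 0))


class TestDecaySet:
    def test_delta_irf_gives_pure_biexponential(self):
        wfs = gen_decay_set(SimScenario(
            "decay_set",
            {"irf": "delta", "amplitudes": [(100.0, 50.0)], "tau1_ns": 1.0,
             "tau2_ns": 4.0, "peak_counts": None},
            {"poisson": False}, seed=0))
        w = wfs[0]
        expect = 100.0 * np.exp(-w.t_ns) + 50.0 * np.exp(-w.t_ns / 4.0)
        np.testing.assert_allclose(w.counts, expect, rtol=1e-12)

    def test_total_counts_match_integral(self):
        """Total counts ~ (A1 tau1 + A2 tau2)/dt within Poisson error."""
        a1, a2, t1, t2, dt = 200.0, 100.0, 1.0, 4.0, 0.05
        wfs = gen_decay_set(SimScenario(
            "decay_set",
            {"irf": "delta", "amplitudes": [(a1, a2)], "tau1_ns": t1,
             "tau2_ns": t2, "dt_ns": dt, "peak_counts": None}, {}, seed=2))
        total = wfs[0].counts.sum()
        expect = (a1 * t1 + a2 * t2) / dt
        assert abs(total - expect) < 4 * np.sqrt(expect) + 0.01 * expect

    def test_undersampled_grid_warns(self):
        with pytest.warns(UserWarning, match="undersampled"):
            gen_decay_set(SimScenario(
                "decay_set", {"tau1_ns": 0.1, "dt_ns": 0.05}, {}, 0))


class TestGradientSeries:
    def test_zero_gradient_limit_is_i0(self):
        att = gen_gradient_series(SimScenario(
            "gradient_series", {"g_frac_min": 1e-6, "i0": 3.0},
            {"sigma_frac": 0.0}, seed=0))
        assert att.intensity[0] == pytest.approx(3.0, rel=1e-6)

    def test_halving_d_halves_log_slope(self):
        def slope(d):
            att = gen_gradient_series(SimScenario(
                "gradient_series", {"d_m2_s": d}, {"sigma_frac": 0.0}, 0))
            return np.polyfit(att.g_T_m**2, np.log(att.intensity), 1)[0]
        assert slope(0.93e-10) == pytest.approx(slope(1.86e-10) / 2, rel=1e-9)

    def test_acquisition_constants_recorded(self):
        att = gen_gradient_series(SimScenario("gradient_series", {}, {}, 0))
        assert att.little_delta_s == 0.004 and att.big_delta_s == 0.060
        assert att.g_T_m.size == 32


class TestPeakLists:
    def test_zero_perturbation_gives_zero_profile(self):
        free, bound = gen_peaklists(SimScenario(
            "peaklists", {"interface": {}}, {"jitter_ppm": 0.0}, seed=0))
        prof = weighted_csp(free, bound)
        np.testing.assert_allclose(prof.delta, 0.0, atol=1e-15)

    def test_planted_interface_exceeds_two_sd(self):
        interface = {r: (0.1, 0.5) for r in (10, 11, 12, 40, 41)}
        free, bound = gen_peaklists(SimScenario(
            "peaklists", {"interface": interface},
            {"jitter_ppm": 0.003}, seed=1))
        prof = weighted_csp(free, bound)
        thr = prof.threshold(2.0)
        above = {int(r) for r, d in zip(prof.residues, prof.delta)
                 if np.isfinite(d) and d > thr}
        assert set(interface) <= above

    def test_dropped_peaks_are_missing_not_zero(self):
        free, bound = gen_peaklists(SimScenario(
            "peaklists", {"drop_probability": 0.3}, {}, seed=4))
        prof = weighted_csp(free, bound)
        assert len(prof.missing_in_bound) > 0
        for r in prof.missing_in_bound:
            k = np.where(prof.residues == r)[0][0]
            assert not np.isfinite(prof.delta[k])

    def test_duplicate_residues_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            gen_peaklists(SimScenario(
                "peaklists", {"residues": [1, 2, 2]}, {}, 0))


class TestToyComplex:
    def test_base_pair_span_matches_fiber_rise(self):
        m = gen_toy_complex(SimScenario(
            "toy_complex", {"sequence": "ACGTACGTAC"}, {}, 0))

        def bp_center(k, n=10):
            a = [i for i in range(m.n_atoms)
                 if m.chain[i] == "B" and m.resnum[i] == k + 1
                 and m.name[i] != "C1'"]
            b = [i for i in range(m.n_atoms)
                 if m.chain[i] == "C" and m.resnum[i] == n - k
                 and m.name[i] != "C1'"]
            return (m.coords[a].mean(0) + m.coords[b].mean(0)) / 2

        span = np.linalg.norm(bp_center(9) - bp_center(0))
        assert span == pytest.approx(9 * 3.38, abs=1e-9)

    def test_strands_are_reverse_complementary(self):
        m = gen_toy_complex(SimScenario(
            "toy_complex", {"sequence": "AACGTTGCAT"}, {}, 0))
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        fwd = m.sequence("B")
        rev = m.sequence("C")
        assert rev == "".join(comp[b] for b in reversed(fwd))

    def test_pdb_round_trip_preserves_coordinates(self, toy_complex):
        m2 = read_structure(write_structure(toy_complex))
        assert np.abs(m2.coords - toy_complex.coords).max() <= 1e-3

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="A, C, G, T"):
            gen_toy_complex(SimScenario("toy_complex", {"sequence": "ACGU"}, {}, 0))
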