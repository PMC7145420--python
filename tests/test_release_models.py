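"""Release-model kinetics: rates, steady states, both simulation engines."""

import numpy as np
import pytest
from scipy import stats

from synapstp.calcium import basal_calcium, constant_field
from synapstp.release_models import (
    ModelSpec,
    integrate_deterministic,
    reaction_rates,
    simulate_stochastic,
    steady_state,
    unpriming_factor,
)


class TestModelSpec:
    def test_fusion_factor_identity(self):
        spec = ModelSpec.single_sensor()
        assert spec.f**5 * spec.l_plus == pytest.approx(spec.k_f, rel=1e-9)
        assert spec.f == pytest.approx(27.978, abs=1e-3)

    def test_neutral_extras_enforced(self):
        spec = ModelSpec(kind="single_sensor", k2=1e7, s=100.0, u=50.0)
        assert spec.k2 == 0.0 and spec.s == 1.0 and spec.u == 0.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(kind="quad_sensor")

    def test_json_roundtrip(self, tmp_path):
        spec = ModelSpec.unpriming()
        spec.to_json(tmp_path / "spec.json")
        back = ModelSpec.from_json(tmp_path / "spec.json")
        assert back == spec

    def test_yaml_roundtrip(self, tmp_path):
        spec = ModelSpec.dual_sensor()
        spec.to_yaml(tmp_path / "spec.yaml")
        assert ModelSpec.from_yaml(tmp_path / "spec.yaml") == spec


class TestReactionRates:
    def test_fully_bound_fast_sensor_fuses_at_kf(self):
        spec = ModelSpec.single_sensor()
        r = reaction_rates((1, 5, 0, 0), 10.0, spec)
        assert r["fusion"] == pytest.approx(6000.0, rel=1e-9)

    def test_resting_state_only_basal_leak(self):
        spec = ModelSpec.single_sensor()
        r = reaction_rates((1, 0, 0, 0), 0.0, spec)
        nonzero = {k: v for k, v in r.items() if v != 0}
        assert nonzero == {"fusion": pytest.approx(3.5e-4)}

    def test_unpriming_factor_half_at_km(self):
        spec = ModelSpec.unpriming()
        assert unpriming_factor(spec.k_m_prim * 1e-3, spec) == pytest.approx(0.5)

    def test_empty_site_replenishes(self):
        spec = ModelSpec.single_sensor()
        r = reaction_rates((0, 0, 0, 0), 5.0, spec)
        assert r["replenish"] == pytest.approx(spec.k_rep)
        assert r["fusion"] == 0.0

    def test_invalid_state_code(self):
        with pytest.raises(ValueError):
            reaction_rates((1, 7, 0, 0), 1.0, ModelSpec.single_sensor())


class TestSteadyState:
    def test_zero_calcium_single_sensor_all_unbound(self):
        dist = steady_state(ModelSpec.single_sensor(), 0.0)
        assert dist.occupied[0, 0] == pytest.approx(1.0)
        assert dist.occupancy == pytest.approx(1.0)

    def test_unpriming_occupancies_at_experimental_calcium(self):
        spec = ModelSpec.unpriming()
        occ_low = steady_state(spec, basal_calcium(0.75) / 1000).occupancy
        occ_high = steady_state(spec, basal_calcium(10.0) / 1000).occupancy
        assert occ_low == pytest.approx(0.41, abs=0.015)
        assert occ_high == pytest.approx(0.99, abs=0.005)

    def test_unpriming_occupancy_monotone_in_calcium(self):
        spec = ModelSpec.unpriming()
        occ = [steady_state(spec, ca).occupancy
               for ca in (0.01, 0.04, 0.08, 0.15)]
        assert np.all(np.diff(occ) > 0)

    def test_site_activation_gate_fraction_monotone_in_calcium(self):
        spec = ModelSpec.site_activation()
        frac_a = [steady_state(spec, ca).gate[0]
                  for ca in (0.01, 0.04, 0.08, 0.15)]
        assert np.all(np.diff(frac_a) > 0)

    def test_formula_matches_long_run_integration(self):
        """Closed-form equilibrium equals the ODE long-run limit at constant
        Ca2+ (basal fusion leak suppressed, as the formula assumes)."""
        spec = ModelSpec(kind="unpriming", u=236.82, k_m_prim=55.21,
                         k_rep=134.85, l_plus=1e-12, n_sites=1)
        ca = 0.2
        det = integrate_deterministic(spec, np.array([100.0]),
                                      constant_field(ca, 400.0),
                                      t_span=(0, 400.0), dt=0.05, n_sites=1)
        ss = steady_state(spec, ca)
        assert abs(det.occupancy[-1] - ss.occupancy) / ss.occupancy < 1e-6


class TestDeterministicEngine:
    def test_basal_leak_fusion_at_zero_calcium(self):
        spec = ModelSpec.single_sensor(n_sites=100)
        det = integrate_deterministic(spec, np.array([100.0]),
                                      constant_field(0.0, 20.0),
                                      t_span=(0, 20.0), dt=0.01, n_sites=100)
        expected = 100 * 3.5e-4 * 0.02  # n_sites * L+ * t
        assert det.cum_fusion[-1] == pytest.approx(expected, rel=1e-3)

    def test_cumulative_fusion_non_decreasing(self, toy_field):
        spec = ModelSpec.single_sensor(n_sites=30)
        det = integrate_deterministic(spec, np.linspace(40, 400, 24),
                                      toy_field, t_span=(0, 22.0), dt=0.005,
                                      n_sites=30)
        assert np.all(np.diff(det.cum_fusion) >= -1e-12)

    def test_probability_conserved_per_bin(self, toy_field):
        spec = ModelSpec.dual_sensor(n_sites=30)
        bins = np.linspace(40, 400, 12)
        det = integrate_deterministic(spec, bins, toy_field,
                                      t_span=(0, 22.0), dt=0.005, n_sites=30,
                                      keep_per_bin=True)
        # occupancy + empties always sum to 1; fused mass re-enters as empty
        assert np.all(det.occupancy <= 1.0 + 1e-8)
        assert det.occupancy[0] == pytest.approx(1.0, abs=1e-9)

    def test_dual_sensor_with_neutral_extras_equals_single(self, toy_field):
        bins = np.linspace(50, 400, 20)
        common = dict(k_rep=165.53, n_sites=20)
        d1 = integrate_deterministic(
            ModelSpec(kind="single_sensor", **common), bins, toy_field,
            (0, 22.0), dt=0.01, n_sites=20)
        d2 = integrate_deterministic(
            ModelSpec(kind="dual_sensor", k2=0.0, s=1.0, **common), bins,
            toy_field, (0, 22.0), dt=0.01, n_sites=20)
        assert np.allclose(d1.cum_fusion, d2.cum_fusion, rtol=1e-12, atol=1e-14)


class TestStochasticEngine:
    def test_single_rate_fusion_times_are_exponential(self):
        """Ca = 0, no replenishment, one site: fusion is a single-rate
        process, so fusion times are Exponential(L+)."""
        spec = ModelSpec(kind="single_sensor", l_plus=100.0, k_rep=0.0,
                         n_sites=1)
        rec = simulate_stochastic(spec, np.full((3000, 1), 100.0),
                                  constant_field(0.0, 100.0),
                                  t_span=(0, 100.0), seed=7)
        times = np.array([ft[0] for ft in rec.fusion_times if len(ft)])
        assert len(times) == 3000  # horizon = 10 mean lifetimes
        res = stats.kstest(times, "expon", args=(0, 1000.0 / 100.0))
        assert res.pvalue > 0.01

    def test_reproducible_and_order_independent(self, toy_field):
        spec = ModelSpec.single_sensor(n_sites=25)
        d = np.tile(np.linspace(60, 350, 25), (4, 1))
        r1 = simulate_stochastic(spec, d, toy_field, (0, 22.0), seed=5)
        r2 = simulate_stochastic(spec, d, toy_field, (0, 22.0), seed=5)
        for a, b in zip(r1.fusion_times, r2.fusion_times):
            assert np.array_equal(a, b)
        # distinct per-repetition substreams: identical site layouts still
        # give different event sequences across repetitions
        assert not np.array_equal(r1.fusion_times[0], r1.fusion_times[1])

    def test_mean_cumulative_fusion_matches_deterministic(self, toy_field):
        """Stochastic mean fusion converges on the deterministic solution
        (checked at 3 SEM for two model kinds on a shared toy transient)."""
        for spec in (ModelSpec.single_sensor(n_sites=40),
                     ModelSpec.unpriming(n_sites=40)):
            d = np.linspace(50, 450, 40)
            det = integrate_deterministic(spec, d, toy_field, (0, 22.0),
                                          dt=0.005, n_sites=40)
            rec = simulate_stochastic(spec, np.tile(d, (150, 1)), toy_field,
                                      (0, 22.0), seed=13)
            counts = np.array([len(ft) for ft in rec.fusion_times])
            sem = counts.std(ddof=1) / np.sqrt(len(counts))
            assert abs(counts.mean() - det.cum_fusion[-1]) < 3 * sem + 0.05

    def test_master_equation_oracle_two_sites(self):
        """SSA state frequencies at t = 5 ms match the dense matrix-
        exponential solution of the master equation for a 2-site toy model
        (n_max = 1, constant Ca2+)."""
        from scipy.linalg import expm

        spec = ModelSpec(kind="single_sensor", n_max=1, l_plus=60.0,
                         k_f=600.0, k_rep=100.0, n_sites=2)
        ca = 1.0
        # per-site generator over (empty, R0, R1); columns are sources
        k1u = spec.k1 * 1e-9
        km1 = spec.k_minus1 * 1e-3
        lp = spec.l_plus * 1e-3
        krep = spec.k_rep * 1e-3
        q = np.zeros((3, 3))
        q[1, 0] = krep
        q[0, 0] -= krep
        q[2, 1] = ca * k1u
        q[1, 1] -= ca * k1u
        q[1, 2] = km1
        q[2, 2] -= km1
        q[0, 1] += lp
        q[1, 1] -= lp
        q[0, 2] += lp * spec.f
        q[2, 2] -= lp * spec.f
        ss = steady_state(spec, ca)
        p0 = np.array([0.0, ss.occupied[0, 0], ss.occupied[1, 0]])
        p_t = expm(q * 5.0) @ p0
        rec = simulate_stochastic(spec, np.full((500, 2), 100.0),
                                  constant_field(ca, 5.0), (0, 5.0), seed=11)
        counts = np.zeros(3)
        for occ, nn, mm, gate in rec.final_states:
            for k in range(2):
                if occ[k] == 0:
                    counts[0] += 1
                elif nn[k] == 0:
                    counts[1] += 1
                else:
                    counts[2] += 1
        phat = counts / counts.sum()
        se = np.sqrt(p_t * (1 - p_t) / counts.sum())
        assert np.all(np.abs(phat - p_t) < 3 * se + 1e-9)

    def test_fusion_record_csv_export(self, toy_field, tmp_path):
        import pandas as pd

        spec = ModelSpec.single_sensor(n_sites=10)
        rec = simulate_stochastic(spec, np.tile(np.linspace(60, 200, 10), (3, 1)),
                                  toy_field, (0, 22.0), seed=2)
        rec.to_csv(tmp_path / "fusions.csv")
        df = pd.read_csv(tmp_path / "fusions.csv")
        assert set(df.columns) == {"rep", "t_ms"}
        assert len(df) == sum(len(ft) for ft in rec.fusion_times)

    def test_distance_outside_cylinder_rejected(self, toy_field):
        spec = ModelSpec.single_sensor(n_sites=2)
        with pytest.raises(ValueError):
            simulate_stochastic(spec, np.array([[100.0, 9999.0]]), toy_field,
                                (0, 22.0), seed=1)
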