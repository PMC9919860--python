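"""BAR estimation, window chaining, thermodynamic cycle and experiment
correlation, including the published transformation table arithmetic."""

import numpy as np
import pytest

import qsarfep as q
from qsarfep.errors import InsufficientOverlapError, ParameterError
from qsarfep.rbfe import (
    AffinityRecord,
    LambdaSchedule,
    WorkSampleSet,
    bar_pair,
    chain_windows,
    correlate,
    cycle_ddg,
    ddg_exp,
    pic50_to_dg,
    protocol_total_ns,
    read_work_samples,
    write_work_samples,
)


class TestBarPair:
    def test_symmetric_samples_give_zero(self):
        w = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        res = bar_pair(w, -w)  # mirror-symmetric bidirectional sampling
        assert res.delta_g == pytest.approx(0.0, abs=1e-10)

    def test_antisymmetry_exact(self, rng):
        fwd = rng.normal(1.5, 1.0, 400)
        rev = rng.normal(-0.5, 1.0, 300)
        a = bar_pair(fwd, rev)
        b = bar_pair(rev, fwd)
        assert b.delta_g == pytest.approx(-a.delta_g, abs=1e-9)
        assert b.stderr == pytest.approx(a.stderr, rel=1e-6)

    def test_recovers_planted_gaussian_dg(self):
        ws = q.generate_work_samples(q.SyntheticWorkSpec(
            delta_g_true=1.0, work_sd=1.0, n_samples=5000, n_windows=2,
            n_replicates=1, seed=21))
        fwd, rev = ws.data[(0, 0)]
        res = bar_pair(fwd, rev)
        assert abs(res.delta_g - 1.0) < 3 * res.stderr

    def test_solution_outside_bracket_raises(self):
        # consistent but enormous free energy difference (~500 kcal/mol):
        # the root lies outside the +/-100 kcal/mol search window
        with pytest.raises(InsufficientOverlapError):
            bar_pair(np.full(10, 500.0), np.full(10, -500.0))

    def test_empty_samples_rejected(self):
        with pytest.raises(ParameterError):
            bar_pair(np.array([]), np.array([1.0]))


class TestChainWindows:
    def test_all_zero_pairs_total_zero(self):
        w = np.array([-1.0, -0.3, 0.3, 1.0])
        data = {(p, 0): (w, -w) for p in range(11)}
        ws = WorkSampleSet(data=data)
        res = chain_windows(ws, LambdaSchedule.uniform(12))
        assert res.mean == pytest.approx(0.0, abs=1e-9)

    def test_planted_total_within_three_stderr(self):
        ws = q.generate_work_samples(q.SyntheticWorkSpec(
            delta_g_true=0.5, work_sd=1.0, n_samples=5000, n_windows=12,
            n_replicates=3, seed=7))
        res = chain_windows(ws, LambdaSchedule.uniform(12))
        assert abs(res.mean - 5.5) < 3 * res.stderr
        assert res.per_replicate.shape == (3,)

    def test_reversed_cycle_sums_to_zero_exactly(self):
        """Chaining A->B and then B->A on the role-swapped samples closes the
        cycle identically (BAR antisymmetry, pair by pair)."""
        ws = q.generate_work_samples(q.SyntheticWorkSpec(
            delta_g_true=0.4, work_sd=1.5, n_samples=500, n_windows=6,
            n_replicates=1, seed=3))
        swapped = WorkSampleSet(
            data={k: (r, f) for k, (f, r) in ws.data.items()},
            temperature=ws.temperature)
        sched = LambdaSchedule.uniform(6)
        forward = chain_windows(ws, sched).mean
        backward = chain_windows(swapped, sched).mean
        assert forward + backward == pytest.approx(0.0, abs=1e-8)

    def test_missing_pair_names_lambda_window(self):
        ws = q.generate_work_samples(q.SyntheticWorkSpec(
            n_samples=10, n_windows=3, n_replicates=1, seed=0))
        del ws.data[(1, 0)]
        with pytest.raises(ParameterError, match="0.500, 1.000"):
            chain_windows(ws, LambdaSchedule.uniform(3))

    def test_replicate_sd_grows_with_work_noise(self):
        sds = []
        for sd in (0.5, 3.0):
            ws = q.generate_work_samples(q.SyntheticWorkSpec(
                delta_g_true=0.5, work_sd=sd, n_samples=200, n_windows=12,
                n_replicates=3, seed=11))
            sds.append(chain_windows(ws, LambdaSchedule.uniform(12)).sd)
        assert 0.0 < sds[0] < sds[1] < 5.0


class TestSchedule:
    def test_uniform_twelve(self):
        s = LambdaSchedule.uniform(12)
        assert s.n_windows == 12 and s.n_pairs == 11
        assert s.values[0] == 0.0 and s.values[-1] == 1.0

    @pytest.mark.parametrize("vals", [[0.0, 0.5], [0.1, 1.0], [0.0, 0.6, 0.5, 1.0], [0.0]])
    def test_invalid_schedules_rejected(self, vals):
        with pytest.raises(ParameterError):
            LambdaSchedule(np.asarray(vals))


class TestCycleAndExperiment:
    @pytest.mark.parametrize(
        "com, lig, expected",
        [((-19.51, 0.87), (-22.45, 0.99), 2.94),   # C36 -> C28
         ((-19.44, 1.02), (-25.01, 0.26), 5.57),   # C70 -> C45
         ((-49.62, 1.06), (-46.76, 3.29), -2.86)], # C70 -> C114
    )
    def test_published_cycle_rows(self, com, lig, expected):
        res = cycle_ddg(com, lig)
        assert res.ddg_rbfe == pytest.approx(expected, abs=1e-9)
        assert res.ddg_sd == pytest.approx(np.hypot(com[1], lig[1]))

    def test_equal_legs_cancel(self):
        assert cycle_ddg((-20.0, 0.1), (-20.0, 0.1)).ddg_rbfe == 0.0

    def test_published_experimental_differences(self):
        c36 = AffinityRecord("C36", 8.254, -11.33)
        c80 = AffinityRecord("C80", 10.221, -14.03)
        c28 = AffinityRecord("C28", 7.205, -9.89)
        assert ddg_exp(c36, c80) == pytest.approx(-2.70, abs=1e-9)
        assert ddg_exp(c36, c28) == pytest.approx(1.44, abs=1e-9)
        assert ddg_exp(c36, c36) == 0.0

    def test_pic50_conversion_round_trip(self):
        assert pic50_to_dg(0.0) == 0.0
        for v in (5.0, 8.254, 10.0):
            assert q.dg_to_pic50(pic50_to_dg(v)) == pytest.approx(v, abs=1e-10)

    def test_c36_conversion_matches_tabulated(self):
        # RT ln10 = 1.3726 kcal/mol at 300 K
        assert pic50_to_dg(8.254, 300.0) == pytest.approx(-11.33, abs=0.005)

    def test_protocol_arithmetic(self):
        assert protocol_total_ns(12, 1.0, 3, 2) == 72.0


class TestCorrelate:
    def test_identity_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, r2, slope, intercept = correlate(x, x)
        assert (r, r2, slope, intercept) == (
            pytest.approx(1.0), pytest.approx(1.0), pytest.approx(1.0), pytest.approx(0.0))

    def test_negative_line_with_offset(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        r, r2, slope, intercept = correlate(-x + 5.0, x)
        assert r == pytest.approx(-1.0)
        assert slope == pytest.approx(-1.0) and intercept == pytest.approx(5.0)

    def test_matches_normal_equations(self, rng):
        x = rng.normal(0, 2, 4)
        y = 0.7 * x + rng.normal(0, 0.5, 4)
        r, r2, slope, intercept = correlate(y, x)
        # closed-form normal equations as the oracle
        n = 4.0
        sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
        slope_exp = (n * sxy - sx * sy) / (n * sxx - sx**2)
        intercept_exp = (sy - slope_exp * sx) / n
        r_exp = (n * sxy - sx * sy) / np.sqrt(
            (n * sxx - sx**2) * (n * (y * y).sum() - sy**2))
        assert slope == pytest.approx(slope_exp, abs=1e-12)
        assert intercept == pytest.approx(intercept_exp, abs=1e-12)
        assert r == pytest.approx(r_exp, abs=1e-12)

    def test_pairing_preserved_under_reordering(self, rng):
        x = rng.normal(0, 1, 6)
        y = x + rng.normal(0, 0.2, 6)
        perm = rng.permutation(6)
        assert correlate(y, x) == pytest.approx(correlate(y[perm], x[perm]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestWorkCsv:
    def test_round_trip(self, tmp_path):
        ws = q.generate_work_samples(q.SyntheticWorkSpec(
            n_samples=20, n_windows=3, n_replicates=2, seed=5), system="ligand")
        path = tmp_path / "work.csv"
        write_work_samples(ws, path)
        back = read_work_samples(path)["ligand"]
        assert back.pairs == ws.pairs and back.replicates == ws.replicates
        for key in ws.data:
            np.testing.assert_allclose(back.data[key][0], ws.data[key][0], atol=1e-9)
            np.testing.assert_allclose(back.data[key][1], ws.data[key][1], atol=1e-9)
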