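import numpy as np
import pandas as pd
import pytest

from connkit import (
    circ_corr_cc,
    circ_corr_cl,
    compare_groups,
    consensus,
    correlate_metrics,
    gen_redundant_metric_table,
    mixed_anova_sidak,
)


class TestCircularCorrelations:
    def test_shifted_angles_perfectly_correlated(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 360, 40)
        rho, p = circ_corr_cc(a, (a + 40.0) % 360)
        assert rho > 0.999
        assert p < 1e-6

    def test_rotation_invariance(self):
        rng = np.random.default_rng(4)
        a = np.degrees(rng.vonmises(0, 1.5, 60)) % 360
        b = np.degrees(rng.vonmises(1.0, 1.5, 60)) % 360
        rho0, _ = circ_corr_cc(a, b)
        rho1, _ = circ_corr_cc((a + 123.0) % 360, (b + 300.0) % 360)
        assert np.isclose(rho0, rho1, atol=1e-10)

    def test_matches_pingouin_cc(self):
        import pingouin as pg

        rng = np.random.default_rng(5)
        a = rng.uniform(0, 360, 30)
        b = (a + np.degrees(rng.vonmises(0, 3.0, 30))) % 360
        rho, _ = circ_corr_cc(a, b)
        ref = pg.circ_corrcc(np.deg2rad(a), np.deg2rad(b))[0]
        assert np.isclose(rho, ref, atol=1e-10)

    def test_matches_pingouin_cl(self):
        import pingouin as pg

        rng = np.random.default_rng(6)
        a = rng.uniform(0, 360, 30)
        x = np.cos(np.deg2rad(a)) + 0.3 * rng.standard_normal(30)
        rho, _ = circ_corr_cl(a, x)
        ref = pg.circ_corrcl(np.deg2rad(a), x)[0]
        assert np.isclose(rho, ref, atol=1e-10)


class TestCorrelateMetrics:
    def test_monotone_transform_rho_one(self):
        x = np.linspace(0.1, 5.0, 20)
        table = pd.DataFrame({"m1": x, "m2": np.exp(x)})
        cells = correlate_metrics(table)
        assert np.isclose(cells[0].rho, 1.0)

    def test_method_dispatch(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(
            {
                "lin1": rng.standard_normal(20),
                "lin2": rng.standard_normal(20),
                "ang1": rng.uniform(0, 360, 20),
                "ang2": rng.uniform(0, 360, 20),
            }
        )
        cells = correlate_metrics(table, circular_cols={"ang1", "ang2"})
        methods = {(c.metric_a, c.metric_b): c.method for c in cells}
        assert methods[("lin1", "lin2")] == "spearman"
        assert methods[("ang1", "ang2")] == "circ_circ"
        assert methods[("lin1", "ang1")] == "circ_lin"

    def test_constant_column_missing_rho(self):
        table = pd.DataFrame({"m1": np.ones(10), "m2": np.arange(10.0)})
        cells = correlate_metrics(table)
        assert cells[0].method == "constant"
        assert np.isnan(cells[0].rho)

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        r1 = correlate_metrics(pd.DataFrame({"a": x, "b": y}))[0].rho
        r2 = correlate_metrics(pd.DataFrame({"a": np.exp(x), "b": y**3}))[0].rho
        assert np.isclose(r1, r2, atol=1e-12)


class TestConsensus:
    def _cells(self, ps, rhos=(0.8, 0.8, 0.8)):
        out = {}
        for i, conn in enumerate(["c1", "c2", "c3"]):
            tab = pd.DataFrame({"m1": np.arange(10.0), "m2": np.arange(10.0)})
            cells = correlate_metrics(tab, connection=conn)
            cells[0].p = ps[i]
            cells[0].rho = rhos[i]
            out[conn] = cells
        return out

    def test_all_significant_flags_true(self):
        df = consensus(self._cells([0.001, 0.005, 0.0001]))
        assert bool(df["all_significant_0.01"].iloc[0])

    def test_two_of_three_not_flagged(self):
        df = consensus(self._cells([0.001, 0.5, 0.0001]))
        assert not bool(df["all_significant_0.01"].iloc[0])
        assert np.isclose(df["mean_rho"].iloc[0], 0.8)

    def test_alpha_monotonicity(self):
        df = consensus(self._cells([0.005, 0.005, 0.005]))
        assert bool(df["all_significant_0.01"].iloc[0])
        assert not bool(df["all_significant_0.001"].iloc[0])

    def test_planted_redundancy_detected(self):
        tables = gen_redundant_metric_table(n_subjects=27, seed=1)
        cells = {c: correlate_metrics(t, connection=c) for c, t in tables.items()}
        df = consensus(cells).set_index(["metric_a", "metric_b"])
        assert bool(df.loc[("m1", "m2"), "all_significant_0.01"])
        assert not bool(df.loc[("m1", "m3"), "all_significant_0.01"])
        assert not bool(df.loc[("m2", "m3"), "all_significant_0.01"])


class TestCompareGroups:
    def test_identical_groups_high_p(self):
        a = np.arange(10.0)
        res = compare_groups(a, a, kind="linear")
        assert res["p"] > 0.99

    def test_large_effect_detected(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal(12)
        b = rng.standard_normal(15) + 1.5
        assert compare_groups(a, b, kind="linear")["p"] < 0.01

    def test_circular_dispatch(self):
        rng = np.random.default_rng(10)
        a = np.degrees(rng.vonmises(0, 3, 15)) % 360
        b = np.degrees(rng.vonmises(np.pi, 3, 15)) % 360
        res = compare_groups(a, b, kind="circular")
        assert res["test"] == "watson_williams"
        assert res["p"] < 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_groups([1.0], [1.0, 2.0])


class TestMixedAnovaSidak:
    def test_planted_group_effect(self):
        rng = np.random.default_rng(11)
        rows = []
        for s in range(24):
            group = "KO" if s < 12 else "WT"
            base = rng.standard_normal() * 0.3 + (1.0 if group == "KO" else 0.0)
            for direction in ("fwd", "rev"):
                rows.append(
                    {"subject": s, "group": group, "direction": direction,
                     "gc": base + 0.1 * rng.standard_normal()}
                )
        res = mixed_anova_sidak(pd.DataFrame(rows), dv="gc", within="direction",
                                between="group", subject="subject")
        assert res["p_group"] < 0.01
        assert all(c["p_sidak"] < 0.05 for c in res["contrasts"])

    def test_sidak_adjustment_increases_p(self):
        rng = np.random.default_rng(12)
        rows = []
        for s in range(20):
            for direction in ("fwd", "rev"):
                rows.append({"subject": s, "group": "A" if s < 10 else "B",
                             "direction": direction, "gc": rng.standard_normal()})
        res = mixed_anova_sidak(pd.DataFrame(rows), dv="gc", within="direction",
                                between="group", subject="subject")
        for c in res["contrasts"]:
            assert c["p_sidak"] >= c["p_unc"]
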