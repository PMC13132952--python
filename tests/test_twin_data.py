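"""Data container, reader, correlations, residualisation and screening."""

import io
import math

import numpy as np
import pandas as pd
import pytest

import twinsem as ts
from twinsem.data import (
    TwinDataError, column_name, correlation_matrix, fisher_ci,
    phenotypic_correlations, read_twin_table, residualize_on_age,
    screen_event_category, twin_correlations,
)


def _csv(rows: list[dict]) -> io.StringIO:
    return io.StringIO(pd.DataFrame(rows).to_csv(index=False))


def _two_row_csv(**overrides):
    base = {"family_id": "F1", "zygosity": "MZ"}
    for w in (1, 2, 3):
        for t in (1, 2):
            base[column_name("wb", w, t)] = 7
            base[column_name("negdep", w, t)] = 2
    rows = [dict(base), dict(base, family_id="F2", zygosity="DZ")]
    rows[0].update(overrides)
    return _csv(rows)


class TestReader:
    def test_valid_two_row_round_trip(self):
        ds = read_twin_table(_two_row_csv())
        assert ds.n_pairs == 2
        assert set(ds.df["zygosity"]) == {"MZ", "DZ"}
        assert not ds.df.filter(like="wb").isna().any().any()

    def test_out_of_range_wellbeing_names_the_cell(self):
        with pytest.raises(TwinDataError, match="wb1_1=11"):
            read_twin_table(_two_row_csv(wb1_1=11))

    def test_unknown_zygosity_is_hard_error(self):
        with pytest.raises(TwinDataError, match="zygosity"):
            read_twin_table(_two_row_csv(zygosity="XX"))

    def test_missing_codes_normalised(self):
        ds = read_twin_table(_two_row_csv(wb1_1="-99"))
        assert math.isnan(ds.df.at[0, "wb1_1"])

    def test_schema_mapping_and_zygosity_codes(self):
        buf = _csv([{"fam": "F1", "zyg": "1", "wellbeing_w1_t1": 5}])
        ds = read_twin_table(
            buf, schema={"fam": "family_id", "zyg": "zygosity",
                         "wellbeing_w1_t1": "wb1_1"})
        assert ds.df.at[0, "zygosity"] == "MZ"
        assert ds.df.at[0, "wb1_1"] == 5

    def test_simulator_round_trip(self, small_discrete_ds, tmp_path):
        """Writing a simulated dataset and reading it back is the identity."""
        path = tmp_path / "twins.csv"
        small_discrete_ds.to_csv(path)
        back = read_twin_table(path)
        assert back == small_discrete_ds

    def test_duplicate_family_id_rejected(self):
        df = pd.DataFrame({"family_id": ["F1", "F1"], "zygosity": ["MZ", "MZ"]})
        with pytest.raises(TwinDataError, match="duplicate"):
            ts.TwinDataset(df)


class TestPhenotypicCorrelations:
    def _ds(self, x, y):
        n = len(x)
        df = pd.DataFrame({
            "family_id": [f"F{i}" for i in range(n)], "zygosity": "MZ",
            "wb1_1": x, "wb1_2": np.nan, "negdep1_1": y, "negdep1_2": np.nan,
        })
        return ts.TwinDataset(df, continuous=True)

    def test_self_correlation_is_one(self):
        ds = self._ds([1, 2, 3, 4.0], [0, 0, 0, 0.0])
        reps = phenotypic_correlations(ds, ["wb1"])
        assert reps[0].r == 1.0

    def test_exact_negation_gives_minus_one(self):
        x = np.arange(10.0)
        reps = phenotypic_correlations(self._ds(x, -x), ["wb1", "negdep1"])
        r = {(c.var1, c.var2): c.r for c in reps}[("wb1", "negdep1")]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula_on_fixture(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        y = 0.4 * x + rng.normal(size=20)
        reps = phenotypic_correlations(self._ds(x, y), ["wb1", "negdep1"])
        got = {(c.var1, c.var2): c for c in reps}[("wb1", "negdep1")]
        # independent oracle: the raw product-moment formula
        sx, sy = x - x.mean(), y - y.mean()
        r_oracle = (sx * sy).sum() / math.sqrt((sx**2).sum() * (sy**2).sum())
        assert got.r == pytest.approx(r_oracle, abs=1e-12)
        assert got.n == 20

    def test_too_few_complete_pairs_undefined(self):
        ds = self._ds([1, 2, np.nan, np.nan], [np.nan, np.nan, 1, 2.0])
        reps = phenotypic_correlations(ds, ["wb1", "negdep1"])
        got = {(c.var1, c.var2): c for c in reps}[("wb1", "negdep1")]
        assert math.isnan(got.r)

    def test_matrix_symmetric_unit_diagonal(self, small_discrete_ds):
        labels = [f"wb{w}" for w in (1, 2, 3)] + [f"negdep{w}" for w in (1, 2, 3)]
        mat = correlation_matrix(phenotypic_correlations(small_discrete_ds, labels))
        arr = mat.to_numpy(float)
        assert np.allclose(arr, arr.T, equal_nan=True)
        assert np.allclose(np.diag(arr), 1.0)


class TestTwinCorrelations:
    def _pairs(self, x1, x2, zyg="MZ"):
        n = len(x1)
        df = pd.DataFrame({"family_id": [f"F{i}" for i in range(n)],
                           "zygosity": zyg, "wb1_1": x1, "wb1_2": x2})
        return ts.TwinDataset(df, continuous=True)

    def test_identical_cotwins_give_r_one(self):
        x = np.arange(10.0)
        out = twin_correlations(self._pairs(x, x), "wb1")
        assert out["MZ"]["r"] == pytest.approx(1.0)

    def test_fisher_ci_closed_form(self):
        # r = 0, n = 100 pairs: bounds are +/- tanh(1.96 / sqrt(97))
        lo, hi = fisher_ci(0.0, 100, 0.95)
        assert hi == pytest.approx(math.tanh(1.959964 / math.sqrt(97)), abs=1e-4)
        assert lo == pytest.approx(-hi, abs=1e-12)
        assert (lo, hi) == pytest.approx((-0.196, 0.196), abs=1e-3)

    def test_double_entry_invariant_to_twin_swap(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.normal(size=50), rng.normal(size=50)
        a = twin_correlations(self._pairs(x1, x2), "wb1", double_entry=True)
        b = twin_correlations(self._pairs(x2, x1), "wb1", double_entry=True)
        assert a["MZ"]["r"] == pytest.approx(b["MZ"]["r"], abs=1e-12)

    def test_large_ae_sample_matches_model_implied(self):
        """Cross-twin MZ correlation under an AE truth equals the implied a2."""
        sc = ts.study_scenario("cholesky", n_mz=30000, n_dz=100)
        ds = ts.simulate_pairs(sc.with_seed(9))
        out = twin_correlations(ds, "wb1")
        from twinsem.cholesky import implied_twin_correlations
        expected = implied_twin_correlations(sc.params).loc["wave1", "rMZ"]
        assert out["MZ"]["r"] == pytest.approx(expected, abs=0.02)


class TestResidualizeOnAge:
    def _ds(self, age, y):
        n = len(age)
        cols = {"family_id": [f"F{i}" for i in range(n)], "zygosity": "MZ"}
        for w in (1, 2, 3):
            cols[f"wb{w}_1"] = y
            cols[f"wb{w}_2"] = np.nan
            cols[f"age{w}_1"] = age
            cols[f"age{w}_2"] = np.nan
        return ts.TwinDataset(pd.DataFrame(cols), continuous=True)

    def test_perfect_fit_gives_zero_residuals(self):
        age = np.array([14.0, 15, 16, 17])
        out = residualize_on_age(self._ds(age, 2 * age))
        assert np.allclose(out.df["wb1_1"], 0.0, atol=1e-10)

    def test_orthogonal_age_mean_centers(self):
        age = np.array([-1.0, 1, -1, 1])
        y = np.array([2.0, 2, 4, 4])   # cov(age, y) = 0
        out = residualize_on_age(self._ds(age, y))
        assert np.allclose(out.df["wb1_1"], y - y.mean(), atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        age = rng.uniform(13, 19, size=30)
        y = 5 + 0.2 * age + rng.normal(size=30)
        out = residualize_on_age(self._ds(age, y))
        X = np.column_stack([np.ones(30), age])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(out.df["wb1_1"], y - X @ beta, atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(12)
        age = rng.uniform(13, 19, size=30)
        y = rng.normal(size=30)
        once = residualize_on_age(self._ds(age, y))
        twice = residualize_on_age(once)
        assert np.allclose(once.df["wb1_1"], twice.df["wb1_1"], atol=1e-10)

    def test_constant_age_falls_back_to_centering(self):
        y = np.array([1.0, 2, 3, 4])
        with pytest.warns(UserWarning, match="identical"):
            out = residualize_on_age(self._ds(np.full(4, 15.0), y))
        assert np.allclose(out.df["wb1_1"], y - y.mean(), atol=1e-10)

    def test_missing_age_blanks_output(self):
        age = np.array([14.0, np.nan, 16, 17])
        out = residualize_on_age(self._ds(age, np.array([5.0, 6, 7, 8])))
        assert math.isnan(out.df.at[1, "wb1_1"])


class TestScreening:
    def _reports(self, rs, ps):
        return [ts.CorrelationReport(f"wb{w}", f"posdep{w}", r, 500, p, p < 0.05)
                for w, (r, p) in enumerate(zip(rs, ps), start=1)]

    def test_null_correlations_excluded(self):
        d = screen_event_category(self._reports([0.0, 0.0, 0.0], [1, 1, 1]), "posdep")
        assert not d.include

    def test_one_strong_same_wave_keeps_category(self):
        d = screen_event_category(
            self._reports([-0.30, 0.0, 0.0], [1e-4, 1, 1]), "posdep")
        assert d.include
        assert d.driving[0].r == -0.30

    def test_category_absent_raises(self):
        with pytest.raises(TwinDataError):
            screen_event_category(self._reports([0.0] * 3, [1] * 3), "negdep")

    def test_null_simulation_excludes_in_most_replicates(self):
        """With true cross-trait correlation 0 at n=2000 individuals,
        the screen excludes in at least 90% of 100 replicates."""
        rng = np.random.default_rng(2024)
        n_excluded = 0
        for _ in range(100):
            wb = rng.normal(size=(1000, 6))      # 1000 pairs = 2000 twins
            pos = rng.normal(size=(1000, 6))
            cols = {"family_id": [f"F{i}" for i in range(1000)], "zygosity": "MZ"}
            for w in (1, 2, 3):
                for t in (1, 2):
                    cols[f"wb{w}_{t}"] = wb[:, 2 * (w - 1) + t - 1]
                    cols[f"posdep{w}_{t}"] = pos[:, 2 * (w - 1) + t - 1]
            ds = ts.TwinDataset(pd.DataFrame(cols), continuous=True)
            labels = [f"wb{w}" for w in (1, 2, 3)] + [f"posdep{w}" for w in (1, 2, 3)]
            reps = phenotypic_correlations(ds, labels)
            if not screen_event_category(reps, "posdep").include:
                n_excluded += 1
        assert n_excluded >= 90


class TestProfileTwinCI:
    def test_profile_interval_close_to_fisher(self):
        """Likelihood-based and Fisher-z twin-correlation intervals agree
        closely at a moderate sample size."""
        sc = ts.study_scenario("cholesky", n_mz=500, n_dz=10, seed=14)
        ds = ts.simulate_pairs(sc)
        fisher = twin_correlations(ds, "wb1", ci_method="fisher")["MZ"]
        profile = twin_correlations(ds, "wb1", ci_method="profile")["MZ"]
        assert profile["ci"][0] == pytest.approx(fisher["ci"][0], abs=0.03)
        assert profile["ci"][1] == pytest.approx(fisher["ci"][1], abs=0.03)
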