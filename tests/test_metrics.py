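import numpy as np
import pandas as pd
import pytest

from mastpheno.metrics import (
    circular_doy,
    circular_mean_sd_doy,
    cv_metric,
    failure_metric,
    intensity_metric,
    metrics_table,
    pca_metrics,
    synchrony_metric,
    synchrony_pair_mean,
    volatility_metric,
)


def volatility_oracle(values):
    """Brute-force frequency-weighted periodogram (direct DFT)."""
    v = np.asarray(values, dtype=float)
    T = len(v)
    y = v - v.mean()
    total = 0.0
    for k in range(1, T // 2 + 1):
        dft = sum(y[t] * np.exp(-2j * np.pi * k * t / T) for t in range(T))
        total += (k / T) * (abs(dft) ** 2 / T)
    return 2.0 / T * total


class TestIntensityCvFailure:
    def test_intensity_examples(self):
        assert intensity_metric([0.2, 0.4]) == pytest.approx(0.3)
        assert intensity_metric([0, 0, 0]) == 0.0
        assert intensity_metric([0, 1, 2, 3]) == pytest.approx(1.5)

    def test_cv_sample_sd_over_mean(self):
        assert cv_metric([2, 2, 2, 2]) == 0.0
        assert cv_metric([0, 0, 0, 4]) == pytest.approx(2.0)  # sd=2 (n-1), mean=1

    def test_cv_zero_mean_is_missing(self):
        with pytest.warns(UserWarning, match="zero-mean"):
            assert np.isnan(cv_metric([0, 0, 0, 0]))

    def test_failure_proportion(self):
        assert failure_metric([0, 0.2, 0, 0.5, 0.1, 0, 0.3, 0.4]) == pytest.approx(3 / 8)
        assert failure_metric([0.1, 0.2]) == 0.0
        assert failure_metric([0, 0, 0]) == 1.0


class TestVolatility:
    def test_constant_series_zero(self):
        assert volatility_metric([1.5] * 8) == 0.0

    def test_quadratic_amplitude_scaling(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(0, 4, 10)
        assert volatility_metric(2 * y) == pytest.approx(4 * volatility_metric(y))

    def test_alternating_exceeds_blocked_equal_variance(self):
        alt = [0, 4, 0, 4, 0, 4, 0, 4]
        blk = [0, 0, 0, 0, 4, 4, 4, 4]
        assert np.var(alt) == np.var(blk)
        assert volatility_metric(alt) > volatility_metric(blk)
        assert volatility_metric(alt) == pytest.approx(volatility_oracle(alt), abs=1e-10)

    def test_agrees_with_dft_oracle_battery(self):
        rng = np.random.default_rng(42)
        for T in range(4, 13):
            for _ in range(5):
                y = rng.uniform(0, 4, T)
                assert volatility_metric(y) == pytest.approx(
                    volatility_oracle(y), abs=1e-10
                )

    def test_interior_gap_policy(self):
        gapped = [1.0, 2.0, np.nan, 3.0, 1.0]
        with pytest.raises(ValueError, match="gap_policy"):
            volatility_metric(gapped)
        filled = volatility_metric(gapped, gap_policy="interpolate")
        assert filled == pytest.approx(volatility_oracle([1, 2, 2.5, 3, 1]), abs=1e-10)

    def test_short_series_missing(self):
        assert np.isnan(volatility_metric([1, 2, 3]))


class TestSynchrony:
    def test_identical_series_full_synchrony(self):
        m = pd.DataFrame([[1, 2, 3, 4], [1, 2, 3, 4]], index=["a", "b"])
        _, species = synchrony_metric(m)
        assert species == pytest.approx(1.0)

    def test_three_tree_pairwise_example(self):
        m = pd.DataFrame(
            [[1, 2, 3], [2, 4, 6], [3, 2, 1]], index=["A", "B", "C"], dtype=float
        )
        per_tree, species = synchrony_metric(m)
        assert per_tree["A"] == pytest.approx(0.0)
        assert per_tree["C"] == pytest.approx(-1.0)
        assert species == pytest.approx(-1 / 3)
        # tree-mean and unordered-pair-mean aggregations agree here
        assert synchrony_pair_mean(m) == pytest.approx(species)

    def test_constant_tree_excluded(self):
        m = pd.DataFrame(
            [[1, 2, 3], [2, 2, 2], [2, 4, 6]], index=["A", "B", "C"], dtype=float
        )
        per_tree, species = synchrony_metric(m)
        assert "B" not in per_tree.index
        assert species == pytest.approx(1.0)

    def test_no_valid_pair_missing(self):
        m = pd.DataFrame([[1, 2, 3]], index=["A"], dtype=float)
        _, species = synchrony_metric(m)
        assert np.isnan(species)

    def test_invariant_to_tree_relabelling_and_missing_year(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.uniform(0, 4, (4, 6)), index=list("abcd"))
        _, s1 = synchrony_metric(m)
        relabel = m.rename(index={"a": "z"}).sort_index()
        _, s2 = synchrony_metric(relabel)
        assert s1 == pytest.approx(s2)
        with_missing = m.copy()
        with_missing[99] = np.nan
        _, s3 = synchrony_metric(with_missing)
        assert s1 == pytest.approx(s3)


def _doy_table(doys_and_scores, year=2015, species="sp", phenophase="flower"):
    rows = []
    for doy, score in doys_and_scores:
        date = pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=doy - 1)
        rows.append(
            {
                "tree_id": "t1",
                "species": species,
                "site": "Sk",
                "date": date,
                "phenophase": phenophase,
                "score": score,
            }
        )
    return pd.DataFrame(rows)


class TestCircularDoy:
    def test_point_mass(self):
        table = _doy_table([(100, 4), (100, 4), (100, 4), (30, 0), (200, 0)])
        s = circular_doy(table, "sp", "flower")
        assert s.mean_doy == pytest.approx(100.0)
        assert s.sd_doy == pytest.approx(0.0, abs=1e-9)
        assert not s.diffuse

    def test_wrap_around_mean(self):
        mean_doy, _, _ = circular_mean_sd_doy([360, 10])
        assert mean_doy == pytest.approx(2.5)

    def test_no_wrap_matches_linear_statistics(self):
        rng = np.random.default_rng(5)
        doys = rng.normal(150, 12, 200).clip(100, 200)
        mean_doy, sd_doy, _ = circular_mean_sd_doy(doys)
        assert mean_doy == pytest.approx(doys.mean(), abs=0.5)
        assert sd_doy == pytest.approx(doys.std(), abs=0.5)

    def test_uniform_flagged_diffuse(self):
        doys = np.linspace(1, 365, 73, endpoint=False)
        table = _doy_table([(int(d), 4) for d in doys] + [(10, 0)] * 80)
        s = circular_doy(table, "sp", "flower")
        assert s.diffuse

    def test_threshold_uses_all_observations(self):
        # mean score = (4+4+1+1+0+0)/6 = 5/3; only the 4s qualify
        table = _doy_table([(100, 4), (110, 4), (200, 1), (210, 1), (5, 0), (6, 0)])
        with pytest.raises(ValueError):
            circular_doy(table, "sp", "flower")  # only 2 qualify
        table = _doy_table(
            [(100, 4), (110, 4), (120, 4), (200, 1), (210, 1), (5, 0), (6, 0)]
        )
        s = circular_doy(table, "sp", "flower")
        assert 100 <= s.mean_doy <= 120


class TestMetricsTable:
    def test_shape_and_flags(self, small_study):
        obs, roster, *_ = small_study
        mt = metrics_table(obs, roster)
        assert set(mt["phenophase"]) == {"flower", "fruit"}
        assert len(mt) == 2
        for _, row in mt.iterrows():
            assert row["cv_gt_1"] == (row["cv"] > 1.0)
            assert row["sync_gt_0.2"] == (row["synchrony"] > 0.2)
        assert (mt["failures"].between(0, 1)).all()
        assert (mt["cv"] >= 0).all()


class TestPCA:
    def _metrics_frame(self, n=5, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            rows.append(
                {
                    "species": f"sp{i}",
                    "phenophase": "flower",
                    "intensity": rng.uniform(0, 1),
                    "cv": rng.uniform(0, 2),
                    "volatility": rng.uniform(0, 0.1),
                    "synchrony": rng.uniform(-0.2, 1),
                    "failures": rng.uniform(0, 1),
                }
            )
        return pd.DataFrame(rows)

    def test_variance_explained_sums_to_one(self):
        res = pca_metrics(self._metrics_frame(), "flower")
        assert res.variance_explained.sum() == pytest.approx(1.0)

    def test_matches_correlation_eigendecomposition(self):
        df = self._metrics_frame(6, seed=3)
        res = pca_metrics(df, "flower")
        X = df.set_index("species")[["intensity", "cv", "volatility", "synchrony", "failures"]]
        eig = np.sort(np.linalg.eigvalsh(np.corrcoef(X.to_numpy(), rowvar=False)))[::-1]
        got = res.variance_explained * eig.sum()
        assert np.allclose(got, eig, atol=1e-10)

    def test_reconstruction(self):
        df = self._metrics_frame(7, seed=4)
        res = pca_metrics(df, "flower")
        X = df.set_index("species")[["intensity", "cv", "volatility", "synchrony", "failures"]]
        Z = (X - X.mean()) / X.std(ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.abs(recon - Z.to_numpy()).max() < 1e-10

    def test_constant_column_dropped(self):
        df = self._metrics_frame(5, seed=6)
        df["volatility"] = 0.05
        with pytest.warns(UserWarning, match="constant metric"):
            res = pca_metrics(df, "flower")
        assert "volatility" in res.dropped_metrics
        assert "volatility" not in res.loadings.index

    def test_too_few_species_errors(self):
        with pytest.raises(ValueError, match=">= 3"):
            pca_metrics(self._metrics_frame(2), "flower")
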