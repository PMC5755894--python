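"""Index arithmetic, fit classification, ROC threshold and descriptor screen."""

import numpy as np
import pandas as pd
import pytest

from aedes_capacity import (
    ImfaSeries,
    aimfa,
    classify_fits,
    descriptor_regressions,
    observed_imfa,
    roc_threshold,
)
from aedes_capacity.surveillance import AreaDescriptors


def make_series(values, n_traps=10):
    weeks = pd.date_range("2008-01-07", periods=len(values), freq="7D")
    return ImfaSeries(weeks=weeks, values=np.asarray(values, float), n_traps=n_traps)


class TestObservedImfa:
    def test_ratio(self):
        assert observed_imfa(10, 20) == 0.5

    def test_zero_captures(self):
        assert observed_imfa(0, 15) == 0.0

    def test_scale_invariance(self):
        assert observed_imfa(6, 12) == observed_imfa(12, 24)

    def test_no_traps_rejected(self):
        with pytest.raises(ZeroDivisionError):
            observed_imfa(3, 0)


class TestAimfa:
    def test_constant(self):
        assert aimfa(make_series(np.full(8, 0.4))) == pytest.approx(0.4)

    def test_two_values(self):
        assert aimfa(make_series([0.0, 1.0])) == 0.5

    def test_ignores_missing_weeks(self):
        assert aimfa(make_series([0.0, np.nan, 1.0])) == 0.5


class TestClassifyFits:
    def test_above_mean_is_poor(self):
        fits = pd.DataFrame({"mse": [1.0, 3.0]})
        assert list(classify_fits(fits)) == ["good", "poor"]

    def test_all_equal_all_good(self):
        fits = pd.DataFrame({"mse": [2.0, 2.0, 2.0]})
        assert set(classify_fits(fits)) == {"good"}

    def test_row_order_invariant(self):
        mses = [5.0, 1.0, 9.0, 2.0]
        a = classify_fits(pd.DataFrame({"mse": mses}))
        b = classify_fits(pd.DataFrame({"mse": mses[::-1]}))
        assert list(a) == list(b)[::-1]

    def test_needs_two_areas(self):
        with pytest.raises(ValueError):
            classify_fits(pd.DataFrame({"mse": [1.0]}))


def brute_force_youden(counts, labels):
    """Exhaustive oracle: try every distinct count as a threshold."""
    good = np.asarray(labels) == "good"
    best = (-np.inf, None)
    for thr in sorted(set(counts)):
        pred = np.asarray(counts) >= thr
        sens = (pred & good).sum() / good.sum()
        spec = (~pred & ~good).sum() / (~good).sum()
        j = sens + spec - 1
        if j > best[0]:
            best = (j, thr)
    return best


class TestRocThreshold:
    def test_perfect_separation(self):
        counts = np.array([4, 6, 8, 10, 20, 25, 30, 40])
        labels = np.array(["poor"] * 4 + ["good"] * 4)
        roc = roc_threshold(counts, labels)
        assert 10 < roc.threshold <= 20
        assert roc.youden_j.max() == pytest.approx(1.0)
        assert roc.auc == pytest.approx(1.0)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(777)
        for _ in range(200):
            n = rng.integers(4, 50)
            counts = rng.integers(2, 150, size=n)
            labels = np.where(rng.random(n) < 0.5, "good", "poor")
            if len(set(labels)) < 2:
                continue
            roc = roc_threshold(counts, labels)
            j_best, _ = brute_force_youden(counts, labels)
            assert roc.youden_j.max() == pytest.approx(j_best)
            # the reported threshold attains the optimum
            idx = np.where(roc.thresholds == roc.threshold)[0][0]
            assert roc.youden_j[idx] == pytest.approx(j_best)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(2, 100, size=30)
        labels = np.where(counts + rng.normal(0, 20, 30) > 40, "good", "poor")
        if len(set(labels)) < 2:
            pytest.skip("degenerate draw")
        base = roc_threshold(counts, labels)
        perm = rng.permutation(30)
        shuffled = roc_threshold(counts[perm], labels[perm])
        assert base.threshold == shuffled.threshold
        assert base.auc == pytest.approx(shuffled.auc)

    def test_tie_takes_smallest_threshold(self):
        # thresholds 10 and 20 give identical J; 10 must win
        counts = np.array([5, 10, 20, 30])
        labels = np.array(["poor", "poor", "good", "good"])
        roc = roc_threshold(counts, labels)
        j_at = dict(zip(roc.thresholds, roc.youden_j))
        assert j_at[20.0] == j_at[roc.threshold] or roc.threshold <= 20.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_threshold([1, 2, 3], ["good", "good", "good"])


def synthetic_association_tables(rng, n=40, garbage_slope=100.0):
    """Areas whose garbage descriptor tracks K with a planted slope
    (descriptor units per 1000 eggs ~ slope/1000 per egg)."""
    k = rng.uniform(1300, 4200, size=n)
    fits = pd.DataFrame(
        {"area_id": [f"a{i}" for i in range(n)], "K_hat": k + rng.normal(0, 200, n)}
    )
    desc = pd.DataFrame(
        {
            "area_id": fits["area_id"],
            "population": rng.uniform(500, 30000, n),
            "households": rng.uniform(100, 10000, n),
            "area_km2": rng.uniform(0.05, 3.0, n),
            "pop_density": rng.uniform(500, 50000, n),
            "pct_illegal_energy": rng.uniform(0, 30, n),
            "pct_garbage_streets": np.clip(
                garbage_slope * (k - 2750) / 1000.0 + rng.normal(0, 50, n) + 300, 0, None
            ),
            "pct_unpaved": rng.uniform(0, 20, n),
            "pct_open_sewage": rng.uniform(36, 54, n),
            "pct_no_manhole": rng.uniform(0, 79, n),
        }
    )
    aimfas = pd.Series(rng.uniform(0.25, 0.78, n), index=fits["area_id"], name="aimfa")
    return fits, aimfas, desc


class TestDescriptorRegressions:
    def test_planted_positive_association_recovered(self):
        rng = np.random.default_rng(42)
        fits, aimfas, desc = synthetic_association_tables(rng, garbage_slope=100.0)
        table = descriptor_regressions(fits, aimfas, desc)
        row = table[(table.descriptor == "pct_garbage_streets") & (table.response == "K")]
        assert row["stars"].iloc[0] == "***"
        assert row["slope"].iloc[0] > 0

    def test_null_effect_rarely_starred(self):
        rng = np.random.default_rng(2024)
        false_positives = 0
        reps = 100
        for _ in range(reps):
            fits, aimfas, desc = synthetic_association_tables(rng, garbage_slope=0.0)
            # make garbage pure noise, independent of K
            desc["pct_garbage_streets"] = rng.uniform(0, 8, len(desc))
            table = descriptor_regressions(fits, aimfas, desc)
            row = table[
                (table.descriptor == "pct_garbage_streets") & (table.response == "K")
            ]
            if row["p_value"].iloc[0] < 0.05:
                false_positives += 1
        assert false_positives <= 10

    def test_regressing_K_on_itself(self):
        rng = np.random.default_rng(3)
        fits, aimfas, desc = synthetic_association_tables(rng)
        desc["area_km2"] = fits["K_hat"].to_numpy()  # descriptor == response
        table = descriptor_regressions(fits, aimfas, desc)
        row = table[(table.descriptor == "area_km2") & (table.response == "K")]
        assert row["slope"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert row["p_value"].iloc[0] < 1e-20

    def test_population_is_log_transformed(self):
        rng = np.random.default_rng(4)
        fits, aimfas, desc = synthetic_association_tables(rng)
        table = descriptor_regressions(fits, aimfas, desc)
        assert "log_population" in set(table.descriptor)
        assert "population" not in set(table.descriptor)

    def test_too_few_areas_rejected(self):
        rng = np.random.default_rng(5)
        fits, aimfas, desc = synthetic_association_tables(rng, n=5)
        with pytest.raises(ValueError):
            descriptor_regressions(fits, aimfas, desc)

    def test_constant_descriptor_skipped(self):
        rng = np.random.default_rng(6)
        fits, aimfas, desc = synthetic_association_tables(rng)
        desc["pct_unpaved"] = 5.0
        table = descriptor_regressions(fits, aimfas, desc)
        assert "pct_unpaved" not in set(table.descriptor)


def test_area_descriptors_validation():
    with pytest.raises(ValueError):
        AreaDescriptors(
            population=100, households=30, area_km2=0.5, pop_density=200,
            pct_illegal_energy=120.0, pct_garbage_streets=1, pct_unpaved=1,
            pct_open_sewage=40, pct_no_manhole=10,
        )
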