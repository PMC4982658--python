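"""Δlog(CV), Δr², verdict logic and the equal-pixel-sampling control."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table
from facomp.noise_infer import (
    Verdict,
    coefficient_of_variation,
    compare_categories,
    delta_fano,
    delta_log_cv,
    delta_r2,
    equal_pixel_control,
    fano_factor,
    infer_change,
    pairwise_r2,
)


class TestCoefficientOfVariation:
    def test_constant_values_have_zero_cv(self):
        assert coefficient_of_variation([4.0, 4.0, 4.0]) == 0.0

    def test_two_point_value(self):
        # sd = sqrt(2), mean = 2
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.lognormal(0, 0.5, 500)
        assert coefficient_of_variation(v * 10) == pytest.approx(
            coefficient_of_variation(v), rel=1e-12
        )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, -2.0])
        with pytest.raises(ValueError):
            coefficient_of_variation([5.0])

    def test_poisson_counts_have_unit_fano(self):
        rng = np.random.default_rng(1)
        for mean in (3.0, 30.0, 300.0):
            f = fano_factor(rng.poisson(mean, 50_000))
            assert f == pytest.approx(1.0, abs=0.05)


class TestPairwiseR2:
    def test_duplicated_column_fully_correlated(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=100)
        t = make_table({"A": v, "B": v.copy(), "C": rng.normal(size=100)})
        r, r2 = pairwise_r2(t)
        assert r.loc["A", "B"] == pytest.approx(1.0)
        assert r2.loc["A", "A"] == 1.0

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        t = make_table({"A": rng.normal(size=10_000), "B": rng.normal(size=10_000)})
        _, r2 = pairwise_r2(t)
        assert abs(np.sqrt(r2.loc["A", "B"])) < 3 / np.sqrt(10_000)

    def test_matches_brute_force_on_small_table(self):
        """Hand computation: covariance over sd products on a 5x3 table."""
        X = np.array(
            [
                [1.0, 2.0, 0.5],
                [2.0, 1.0, 1.5],
                [3.0, 4.0, 2.0],
                [4.0, 3.0, 4.0],
                [5.0, 6.0, 3.0],
            ]
        )
        t = make_table({"A": X[:, 0], "B": X[:, 1], "C": X[:, 2]})
        r, _ = pairwise_r2(t)
        for i, a in enumerate("ABC"):
            for j, b in enumerate("ABC"):
                num = np.mean((X[:, i] - X[:, i].mean()) * (X[:, j] - X[:, j].mean()))
                den = X[:, i].std() * X[:, j].std()
                assert r.loc[a, b] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_column_flagged_undefined(self):
        t = make_table({"A": [1.0, 2, 3, 4], "B": [5.0, 5, 5, 5]})
        r, r2 = pairwise_r2(t)
        assert np.isnan(r.loc["A", "B"])
        assert r.loc["A", "A"] == 1.0

    def test_too_few_rows_rejected(self):
        t = make_table({"A": [1.0, 2], "B": [3.0, 4]})
        with pytest.raises(ValueError):
            pairwise_r2(t)


def two_dataset_fixture():
    """A 2-dataset, 3-component worked example with hand-computable deltas.

    Category 2 values are category 1 values scaled and spread so that each
    component's CV exactly doubles: x -> mean + 2*(x - mean) preserves the
    mean and doubles the sd.
    """
    rng = np.random.default_rng(4)
    cat1, cat2 = [], []
    for ds in ("R1O1", "R1O2"):
        base = {
            c: rng.lognormal(2.0, 0.3, 40) for c in ("P", "Q", "R")
        }
        doubled = {c: v.mean() + 2.0 * (v - v.mean()) for c, v in base.items()}
        meta = {"dataset_id": ds, "repeat": "R1", "labeling_order": ds[-2:]}
        cat1.append(make_table(base, **meta))
        cat2.append(make_table(doubled, **meta))
    return cat1, cat2


class TestDeltaLogCV:
    def test_identical_categories_give_zero(self):
        cat1, _ = two_dataset_fixture()
        d = delta_log_cv(cat1, cat1)
        assert d.mean == 0.0
        assert d.sem == 0.0

    def test_doubled_cv_gives_log_two_exactly(self):
        """Hand-computed: CV2 = 2 CV1 for every component and dataset."""
        cat1, cat2 = two_dataset_fixture()
        d = delta_log_cv(cat1, cat2)
        assert d.mean == pytest.approx(np.log(2.0), abs=1e-12)
        assert d.sem == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_average_over_datasets_then_components(self):
        """Full hand recomputation of the two-stage average and its SEM."""
        cat1, cat2 = two_dataset_fixture()
        # perturb one dataset to give a nonzero SEM
        cat2[1].data["P"] *= 1.7
        d = delta_log_cv(cat1, cat2)
        vals = np.empty((2, 3))
        for i, (t1, t2) in enumerate(zip(cat1, cat2)):
            for j, c in enumerate(("P", "Q", "R")):
                cv1 = t1.raw[c].std(ddof=1) / t1.raw[c].mean()
                cv2 = t2.raw[c].std(ddof=1) / t2.raw[c].mean()
                vals[i, j] = np.log(cv2 / cv1)
        expected_mean = vals.mean(axis=0).mean()
        ds_means = vals.mean(axis=1)
        expected_sem = ds_means.std(ddof=1) / np.sqrt(2)
        assert d.mean == pytest.approx(expected_mean, abs=1e-12)
        assert d.sem == pytest.approx(expected_sem, abs=1e-12)

    def test_small_dataset_excluded_by_min_rule(self):
        cat1, cat2 = two_dataset_fixture()
        cat2[1] = cat2[1].select(cat2[1].data.index < 4)  # only 4 adhesions
        d = delta_log_cv(cat1, cat2)
        assert d.n_datasets == 1
        assert list(d.per_dataset.index) == ["R1O1"]

    def test_no_qualifying_dataset_is_an_error(self):
        cat1, cat2 = two_dataset_fixture()
        small = [t.select(t.data.index < 3) for t in cat2]
        with pytest.raises(ValueError):
            delta_log_cv(cat1, small)

    def test_antisymmetry_exact(self):
        cat1, cat2 = two_dataset_fixture()
        cat2[0].data["Q"] *= 1.3
        fwd = delta_log_cv(cat1, cat2)
        rev = delta_log_cv(cat2, cat1)
        assert fwd.mean == pytest.approx(-rev.mean, abs=1e-12)
        assert fwd.sem == pytest.approx(rev.sem, abs=1e-12)


class TestDeltaR2:
    def test_identical_categories_give_zero(self):
        cat1, _ = two_dataset_fixture()
        d = delta_r2(cat1, cat1)
        assert d.mean == 0.0

    def test_known_r_shift(self):
        """r1 = 0.5, r2 = 0.9 on every pair -> delta = 0.81 - 0.25 = 0.56."""
        n = 20_000
        rng = np.random.default_rng(5)

        def correlated_pair_table(r, ds):
            # three components sharing one factor with loading sqrt(r)
            lam = np.sqrt(r)
            f = rng.normal(size=n)
            cols = {
                c: lam * f + np.sqrt(1 - lam**2) * rng.normal(size=n) + 10
                for c in ("P", "Q", "R")
            }
            return make_table(cols, dataset_id=ds)

        cat1 = [correlated_pair_table(0.5, "R1O1")]
        cat2 = [correlated_pair_table(0.9, "R1O1")]
        d = delta_r2(cat1, cat2, use_zscores=False)
        assert d.mean == pytest.approx(0.56, abs=0.03)

    def test_bounded_in_unit_interval(self):
        cat1, cat2 = two_dataset_fixture()
        d = delta_r2(cat1, cat2)
        assert -1.0 <= d.mean <= 1.0

    def test_antisymmetry_exact(self):
        cat1, cat2 = two_dataset_fixture()
        cat2[0].data["Q"] = cat2[0].data["Q"].to_numpy()[::-1]
        fwd = delta_r2(cat1, cat2)
        rev = delta_r2(cat2, cat1)
        assert fwd.mean == pytest.approx(-rev.mean, abs=1e-12)


class TestDeltaFano:
    def test_identical_categories_give_zero(self):
        cat1, _ = two_dataset_fixture()
        assert delta_fano(cat1, cat1).mean == 0.0

    def test_poisson_fano_delta_near_zero_between_different_means(self):
        """Fano stays ~1 for Poisson counts regardless of the mean."""
        rng = np.random.default_rng(6)
        cat1 = [make_table({c: rng.poisson(50, 3000).astype(float) for c in "PQR"})]
        cat2 = [make_table({c: rng.poisson(400, 3000).astype(float) for c in "PQR"})]
        d = delta_fano(cat1, cat2)
        assert abs(d.mean) < 0.1

    def test_sign_usually_matches_delta_log_cv(self):
        """When fluctuations are uncoupled from the mean, both dispersion
        measures move together."""
        cat1, cat2 = two_dataset_fixture()
        assert np.sign(delta_fano(cat1, cat2).mean) == np.sign(
            delta_log_cv(cat1, cat2).mean
        )


class TestInferChange:
    @pytest.mark.parametrize(
        "dcv,dr2,expected",
        [
            ((-0.2, 0.05), (+0.10, 0.02), Verdict.NOISE_LOWER_IN_2),
            ((+0.2, 0.05), (-0.10, 0.02), Verdict.NOISE_LOWER_IN_1),
            ((+0.2, 0.05), (+0.10, 0.02), Verdict.DIVERSITY_HIGHER_IN_2),
            ((-0.2, 0.05), (-0.10, 0.02), Verdict.DIVERSITY_HIGHER_IN_1),
            ((-0.03, 0.05), (+0.10, 0.02), Verdict.INCONCLUSIVE),  # |mean| < SEM
            ((-0.2, 0.05), (+0.01, 0.02), Verdict.INCONCLUSIVE),
            ((0.0, 0.0), (0.0, 0.0), Verdict.INCONCLUSIVE),
        ],
    )
    def test_quadrant_and_sem_rules(self, dcv, dr2, expected):
        assert infer_change(dcv, dr2) is expected

    @given(
        m1=st.floats(-1, 1), s1=st.floats(0, 0.5),
        m2=st.floats(-1, 1), s2=st.floats(0, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_swap_consistency(self, m1, s1, m2, s2):
        """Exchanging the categories flips both means and mirrors the verdict."""
        fwd = infer_change((m1, s1), (m2, s2))
        rev = infer_change((-m1, s1), (-m2, s2))
        assert rev is fwd.swapped()

    def test_negative_sem_rejected(self):
        with pytest.raises(ValueError):
            infer_change((0.1, -0.01), (0.1, 0.01))


class TestCompareCategories:
    def test_area_axis_with_fix(self, study_tables):
        from facomp.preprocess import preprocess_study

        pre = preprocess_study(study_tables)
        stats = compare_categories(pre.tables, "area_cat", "S", "M")
        assert stats.verdict in set(Verdict)
        assert stats.n_datasets >= 1
        summary = stats.summary()
        assert {"delta_log_cv", "delta_r2", "verdict"} <= set(summary)


class TestEqualPixelControl:
    def _dataset(self, seed):
        """A label map with two area categories of uniform-density regions."""
        rng = np.random.default_rng(seed)
        labels = np.zeros((120, 240), dtype=np.int32)
        rows = []
        # 12 small (4x4) and 12 large (10x10) square adhesions
        for i in range(12):
            r0, c0 = 5 + (i % 4) * 28, 5 + (i // 4) * 70
            labels[r0 : r0 + 4, c0 : c0 + 4] = i + 1
            rows.append((i + 1, 16, "S"))
        for i in range(12):
            r0, c0 = 8 + (i % 4) * 28, 40 + (i // 4) * 70
            labels[r0 : r0 + 10, c0 : c0 + 10] = 13 + i
            rows.append((13 + i, 100, "L"))
        # densities: common factor + per-component noise, noisier for S
        div = np.exp(rng.normal(0, 0.4, 24))
        channels = []
        comp_names = ("P", "Q", "R")
        dens = {}
        for c in comp_names:
            noise = np.where(
                np.array([cat == "S" for _, _, cat in rows]),
                rng.normal(0, 0.45, 24),
                rng.normal(0, 0.1, 24),
            )
            dens[c] = 100 * div * np.exp(noise)
            img = np.zeros_like(labels, dtype=float)
            for (lab, _, _), d in zip(rows, dens[c]):
                img[labels == lab] = d
            channels.append(img)
        from facomp.imaging import LabelMap, measure_regions

        lm = LabelMap(labels)
        table = measure_regions(lm, channels, components=comp_names)
        table.data["area_cat"] = [cat for _, _, cat in rows]
        return lm, channels, table

    def test_full_subsample_reproduces_measured_densities(self):
        from facomp.imaging import measure_regions

        lm, channels, table = self._dataset(7)
        again = measure_regions(
            lm, channels, components=table.components,
            sample_pixels={int(l): 10_000 for l in table.data["adhesion_id"]},
            rng=np.random.default_rng(0),
        )
        np.testing.assert_allclose(again.raw, table.raw, atol=1e-12)

    @pytest.mark.parametrize("mode", ["mean", "fixed"])
    def test_verdict_survives_equal_pixel_sampling(self, mode):
        datasets = [self._dataset(seed) for seed in (7, 8, 9, 10)]
        for i, (lm, ch, t) in enumerate(datasets):
            t.dataset_id = f"R{i + 1}O1"
        stats = equal_pixel_control(
            datasets, "area_cat", "S", "L", mode=mode, seed=1
        )
        # noise was imposed lower in the large adhesions
        assert stats.verdict is Verdict.NOISE_LOWER_IN_2

    def test_fixed_seed_reproducible(self):
        datasets = [self._dataset(seed) for seed in (7, 8, 9, 10)]
        for i, (lm, ch, t) in enumerate(datasets):
            t.dataset_id = f"R{i + 1}O1"
        a = equal_pixel_control(datasets, "area_cat", "S", "L", mode="fixed", seed=3)
        b = equal_pixel_control(datasets, "area_cat", "S", "L", mode="fixed", seed=3)
        assert a.dlogcv.mean == b.dlogcv.mean
        assert a.dr2.mean == b.dr2.mean
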