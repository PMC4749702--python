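"""Synthetic generators: analytic fractals, tissue patterns, cohorts."""

import numpy as np
import pytest

from fractopath.errors import DegenerateInputError, PackingError, SpecError
from fractopath.global_dimensions import box_count, capacity_dimension
from fractopath.relations import D0_LAMBDA_COEFFS, fit_linear
from fractopath.stratification import classify_d0, restratify
from fractopath.synthetic import (
    CLASS_SIZES,
    TABLE_STATS,
    CohortSpec,
    PatternSpec,
    make_cascade,
    make_cohort,
    make_percolation,
    make_sierpinski,
    make_tissue_pattern,
)


class TestSierpinski:
    def test_depth_one(self):
        img = make_sierpinski(1)
        assert img.shape == (3, 3) and img.sum() == 8 and not img[1, 1]

    def test_depth_four_foreground(self):
        assert make_sierpinski(4).sum() == 8**4

    def test_box_counts_reproduce_construction(self):
        img = make_sierpinski(3)
        s = box_count(img, np.array([1, 3, 9, 27]))
        assert np.array_equal(s.n_boxes, [8**3, 8**2, 8, 1])

    @pytest.mark.parametrize("depth", [0, 7])
    def test_depth_out_of_range(self, depth):
        with pytest.raises(ValueError):
            make_sierpinski(depth)


class TestPercolation:
    def test_p_one_is_filled(self):
        img = make_percolation(3, 4, 1.0, seed=0)
        assert img.all()
        est = capacity_dimension(box_count(img, np.array([3, 9, 27])))
        assert est.value == pytest.approx(2.0, abs=1e-12)

    def test_p_zero_empty_downstream_error(self):
        img = make_percolation(3, 3, 0.0, seed=0)
        with pytest.raises(DegenerateInputError):
            box_count(img)

    def test_expected_dimension_seed_averaged(self):
        # E[D0] = log(9 * 0.9) / log 3 ~= 1.9037 for b=3, p=0.9
        target = np.log(8.1) / np.log(3)
        vals = []
        for seed in range(20):
            img = make_percolation(3, 5, 0.9, seed=seed)
            if img.sum() == 0:
                continue
            vals.append(
                capacity_dimension(box_count(img, np.array([3, 9, 27, 81]))).value
            )
        assert abs(np.mean(vals) - target) <= 0.1

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_percolation(1, 3, 0.5, seed=0)
        with pytest.raises(ValueError):
            make_percolation(3, 3, 1.5, seed=0)


class TestCascade:
    def test_shape_and_sampling_budget(self):
        img = make_cascade(levels=6, n_points=500, seed=0)
        assert img.shape == (64, 64)
        assert 0 < img.sum() <= 500  # dedup can only shrink the count

    def test_bad_weights(self):
        with pytest.raises(ValueError):
            make_cascade(weights=(0.5, 0.5, 0.5, 0.5))


class TestReproducibility:
    @pytest.mark.parametrize(
        "gen",
        [
            lambda s: make_percolation(3, 4, 0.8, seed=s),
            lambda s: make_cascade(levels=6, n_points=800, seed=s),
            lambda s: make_tissue_pattern(PatternSpec(kind="gland", seed=s)),
            lambda s: make_tissue_pattern(PatternSpec(kind="infiltrate", seed=s)),
        ],
    )
    def test_same_seed_bitwise_same_different_seed_differs(self, gen):
        assert np.array_equal(gen(11), gen(11))
        assert not np.array_equal(gen(11), gen(12))

    def test_cohort_reproducible(self):
        a = make_cohort(CohortSpec(seed=5))
        b = make_cohort(CohortSpec(seed=5))
        assert a.equals(b)


class TestTissuePatterns:
    def test_gland_below_infiltrate_capacity_dimension(self):
        for seed in (0, 1, 2):
            g = make_tissue_pattern(PatternSpec(kind="gland", seed=seed))
            i = make_tissue_pattern(PatternSpec(kind="infiltrate", seed=seed))
            d0_g = capacity_dimension(box_count(g)).value
            d0_i = capacity_dimension(box_count(i)).value
            assert d0_g < d0_i

    def test_dense_infiltrate_approaches_plane_filling(self):
        img = make_tissue_pattern(
            PatternSpec(kind="infiltrate", seed=0, n_dots=30000)
        )
        assert capacity_dimension(box_count(img)).value > 1.95

    def test_equal_density_pairing(self):
        g = make_tissue_pattern(PatternSpec(kind="gland", seed=3))
        i = make_tissue_pattern(
            PatternSpec(kind="infiltrate", seed=3, target_foreground=int(g.sum()))
        )
        assert abs(int(i.sum()) - int(g.sum())) / g.sum() < 0.02

    def test_degenerate_kinds(self):
        assert make_tissue_pattern(PatternSpec(kind="filled", size=(16, 16))).all()
        assert make_tissue_pattern(PatternSpec(kind="line", size=(16, 16))).sum() == 16
        assert make_tissue_pattern(PatternSpec(kind="point", size=(16, 16))).sum() == 1

    def test_packing_error(self):
        with pytest.raises(PackingError):
            make_tissue_pattern(
                PatternSpec(kind="gland", seed=0, n_glands=500, size=(200, 200))
            )

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_tissue_pattern(PatternSpec(kind="spiral"))


class TestCohort:
    def test_default_sizes_and_columns(self):
        df = make_cohort(CohortSpec(seed=0))
        assert len(df) == sum(CLASS_SIZES.values()) == 208
        assert df.complexity_class.value_counts().to_dict() == CLASS_SIZES
        for col in ("d0", "d1", "d2", "lfd_mean", "lcfd_mean", "h", "lam"):
            assert np.isfinite(df[col]).all()

    def test_c7_mean_within_three_stderr(self):
        spec = CohortSpec(seed=42, n_per_class={"C7": 200})
        df = make_cohort(spec)
        target = TABLE_STATS["d0"]["C7"][0]  # 1.7986
        se = df.d0.std(ddof=1) / np.sqrt(len(df))
        assert abs(df.d0.mean() - target) <= 3 * se

    def test_zero_noise_coupling_recovers_reference_relation(self):
        spec = CohortSpec(seed=1, noise_lambda=0.0)
        df = make_cohort(spec)
        fit = fit_linear(df.d0, df.lam)
        intercept, slope = D0_LAMBDA_COEFFS
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)

    def test_d0_d1_highly_correlated(self):
        df = make_cohort(CohortSpec(seed=2))
        assert np.corrcoef(df.d0, df.d1)[0, 1] >= 0.95

    def test_classification_round_trip(self):
        df = make_cohort(CohortSpec(seed=3))
        assert (classify_d0(df.d0.to_numpy()) == df.complexity_class).all()

    def test_restratify_fixed_point_on_cohort(self):
        df = make_cohort(CohortSpec(seed=4))
        res = restratify(df.d0.to_numpy(), df.complexity_class.to_numpy())
        assert res.n_reassigned == 0
        assert np.array_equal(res.assignments, df.complexity_class.to_numpy())

    def test_bph_group_optional(self):
        df = make_cohort(CohortSpec(seed=0, include_bph=True))
        assert (df.complexity_class == "BPH").sum() == 20

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_per_class={"C9": 5}),
            dict(n_per_class={"C1": -1}),
            dict(cutoffs=(1.6, 1.5, 1.7, 1.8, 1.85, 1.9)),
        ],
    )
    def test_spec_errors(self, bad):
        with pytest.raises(SpecError):
            make_cohort(CohortSpec(seed=0, **bad))
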