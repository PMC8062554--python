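"""RNA-seq unit conversions: hand-computed oracles and invariances."""

import numpy as np
import pandas as pd
import pytest

from crossclust import units
from crossclust.matrix import ExprMatrix


def frame(values, **kw):
    return pd.DataFrame(np.asarray(values, dtype=float), **kw)


class TestCpm:
    def test_hand_example(self):
        out = units.cpm(frame([[250], [750]])).data
        np.testing.assert_allclose(out.to_numpy().ravel(), [250000.0, 750000.0])

    def test_equal_counts_symmetry(self):
        out = units.cpm(frame(np.full((8, 3), 5))).data
        np.testing.assert_allclose(out.to_numpy(), 1e6 / 8)

    def test_scale_invariance(self, rng):
        counts = frame(rng.integers(1, 100, (30, 4)))
        scaled = counts.copy()
        scaled.iloc[:, 2] *= 10
        a = units.cpm(counts).data
        b = units.cpm(scaled).data
        np.testing.assert_allclose(a.iloc[:, 2], b.iloc[:, 2])

    def test_zero_library_names_sample(self):
        bad = frame([[1, 0], [2, 0]], columns=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            units.cpm(bad)


class TestRpkmFpkm:
    def test_rpkm_hand_examples(self):
        counts = frame([[1000], [999000]])
        lengths = pd.Series([1000.0, 10000.0], index=counts.index)
        out = units.rpkm(counts, lengths).data
        assert out.iloc[0, 0] == pytest.approx(1000.0)
        # CPM 100 at length 500 -> RPKM 200
        counts2 = frame([[100], [999900]])
        lengths2 = pd.Series([500.0, 1000.0], index=counts2.index)
        assert units.rpkm(counts2, lengths2).data.iloc[0, 0] == pytest.approx(200.0)

    def test_rpkm_length_proportionality(self, rng):
        counts = frame(rng.integers(1, 100, (10, 3)))
        lengths = pd.Series(rng.uniform(200, 5000, 10), index=counts.index)
        doubled = lengths.copy()
        doubled.iloc[4] *= 2
        a = units.rpkm(counts, lengths).data
        b = units.rpkm(counts, doubled).data
        np.testing.assert_allclose(b.iloc[4], a.iloc[4] / 2)

    def test_rpkm_missing_length(self):
        counts = frame([[1], [2]], index=["g1", "g2"])
        with pytest.raises(ValueError, match="g2"):
            units.rpkm(counts, pd.Series({"g1": 100.0}))

    def test_fpkm_reduces_to_rpkm(self):
        counts = frame([[100, 100], [999900, 999900]])
        lengths = pd.Series([2000.0, 1000.0], index=counts.index)
        sf = pd.Series(1.0, index=counts.columns)
        np.testing.assert_allclose(units.fpkm(counts, lengths, sf).data,
                                   units.rpkm(counts, lengths).data)

    def test_fpkm_hand_example(self):
        counts = frame([[100], [999900]])
        lengths = pd.Series([2000.0, 1000.0], index=counts.index)
        out = units.fpkm(counts, lengths, pd.Series([1.0], index=counts.columns))
        assert out.data.iloc[0, 0] == pytest.approx(50.0)

    def test_fpkm_size_factor_proportionality(self, rng):
        counts = frame(rng.integers(1, 200, (20, 3)))
        lengths = pd.Series(rng.uniform(300, 3000, 20), index=counts.index)
        sf = pd.Series([1.0, 1.0, 1.0], index=counts.columns)
        half = pd.Series([1.0, 1.0, 0.5], index=counts.columns)
        a = units.fpkm(counts, lengths, sf).data
        b = units.fpkm(counts, lengths, half).data
        np.testing.assert_allclose(b.iloc[:, 2], 2 * a.iloc[:, 2])


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = frame([[10, 10], [55, 55]])
        np.testing.assert_allclose(units.size_factors_median_ratio(counts), 1.0)

    def test_doubled_column_hand_example(self):
        counts = frame([[10, 20], [30, 60], [7, 14]])
        sf = units.size_factors_median_ratio(counts)
        np.testing.assert_allclose(sf.to_numpy(),
                                   [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_permutation_equivariance(self, rng):
        counts = frame(rng.integers(1, 500, (40, 5)),
                       columns=list("abcde"))
        sf = units.size_factors_median_ratio(counts)
        perm = counts[["d", "b", "a", "e", "c"]]
        sf_perm = units.size_factors_median_ratio(perm)
        np.testing.assert_allclose(sf_perm.to_numpy(),
                                   sf[["d", "b", "a", "e", "c"]].to_numpy())

    def test_no_common_positive_gene_errors(self):
        with pytest.raises(ValueError):
            units.size_factors_median_ratio(frame([[0, 1], [1, 0]]))


class TestShiftedLog:
    def test_hand_values(self):
        out = units.shifted_log(frame([[0, 7]]),
                                pd.Series([1.0, 1.0])).data.to_numpy().ravel()
        np.testing.assert_allclose(out, [0.0, 3.0])

    def test_monotone_in_counts(self):
        vals = units.shifted_log(frame([[0], [3], [9], [100]]),
                                 pd.Series([1.0])).data.to_numpy().ravel()
        assert (np.diff(vals) > 0).all()


class TestVst:
    def test_zero_maps_to_sample_minimum(self):
        counts = frame([[0, 5], [10, 2], [3, 0]])
        out = units.vst_closed_form(counts, size_factors=pd.Series([1.0, 1.0]),
                                    dispersion=0.1).data.to_numpy()
        assert out[0, 0] == out.min(axis=0)[0]

    def test_small_dispersion_approaches_sqrt_transform(self):
        x = np.arange(1, 200, 13, dtype=float)
        alpha = 1e-6
        v = units.vst_closed_form(frame(x[:, None]), size_factors=pd.Series([1.0]),
                                  dispersion=alpha).data.to_numpy().ravel()
        approx = 2 * np.sqrt(alpha * x) / np.log(2) - np.log2(4 * alpha)
        np.testing.assert_allclose(v, approx, atol=1e-4)

    def test_variance_stabilized_across_mean_levels(self):
        # NB replicates at means 2^4..2^10 should transform to near-equal spread
        rng = np.random.default_rng(11)
        alpha = 0.1
        sds = []
        for mean in [16, 64, 256, 1024]:
            lam = rng.gamma(1 / alpha, alpha * mean, 4000)
            counts = rng.poisson(lam)
            v = units.vst_closed_form(frame(counts[None, :]),
                                      size_factors=pd.Series(np.ones(4000)),
                                      dispersion=alpha).data.to_numpy().ravel()
            sds.append(v.std())
        sds = np.array(sds)
        assert sds.max() / sds.min() < 1.35

    def test_auto_dispersion_close_to_truth(self):
        rng = np.random.default_rng(12)
        alpha = 0.2
        mean = rng.uniform(50, 500, 300)
        lam = rng.gamma(1 / alpha, alpha * mean[:, None], (300, 40))
        counts = frame(rng.poisson(lam))
        est = units.estimate_common_dispersion(counts,
                                               size_factors=pd.Series(np.ones(40)))
        assert 0.1 < est < 0.4

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            units.vst_closed_form(frame(np.zeros((3, 2))),
                                  size_factors=pd.Series([1.0, 1.0]))


class TestVoomLogCpm:
    def test_hand_example(self):
        counts = frame([[0], [999999]])
        out = units.voom_logcpm(counts).data
        assert out.iloc[0, 0] == pytest.approx(-1.0)

    def test_matches_cpm_convention_for_large_libraries(self, rng):
        counts = frame(rng.integers(0, 2000, (50, 3)))
        counts.iloc[0] += 100000  # push library size over 1e5
        a = units.voom_logcpm(counts).data.to_numpy()
        b = np.log2(units.cpm(counts, prior_count=0.5).data.to_numpy())
        assert np.abs(a - b).max() < 1e-5

    def test_monotone_in_counts(self):
        out = units.voom_logcpm(frame([[0], [5], [50], [500]])).data.to_numpy().ravel()
        assert (np.diff(out) > 0).all()


class TestScaleToReference:
    def test_idempotent_on_reference(self, rng):
        ref = frame(rng.normal(5, 2, (20, 8)))
        out = units.scale_to_reference(ref, ref).data
        np.testing.assert_allclose(out, ref, atol=1e-10)

    def test_matches_reference_moments(self, rng):
        target = frame(rng.normal(0, 1, (30, 12)))
        ref = frame(rng.normal(7, 3, (30, 9)))
        out = units.scale_to_reference(target, ref).data
        np.testing.assert_allclose(out.mean(axis=1), ref.mean(axis=1), atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1),
                                   ref.std(axis=1, ddof=1), atol=1e-10)

    def test_constant_gene_maps_to_reference_mean(self, rng):
        target = frame(np.full((1, 6), 3.0))
        ref = frame(rng.normal(4, 1, (1, 6)))
        out = units.scale_to_reference(target, ref).data
        np.testing.assert_allclose(out.to_numpy(), ref.mean(axis=1).iloc[0])

    def test_disjoint_genes_error(self):
        with pytest.raises(ValueError):
            units.scale_to_reference(frame([[1.0]], index=["a"]),
                                     frame([[1.0]], index=["b"]))


def test_linear_units_invariant_to_sample_rescaling(rng):
    """CPM/RPKM/FPKM (p=0) don't change when a sample's counts are rescaled."""
    counts = frame(rng.integers(1, 300, (25, 4)))
    lengths = pd.Series(rng.uniform(200, 4000, 25), index=counts.index)
    scaled = counts * 3
    for func in (lambda c: units.cpm(c).data,
                 lambda c: units.rpkm(c, lengths).data):
        np.testing.assert_allclose(func(counts), func(scaled), rtol=1e-12)


def test_log_outputs_finite(rng):
    counts = frame(rng.integers(0, 50, (40, 6)))
    for out in (units.cpm(counts, prior_count=0.5, log_output=True),
                units.voom_logcpm(counts),
                units.shifted_log(counts, pd.Series(np.ones(6), index=counts.columns)),
                units.vst_closed_form(counts,
                                      size_factors=pd.Series(np.ones(6),
                                                             index=counts.columns),
                                      dispersion=0.1)):
        assert np.isfinite(out.data.to_numpy()).all()
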