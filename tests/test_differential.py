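"""Quantification, composition factors and the NB Wald test."""

import numpy as np
import pandas as pd
import pytest

from epinorm import (
    CountMatrix,
    DiffConfig,
    DifferentialBindingModel,
    RegionSet,
    SampleRecord,
    SampleSheet,
    SignalTrack,
    classify_and_export,
    filter_low_counts,
    nb_test,
    norm_factors,
    quantify_regions,
)
from epinorm.differential import classify

from conftest import CHROM_LEN, random_dense


def matrix_from_array(Y, samples=None, region_width=500):
    Y = np.asarray(Y)
    samples = samples or [f"s{i}" for i in range(Y.shape[1])]
    regions = RegionSet.from_intervals(
        [("c", i * 1000, i * 1000 + region_width) for i in range(Y.shape[0])]
    )
    return CountMatrix(
        regions=regions,
        data=pd.DataFrame(Y, index=regions.labels(), columns=samples),
    )


class TestQuantify:
    def test_uniform_region(self):
        t = SignalTrack({"chrA": ([0], [10], [2.0])})
        cm = quantify_regions({"s": t}, RegionSet.from_intervals([("chrA", 0, 10)]))
        assert cm.data.loc["chrA:0-10", "s"] == 20

    def test_region_without_signal_is_zero(self):
        t = SignalTrack({"chrA": ([100], [200], [2.0])})
        cm = quantify_regions({"s": t}, RegionSet.from_intervals([("chrA", 0, 50)]))
        assert cm.data.iloc[0, 0] == 0

    def test_matches_per_base_oracle(self, rng):
        for _ in range(20):
            arr = random_dense(rng)
            t = SignalTrack.from_dense({"chrA": arr})
            ivals = []
            for _ in range(6):
                s = int(rng.integers(0, CHROM_LEN - 1))
                ivals.append(("chrA", s, s + int(rng.integers(1, 300))))
            ivals = [(c, s, min(e, CHROM_LEN)) for c, s, e in ivals]
            rs = RegionSet.from_intervals(sorted(set(ivals)))
            cm = quantify_regions({"s": t}, rs)
            for (c, s, e), label in zip(rs.intervals(), rs.labels()):
                assert cm.data.loc[label, "s"] == round(arr[s:e].sum())


class TestNormFactors:
    def test_identical_columns_unit_factors(self):
        Y = np.tile([[10], [40], [100]], (1, 4))
        for method in ("rle", "tmm", "upperquartile", "none"):
            f = norm_factors(matrix_from_array(Y), method)
            assert np.allclose(f, 1.0)

    def test_pure_depth_difference_gives_unit_factors(self, rng):
        base = rng.integers(10, 500, size=(60, 1))
        Y = np.hstack([base, base * 2])  # depth handled by offsets, not factors
        for method in ("rle", "upperquartile"):
            f = norm_factors(matrix_from_array(Y), method)
            assert np.allclose(f, 1.0, atol=1e-9)

    def test_composition_shift_detected_by_rle(self, rng):
        # sample 2 spends half its reads on one runaway region
        base = rng.integers(50, 200, size=(100, 2)).astype(float)
        base[:, 1] = base[:, 0]
        Y = base.copy()
        Y[0, 1] += base[:, 0].sum()
        f = norm_factors(matrix_from_array(Y), "rle")
        # after depth normalization, ordinary regions of sample 2 look ~2x down
        assert f["s1"] / f["s0"] == pytest.approx(0.5, rel=0.1)

    def test_none_is_all_ones(self, rng):
        Y = rng.integers(0, 100, size=(30, 3))
        assert (norm_factors(matrix_from_array(Y), "none") == 1.0).all()

    def test_geometric_mean_is_one(self, rng):
        Y = rng.integers(1, 400, size=(80, 5))
        for method in ("rle", "tmm", "upperquartile"):
            f = norm_factors(matrix_from_array(Y), method).to_numpy()
            assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_rle_requires_allpositive_region(self):
        Y = np.array([[0, 5], [3, 0]])
        with pytest.raises(ValueError, match="RLE"):
            norm_factors(matrix_from_array(Y), "rle")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown scaling"):
            norm_factors(matrix_from_array(np.ones((3, 2))), "median")


class TestFilterLowCounts:
    def test_zero_threshold_identity(self, rng):
        cm = matrix_from_array(rng.integers(0, 50, size=(20, 3)))
        out = filter_low_counts(cm, 0)
        assert out.data.equals(cm.data)

    def test_row_sum_boundary(self):
        cm = matrix_from_array([[33, 33, 33], [34, 33, 33]])
        out = filter_low_counts(cm, 100)
        assert len(out) == 1
        assert out.data.iloc[0].sum() == 100

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            Y = rng.integers(0, 40, size=(30, 4))
            thr = int(rng.integers(0, 120))
            out = filter_low_counts(matrix_from_array(Y), thr)
            assert len(out) == sum(1 for row in Y if row.sum() >= thr)


class TestNBTest:
    def test_identical_counts_null_result(self, sheet_2x2):
        Y = np.tile([[100], [50], [200]], (1, 4))
        res = nb_test(matrix_from_array(Y, samples=[r.sample_id for r in sheet_2x2]),
                      sheet_2x2, ("A", "B"))
        assert np.allclose(res["log2fc"], 0.0, atol=1e-8)
        assert (res["pvalue"] > 0.99).all()

    def test_replicates_required(self, sheet_2x2):
        recs = list(sheet_2x2.records)[:3]  # only one B replicate
        sheet = SampleSheet(recs)
        Y = np.ones((5, 3), dtype=int) * 10
        cm = matrix_from_array(Y, samples=[r.sample_id for r in recs])
        with pytest.raises(ValueError, match="replicates required"):
            nb_test(cm, sheet, ("A", "B"))

    def test_contrast_swap_antisymmetry(self, sheet_4x4, rng):
        Y = rng.negative_binomial(10, 0.05, size=(200, 8))
        cm = matrix_from_array(Y, samples=[r.sample_id for r in sheet_4x4])
        ab = nb_test(cm, sheet_4x4, ("A", "B"))
        ba = nb_test(cm, sheet_4x4, ("B", "A"))
        assert np.allclose(ab["log2fc"], -ba["log2fc"], atol=1e-7)
        assert np.allclose(ab["pvalue"], ba["pvalue"], atol=1e-9)
        assert ((ab["class"] == "gain") == (ba["class"] == "loss")).all()

    def test_doubling_counts_preserves_log2fc_with_equal_libs(self, sheet_4x4, rng):
        base = rng.negative_binomial(10, 0.05, size=(150, 8)) + 1
        # equalize library sizes exactly
        base = (base / base.sum(axis=0, keepdims=True) * 50_000).round().astype(int)
        cm1 = matrix_from_array(base, samples=[r.sample_id for r in sheet_4x4])
        cm2 = matrix_from_array(base * 2, samples=[r.sample_id for r in sheet_4x4])
        f = norm_factors(cm1, "none")
        r1 = nb_test(cm1, sheet_4x4, ("A", "B"), factors=f)
        r2 = nb_test(cm2, sheet_4x4, ("A", "B"), factors=f)
        assert np.allclose(r1["log2fc"], r2["log2fc"], atol=1e-6)

    def test_bh_monotone_in_p_and_single_region_q_equals_p(self, sheet_4x4, rng):
        Y = rng.negative_binomial(10, 0.05, size=(300, 8))
        cm = matrix_from_array(Y, samples=[r.sample_id for r in sheet_4x4])
        res = nb_test(cm, sheet_4x4, ("A", "B"))
        order = np.argsort(res["pvalue"].to_numpy())
        q_sorted = res["qvalue"].to_numpy()[order]
        assert (np.diff(q_sorted) >= -1e-12).all()
        one = nb_test(
            matrix_from_array(Y[:1], samples=[r.sample_id for r in sheet_4x4]),
            sheet_4x4, ("A", "B"),
        )
        assert one["qvalue"].iloc[0] == pytest.approx(one["pvalue"].iloc[0])

    def test_global_loss_with_and_without_scaling(self, sheet_4x4, rng):
        """Halving every region in B: with offsets disabled the losses are
        visible everywhere; RLE re-centers them near zero — the rationale
        for offering scaling 'none'."""
        A = rng.negative_binomial(20, 0.09, size=(400, 4)) + 50
        B = np.maximum((A * 0.5).astype(int), 1)
        Y = np.hstack([A, B])
        cm = matrix_from_array(Y, samples=[r.sample_id for r in sheet_4x4])
        res_none = nb_test(cm, sheet_4x4, ("A", "B"),
                           factors=norm_factors(cm, "none"), use_offsets=False)
        assert (res_none["log2fc"] < 0).mean() > 0.95
        res_rle = nb_test(cm, sheet_4x4, ("A", "B"),
                          factors=norm_factors(cm, "rle"))
        assert abs(res_rle["log2fc"].median()) < 0.1

    def test_effect_recovery_median_error(self, sheet_4x4):
        rng = np.random.default_rng(77)
        R, mean, disp = 400, 200.0, 0.05
        mu = np.full((R, 8), mean)
        true_lfc = np.zeros(R)
        idx = rng.choice(R, 80, replace=False)
        folds = rng.choice([0.25, 0.5, 2.0, 4.0], size=80)
        mu[idx, 4:] *= folds[:, None]
        true_lfc[idx] = np.log2(folds)
        Y = rng.poisson(rng.gamma(1 / disp, mu * disp))
        cm = matrix_from_array(Y, samples=[r.sample_id for r in sheet_4x4])
        res = nb_test(cm, sheet_4x4, ("A", "B"), factors=norm_factors(cm, "rle"))
        err = np.abs(res["log2fc"].to_numpy() - true_lfc)
        assert np.median(err[idx]) < 0.2


class TestClassify:
    def test_toy_table(self):
        q = np.array([0.01, 0.01, 0.2])
        lfc = np.array([1.0, -1.0, 3.0])
        got = classify(q, lfc, alpha=0.05, lfc=0.58)
        assert got.tolist() == ["gain", "loss", "ns"]

    def test_lfc_zero_classifies_by_q_alone(self):
        q = np.array([0.01, 0.2, 0.01])
        lfc = np.array([0.0, 5.0, -0.1])
        got = classify(q, lfc, alpha=0.05, lfc=0.0)
        assert got.tolist() == ["gain", "ns", "loss"]

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            n = 50
            q = rng.uniform(0, 1, n)
            lfc = rng.normal(0, 2, n)
            a, thr = float(rng.uniform(0.01, 0.2)), float(rng.uniform(0, 1.5))
            got = classify(q, lfc, a, thr)
            for i in range(n):
                if q[i] < a and lfc[i] >= thr:
                    assert got[i] == "gain"
                elif q[i] < a and lfc[i] <= -thr:
                    assert got[i] == "loss"
                else:
                    assert got[i] == "ns"

    def test_export_partitions(self, tmp_path):
        df = pd.DataFrame(
            {
                "chrom": ["c", "c", "c"],
                "start": [0, 100, 200],
                "end": [50, 150, 250],
                "base_mean": [10.0, 10.0, 10.0],
                "log2fc": [1.0, -1.0, 3.0],
                "pvalue": [0.001, 0.001, 0.1],
                "qvalue": [0.01, 0.01, 0.2],
            },
            index=["c:0-50", "c:100-150", "c:200-250"],
        )
        paths = classify_and_export(df, alpha=0.05, lfc=0.58, out_dir=tmp_path)
        assert paths["gain"].read_text() == "c\t0\t50\n"
        assert paths["loss"].read_text() == "c\t100\t150\n"
        table = pd.read_csv(paths["table"], sep="\t")
        assert list(table["class"]) == ["gain", "loss", "ns"]


class TestModelResults:
    def test_fit_returns_results_with_summary(self, sheet_4x4, rng):
        Y = rng.negative_binomial(10, 0.05, size=(100, 8)) + 20
        cm = matrix_from_array(Y, samples=[r.sample_id for r in sheet_4x4])
        model = DifferentialBindingModel(
            cm, sheet_4x4, ("A", "B"), DiffConfig(method="edger-like", min_counts=50)
        )
        res = model.fit()
        text = res.summary()
        assert "edger-like / upperquartile" in text
        assert f"gain regions:        {res.n_gain}" in text
        assert set(res.table["class"]).issubset({"gain", "loss", "ns"})
        assert len(res.volcano_data()) == len(res.table)

    def test_method_labels_pick_scaling_defaults(self):
        assert DiffConfig(method="deseq2-like").scaling == "rle"
        assert DiffConfig(method="edger-like").scaling == "upperquartile"
        assert DiffConfig(method="edger-like", scaling="none").scaling == "none"

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DiffConfig(method="limma")
        with pytest.raises(ValueError):
            DiffConfig(alpha=1.5)
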