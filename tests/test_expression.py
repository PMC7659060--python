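"""geNorm stability, efficiency-corrected relative expression, temporal
pattern classification, candidate selection and the heatmap transform."""

import numpy as np
import pandas as pd
import pytest

from famsurvey.expression import (
    ExpressionMatrix,
    QpcrTable,
    classify_pattern,
    genorm_stability,
    heatmap_matrix,
    relative_expression,
    select_rns_candidates,
)
from famsurvey.io_formats import ValidationError


def make_qpcr(ct_by_gene: dict[str, list[float]], efficiency=2.0,
              replicates=1, noise=0.0, seed=0) -> QpcrTable:
    """Ct table from per-gene per-sample mean Ct values."""
    rng = np.random.default_rng(seed)
    n_samples = len(next(iter(ct_by_gene.values())))
    samples = [f"s{i}" for i in range(n_samples)]
    rows = []
    for gene, cts in ct_by_gene.items():
        for sample, ct in zip(samples, cts):
            for rep in range(1, replicates + 1):
                eps = rng.normal(0, noise) if noise else 0.0
                rows.append(
                    {"gene_id": gene, "sample_id": sample, "replicate": rep,
                     "ct": ct + eps, "efficiency": efficiency}
                )
    return QpcrTable(pd.DataFrame(rows))


class TestGenorm:
    def test_parallel_profiles_both_zero(self):
        q = make_qpcr({"r1": [20, 22, 24], "r2": [25, 27, 29]})
        results = genorm_stability(q, ["r1", "r2"])
        assert all(r.M == pytest.approx(0.0, abs=1e-12) for r in results)

    def test_hand_computed_toy_table(self):
        # 4 candidates x 5 samples; expected M computed step by step below
        ct = {
            "a": [20.0, 20.5, 21.0, 20.2, 20.8],
            "b": [22.0, 22.4, 23.1, 22.1, 22.9],
            "c": [18.0, 19.5, 18.2, 19.0, 18.4],
            "d": [25.0, 24.0, 26.0, 25.5, 24.5],
        }
        q = make_qpcr(ct, efficiency=2.0)
        results = {r.gene_id: r.M for r in genorm_stability(q, list(ct))}

        # independent spreadsheet-style recomputation
        quantities = {
            g: np.array([2.0 ** (min(v) - x) for x in v])
            for g, v in ct.items()
        }
        for gene in ct:
            sds = [
                np.std(np.log2(quantities[gene] / quantities[other]), ddof=1)
                for other in ct if other != gene
            ]
            assert results[gene] == pytest.approx(np.mean(sds), abs=1e-12)

    def test_ranking_ascending_in_m(self):
        ct = {
            "stable1": [20, 20.1, 19.9, 20.0, 20.05],
            "stable2": [22, 22.1, 21.9, 22.0, 22.05],
            "wild": [20, 25, 18, 23, 26],
        }
        results = genorm_stability(make_qpcr(ct), list(ct))
        assert [r.rank for r in results] == [1, 2, 3]
        assert results[-1].gene_id == "wild"
        assert results[0].M <= results[1].M <= results[2].M

    def test_constant_ct_shift_per_sample_invariant(self):
        ct = {
            "a": [20.0, 21.0, 19.5, 22.0],
            "b": [23.0, 22.5, 24.0, 23.5],
            "c": [18.0, 18.5, 19.0, 17.5],
        }
        shifted = {g: [x + s for x, s in zip(v, [1.0, -2.0, 0.5, 3.0])]
                   for g, v in ct.items()}
        m1 = {r.gene_id: r.M for r in
              genorm_stability(make_qpcr(ct), list(ct))}
        m2 = {r.gene_id: r.M for r in
              genorm_stability(make_qpcr(shifted), list(ct))}
        for gene in ct:
            assert m1[gene] == pytest.approx(m2[gene], abs=1e-9)

    def test_missing_candidate_sample_rejected(self):
        rows = pd.DataFrame([
            {"gene_id": "a", "sample_id": "s0", "replicate": 1,
             "ct": 20.0, "efficiency": 2.0},
            {"gene_id": "a", "sample_id": "s1", "replicate": 1,
             "ct": 21.0, "efficiency": 2.0},
            {"gene_id": "b", "sample_id": "s0", "replicate": 1,
             "ct": 22.0, "efficiency": 2.0},
        ])
        with pytest.raises(ValidationError, match="missing"):
            genorm_stability(QpcrTable(rows), ["a", "b"])


class TestRelativeExpression:
    def test_baseline_is_exactly_one(self):
        q = make_qpcr({"t": [24, 23, 22], "r": [20, 20, 20]})
        folds = relative_expression(q, "t", ["r"], "s0")
        assert folds.loc[folds.sample_id == "s0", "fold_change"].item() == 1.0

    def test_one_cycle_lower_doubles_with_e2(self):
        q = make_qpcr({"t": [24, 23], "r": [20, 20]})
        folds = relative_expression(q, "t", ["r"], "s0")
        assert folds.loc[folds.sample_id == "s1", "fold_change"].item() == (
            pytest.approx(2.0)
        )

    def test_matches_two_power_minus_ddct(self):
        rng = np.random.default_rng(3)
        ct = {
            "t": list(rng.uniform(20, 28, size=4)),
            "r1": list(rng.uniform(18, 24, size=4)),
            "r2": list(rng.uniform(18, 24, size=4)),
        }
        q = make_qpcr(ct, efficiency=2.0)
        folds = relative_expression(q, "t", ["r1", "r2"], "s0")
        ref_ct = (np.array(ct["r1"]) + np.array(ct["r2"])) / 2
        dct = np.array(ct["t"]) - ref_ct
        ddct = dct - dct[0]
        expected = 2.0 ** (-ddct)
        assert np.allclose(folds["fold_change"].to_numpy(), expected)

    def test_replicate_scatter_propagates_to_sd(self):
        q = make_qpcr({"t": [24, 22], "r": [20, 20]},
                      replicates=3, noise=0.3, seed=5)
        folds = relative_expression(q, "t", ["r"], "s0")
        assert folds.loc[folds.sample_id == "s0", "sd"].item() == 0.0
        assert folds.loc[folds.sample_id == "s1", "sd"].item() > 0.0

    def test_missing_sample_rejected(self):
        q = make_qpcr({"t": [24, 23], "r": [20, 20]})
        with pytest.raises(ValidationError):
            relative_expression(q, "t", ["r"], "s9")


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "folds,expected",
        [
            ([1, 1.2, 2.5, 4, 9], "senescence_up"),
            ([1, 0.4, 0.3, 0.2, 0.2], "development_down"),
            ([1, 3, 9, 3, 1], "mid_peak"),
            ([1, 0.25, 0.25, 1.5, 9], "down_then_up"),
            ([1, 3, 9, 27, 3], "up_then_down"),
            ([1, 10, 1, 1, 16], "bimodal"),
            ([1, 1.1, 0.9, 1.05, 1], "flat"),
        ],
    )
    def test_class_examples(self, folds, expected):
        assert classify_pattern(folds, 2.0).pattern == expected

    def test_peak_timepoint_reported(self):
        call = classify_pattern([1, 3, 9, 3, 1], 2.0)
        assert call.peak_timepoint == 2

    def test_scale_invariant(self):
        rng = np.random.default_rng(6)
        profiles = [
            [1, 2, 4, 8, 16], [1, 0.4, 0.2, 0.3, 4], [1, 3, 9, 3, 1],
            [1, 1, 1, 1, 1],
        ]
        for profile in profiles:
            base = classify_pattern(profile, 2.0).pattern
            for _ in range(5):
                k = float(rng.uniform(0.1, 20))
                scaled = [v * k for v in profile]
                assert classify_pattern(scaled, 2.0).pattern == base

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValidationError):
            classify_pattern([1, 2], 2.0)

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValidationError):
            classify_pattern([1, 0, 2], 2.0)


def make_matrix(values, sym=("T1", "T2"), nod=("N1", "N2")):
    genes = [f"g{i}" for i in range(len(values))]
    cols = list(sym) + list(nod)
    df = pd.DataFrame(values, index=genes, columns=cols)
    classes = {s: "symbiosis_tissue" for s in sym}
    classes.update({s: "nodule_stage" for s in nod})
    return ExpressionMatrix(values=df, sample_class=classes)


class TestSelectRns:
    def test_globally_maximal_gene_selected(self):
        m = make_matrix([[100, 100, 100, 100]] + [[1, 1, 1, 1]] * 7)
        assert select_rns_candidates(m, 0.75) == {"g0"}

    def test_high_in_one_class_only_not_selected(self):
        m = make_matrix([[100, 100, 1, 1]] + [[1, 1, 100, 100]]
                        + [[1, 1, 1, 1]] * 6)
        assert select_rns_candidates(m, 0.75) == set()

    def test_missing_tissue_class_rejected(self):
        df = pd.DataFrame([[1, 2]], index=["g0"], columns=["a", "b"])
        m = ExpressionMatrix(df, {"a": "symbiosis_tissue",
                                  "b": "symbiosis_tissue"})
        with pytest.raises(ValidationError, match="nodule_stage"):
            select_rns_candidates(m, 0.75)


class TestHeatmap:
    def test_all_zero_gene_stays_zero(self):
        m = make_matrix([[0, 0, 0, 0], [1, 2, 3, 4]])
        out, meta = heatmap_matrix(m)
        assert np.allclose(out.loc["g0"], 0.0)
        assert "log2" in meta["transform"]

    def test_constant_gene_centers_to_zero(self):
        m = make_matrix([[5, 5, 5, 5], [1, 2, 3, 4]])
        out, _ = heatmap_matrix(m)
        assert np.allclose(out.loc["g0"], 0.0)

    def test_row_means_zero(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.uniform(0, 50, size=(6, 4)))
        out, _ = heatmap_matrix(m)
        assert np.allclose(out.mean(axis=1), 0.0)


class TestContainers:
    def test_negative_expression_rejected(self):
        df = pd.DataFrame([[-1.0]], index=["g"], columns=["s"])
        with pytest.raises(ValidationError):
            ExpressionMatrix(df, {"s": "nodule_stage"})

    def test_bad_efficiency_rejected(self):
        df = pd.DataFrame([
            {"gene_id": "g", "sample_id": "s", "replicate": 1,
             "ct": 20.0, "efficiency": 2.5}
        ])
        with pytest.raises(ValidationError, match="efficiency"):
            QpcrTable(df)

    def test_matrix_tsv_round_trip(self, tmp_path):
        m = make_matrix([[1.5, 2, 3, 4], [5, 6, 7, 8]])
        path = tmp_path / "expr.tsv"
        m.to_tsv(path)
        back = ExpressionMatrix.from_tsv(path)
        assert back.sample_class == m.sample_class
        assert np.allclose(back.values.to_numpy(), m.values.to_numpy())
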