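"""Differential peak classification, motif statistics, peak-gene mapping."""

import numpy as np
import pandas as pd
import pytest

from lumishift.chromatin import (
    cap_peaks,
    classify_differential_peaks,
    expression_trend_test,
    map_peaks_to_genes,
    motif_cooccurrence_partition,
    motif_enrichment,
    tss_to_peak_distance,
)
from lumishift.config import ThresholdConfig
from tests.test_stats import hypergeom_tail_oracle


def _peaks(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "peak_id", "log2fc", "fdr"]
    )


class TestClassifyPeaks:
    @pytest.mark.parametrize(
        "lfc,fdr,expected",
        [
            (1.5, 0.01, "up"),
            (-1.5, 0.01, "down"),
            (0.0, 0.99, "unchanged"),   # FDR < 1 suffices inside the band
            (1.5, 0.2, "excluded"),     # fails the FDR gate outside the band
            (1.0, 0.2, "excluded"),     # boundary fold change, non-significant
        ],
    )
    def test_rules(self, lfc, fdr, expected):
        peaks = _peaks([("chr1", 0, 100, "p1", lfc, fdr)])
        classes, _ = classify_differential_peaks(peaks)
        assert classes["p1"] == expected

    def test_partition_exhaustive(self):
        rng = np.random.default_rng(0)
        n = 500
        peaks = _peaks(
            [
                ("chr1", i * 10, i * 10 + 5, f"p{i}", lfc, fdr)
                for i, (lfc, fdr) in enumerate(
                    zip(rng.normal(0, 1.5, n), rng.uniform(0, 1, n))
                )
            ]
        )
        classes, counts = classify_differential_peaks(peaks)
        assert sum(counts.values()) == n
        assert set(classes.unique()) <= {"up", "down", "unchanged", "excluded"}


class TestCapPeaks:
    def test_within_cap_identity(self):
        peaks = _peaks([("chr1", i, i + 5, f"p{i}", 0.0, 0.5) for i in range(10)])
        assert cap_peaks(peaks, ThresholdConfig(peak_cap=10)) is peaks

    def test_oversize_sampled_to_cap_preserving_order(self):
        peaks = _peaks([("chr1", i, i + 5, f"p{i}", 0.0, 0.5) for i in range(200)])
        cfg = ThresholdConfig(peak_cap=50)
        out = cap_peaks(peaks, cfg, seed=1)
        assert len(out) == 50
        idx = [int(p[1:]) for p in out["peak_id"]]
        assert idx == sorted(idx)
        again = cap_peaks(peaks, cfg, seed=1)
        assert out.equals(again)
        assert not out.equals(cap_peaks(peaks, cfg, seed=2))


def _hits(rows):
    return pd.DataFrame(rows).set_index("peak_id")


class TestMotifEnrichment:
    def test_score_bounds(self):
        hits = _hits(
            [{"peak_id": f"p{i}", "M": i < 10} for i in range(20)]
        )
        out = motif_enrichment(
            [f"p{i}" for i in range(10)], [f"p{i}" for i in range(10, 20)], hits
        ).set_index("motif")
        assert out.loc["M", "score"] == pytest.approx(100.0)

    def test_no_difference_scores_zero(self):
        hits = _hits([{"peak_id": f"p{i}", "M": i % 2 == 0} for i in range(20)])
        fg = [f"p{i}" for i in range(10)]
        bg = [f"p{i}" for i in range(10, 20)]
        out = motif_enrichment(fg, bg, hits).set_index("motif")
        assert out.loc["M", "score"] == pytest.approx(0.0)

    def test_fisher_matches_enumeration(self):
        rows = [{"peak_id": f"f{i}", "M": i < 8} for i in range(10)]
        rows += [{"peak_id": f"b{i}", "M": i < 2} for i in range(10)]
        out = motif_enrichment(
            [f"f{i}" for i in range(10)], [f"b{i}" for i in range(10)], _hits(rows)
        ).set_index("motif")
        assert out.loc["M", "score"] == pytest.approx(60.0)
        assert out.loc["M", "p"] == pytest.approx(
            hypergeom_tail_oracle(8, 2, 2, 8), abs=1e-10
        )

    def test_overlapping_sets_rejected(self):
        hits = _hits([{"peak_id": "p1", "M": True}, {"peak_id": "p2", "M": False}])
        with pytest.raises(ValueError):
            motif_enrichment(["p1"], ["p1", "p2"], hits)


class TestCooccurrence:
    def test_direct_counting(self):
        rows = [
            {"peak_id": "p1", "A": True, "B": False},
            {"peak_id": "p2", "A": False, "B": True},
            {"peak_id": "p3", "A": True, "B": True},
            {"peak_id": "p4", "A": True, "B": False},
        ]
        part = motif_cooccurrence_partition(
            [r["peak_id"] for r in rows], _hits(rows), "A", "B"
        )
        assert (part.a_only, part.b_only, part.both) == (2, 1, 1)
        assert sum(part.fractions.values()) == pytest.approx(1.0)

    def test_swap_symmetry(self):
        rows = [
            {"peak_id": "p1", "A": True, "B": False},
            {"peak_id": "p2", "A": False, "B": True},
            {"peak_id": "p3", "A": True, "B": True},
        ]
        ids = [r["peak_id"] for r in rows]
        ab = motif_cooccurrence_partition(ids, _hits(rows), "A", "B")
        ba = motif_cooccurrence_partition(ids, _hits(rows), "B", "A")
        assert (ab.a_only, ab.b_only) == (ba.b_only, ba.a_only)
        assert ab.both == ba.both

    def test_empty_restriction_rejected(self):
        rows = [{"peak_id": "p1", "A": False, "B": False}]
        with pytest.raises(ValueError):
            motif_cooccurrence_partition(["p1"], _hits(rows), "A", "B")


class TestPeakGeneMapping:
    def test_distance_convention(self):
        assert tss_to_peak_distance(5000, 7500, 7800) == 2500
        assert tss_to_peak_distance(5000, 8001, 8200) == 3001
        assert tss_to_peak_distance(7600, 7500, 7800) == 0
        assert tss_to_peak_distance(8000, 7500, 7800) == 201

    def test_window_boundary(self):
        genes = pd.DataFrame(
            {"gene": ["G1", "G2"], "chrom": "chr1", "tss": [5000, 5000], "strand": "+"}
        )
        cfg = ThresholdConfig(min_sites_per_gene=1)
        near = _peaks([("chr1", 8000, 8200, "p1", 0, 0.5)])
        far = _peaks([("chr1", 8001, 8200, "p1", 0, 0.5)])
        assert len(map_peaks_to_genes(near, genes, cfg)) == 2
        assert map_peaks_to_genes(far, genes, cfg).empty

    def test_min_sites_rule(self):
        genes = pd.DataFrame({"gene": ["G1"], "chrom": "chr1", "tss": [5000], "strand": "+"})
        one = _peaks([("chr1", 5100, 5200, "p1", 0, 0.5)])
        two = _peaks(
            [
                ("chr1", 5100, 5200, "p1", 0, 0.5),
                ("chr1", 3000, 3400, "p2", 0, 0.5),
            ]
        )
        assert map_peaks_to_genes(one, genes).empty
        mapped = map_peaks_to_genes(two, genes)
        assert list(mapped["gene"]) == ["G1"]
        assert list(mapped["n_sites"]) == [2]

    def test_chromosome_mismatch_rejected(self):
        genes = pd.DataFrame({"gene": ["G1"], "chrom": "1", "tss": [5000], "strand": "+"})
        peaks = _peaks([("chr1", 5100, 5200, "p1", 0, 0.5)])
        with pytest.raises(ValueError, match="chromosome"):
            map_peaks_to_genes(peaks, genes)


class TestExpressionTrend:
    def test_identical_conditions_null(self):
        expr = pd.DataFrame(
            {"parental": [1.0, 2.0, 3.0], "two_month": [1.0, 2.0, 3.0], "resistant": [1.0, 2.0, 3.0]},
            index=["A", "B", "C"],
        )
        with pytest.warns(UserWarning):
            out = expression_trend_test({"s": ["A", "B", "C"]}, expr)
        assert (out["p"] == 1.0).all()

    def test_swapped_conditions_flip_effect_sign(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(30)]
        base = rng.normal(size=30)
        expr = pd.DataFrame(
            {"parental": base, "two_month": base + 1.0 + rng.normal(0, 0.1, 30), "resistant": base + 2.0},
            index=genes,
        )
        fwd = expression_trend_test({"s": genes}, expr)
        rev = expression_trend_test(
            {"s": genes}, expr, conditions=("resistant", "two_month", "parental")
        )
        f = fwd.set_index(["from", "to"])
        r = rev.set_index(["from", "to"])
        assert f.loc[("parental", "resistant"), "median_change"] == pytest.approx(
            -r.loc[("resistant", "parental"), "median_change"]
        )
        assert f.loc[("parental", "resistant"), "p"] == pytest.approx(
            r.loc[("resistant", "parental"), "p"]
        )

    def test_planted_trend_detected(self, chromatin_data):
        out = expression_trend_test(
            {k: list(v) for k, v in chromatin_data.planted_trend_genes.items()},
            chromatin_data.trend_expr,
        )
        full = out[(out["from"] == "parental") & (out["to"] == "resistant")]
        assert (full["p"] < 0.01).all()
        assert (full["median_change"] > 0).all()

    def test_missing_gene_rejected(self):
        expr = pd.DataFrame(
            {"parental": [1.0], "two_month": [1.0], "resistant": [1.0]}, index=["A"]
        )
        with pytest.raises(ValueError):
            expression_trend_test({"s": ["A", "MISSING"]}, expr)
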