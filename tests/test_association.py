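"""Differential expression, preranked GSEA, logistic association, TF enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from lumishift.association import (
    SEPARATION_SENTINEL,
    differential_expression_paired,
    gsea_preranked,
    response_gene_association,
    tf_enrichment,
)
from lumishift.signatures import GeneSignature
from tests.test_stats import hypergeom_tail_oracle


def _pairs(n):
    return {f"b{i}": f"t{i}" for i in range(n)}


def _matrix(values, prefix):
    n_genes, n_samples = values.shape
    return pd.DataFrame(
        values,
        index=[f"g{j}" for j in range(n_genes)],
        columns=[f"{prefix}{i}" for i in range(n_samples)],
    )


class TestPairedDE:
    def test_no_change_means_no_calls(self):
        rng = np.random.default_rng(0)
        base = _matrix(rng.normal(size=(20, 5)), "b")
        treated = base.copy()
        treated.columns = [f"t{i}" for i in range(5)]
        de = differential_expression_paired(base, treated, _pairs(5))
        assert np.allclose(de["log2fc"], 0.0)
        assert not de["significant"].any()

    def test_exact_constant_shift(self):
        rng = np.random.default_rng(1)
        base = _matrix(rng.normal(size=(3, 4)), "b")
        treated = base + 2.0
        treated.columns = [f"t{i}" for i in range(4)]
        de = differential_expression_paired(base, treated, _pairs(4))
        assert np.allclose(de["log2fc"], 2.0)

    def test_unpaired_samples_rejected(self):
        rng = np.random.default_rng(2)
        base = _matrix(rng.normal(size=(3, 4)), "b")
        treated = _matrix(rng.normal(size=(3, 4)), "t")
        with pytest.raises(ValueError, match="unpaired"):
            differential_expression_paired(base, treated, {"b0": "t9", "b9": "t0", "b1": "t1"})

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(3)
        n_pairs, n_null, n_hit = 10, 300, 30
        base = rng.normal(7, 1, size=(n_null + n_hit, n_pairs))
        noise = rng.normal(0, 0.5, size=base.shape)
        treated = base + noise
        treated[:n_hit] -= 1.5
        de = differential_expression_paired(
            _matrix(base, "b"), _matrix(treated, "t"), _pairs(n_pairs)
        )
        flagged = set(de[de["significant"]]["gene"])
        planted = {f"g{j}" for j in range(n_hit)}
        assert len(flagged & planted) >= 27
        assert len(flagged - planted) <= max(1, int(0.05 * len(flagged)))


def gsea_es_oracle(metric: pd.Series, genes, weight=0.0) -> float:
    """Literal running-sum enrichment score, computed step by step."""
    order = sorted(metric.index, key=lambda g: (-metric[g], str(g)))
    hits = {str(g).upper() for g in genes}
    w = {g: (abs(metric[g]) ** weight if weight else 1.0) for g in order}
    denom = sum(w[g] for g in order if str(g).upper() in hits)
    n_miss = len(order) - len([g for g in order if str(g).upper() in hits])
    running, best = 0.0, 0.0
    for g in order:
        if str(g).upper() in hits:
            running += w[g] / denom
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestGseaPreranked:
    def test_top_ranked_set_maximally_enriched(self):
        rng = np.random.default_rng(4)
        metric = pd.Series(rng.normal(size=100), index=[f"g{j}" for j in range(100)])
        top5 = metric.sort_values(ascending=False).index[:5]
        res = gsea_preranked(metric, [GeneSignature("top", tuple(top5))], n_perm=1000, seed=0)
        assert res[0].es > 0
        assert res[0].p <= 2 / 1001 + 1e-12

    def test_es_matches_brute_force_running_sum(self):
        metric = pd.Series(
            [3.0, 2.5, 2.0, 1.0, -0.5, -1.0, -2.0, -3.0],
            index=list("ABCDEFGH"),
        )
        sig = GeneSignature("s", ("B", "C", "G"))
        res = gsea_preranked(metric, [sig], n_perm=50, seed=0, weight=0.0)
        assert res[0].es == pytest.approx(gsea_es_oracle(metric, sig.genes), abs=1e-12)

    def test_unit_weight_invariant_to_monotone_rescale(self):
        rng = np.random.default_rng(5)
        metric = pd.Series(rng.normal(size=40), index=[f"g{j}" for j in range(40)])
        sig = GeneSignature("s", tuple(metric.index[::5]))
        es1 = gsea_preranked(metric, [sig], n_perm=10, seed=1, weight=0.0)[0].es
        es2 = gsea_preranked(np.exp(metric / 3), [sig], n_perm=10, seed=1, weight=0.0)[0].es
        assert es1 == pytest.approx(es2)

    def test_leading_edge_contains_top_hits(self):
        metric = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0, 0.5], index=list("ABCDEF"))
        res = gsea_preranked(metric, [GeneSignature("s", ("A", "B", "F"))], n_perm=20, seed=0)
        assert "A" in res[0].leading_edge and "B" in res[0].leading_edge

    def test_tiny_set_skipped_with_warning(self):
        metric = pd.Series([1.0, 0.5, -0.5], index=list("ABC"))
        with pytest.warns(UserWarning):
            res = gsea_preranked(metric, [GeneSignature("s", ("A", "ZZZ"))], n_perm=10)
        assert res == []


def _assoc_data(seed=0, n=60, n_genes=8):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    labels = pd.Series(["Resp" if i < n // 2 else "NR" for i in range(n)], index=samples)
    expr = pd.DataFrame(
        rng.normal(size=(n_genes, n)),
        index=[f"g{j}" for j in range(n_genes)],
        columns=samples,
    )
    cov = pd.DataFrame(
        {"arm": rng.choice(["mono", "combo"], size=n)}, index=samples
    )
    return expr, labels, cov


class TestResponseGeneAssociation:
    def test_signal_gene_detected_with_positive_log2_odds(self):
        expr, labels, cov = _assoc_data(seed=1)
        expr.loc["g0"] += (labels == "Resp") * 2.0
        out = response_gene_association(expr, labels, cov).set_index("gene")
        assert out.loc["g0", "log2_odds"] > 0
        assert out.loc["g0", "p"] < 0.01

    def test_perfect_separation_sentinel(self):
        expr, labels, cov = _assoc_data(seed=2)
        expr.loc["g1"] = (labels == "Resp").astype(float) * 1.0
        out = response_gene_association(expr, labels, cov).set_index("gene")
        assert out.loc["g1", "separated"]
        assert out.loc["g1", "log2_odds"] == SEPARATION_SENTINEL
        assert math.isnan(out.loc["g1", "p"])

    def test_label_swap_flips_sign(self):
        expr, labels, cov = _assoc_data(seed=3)
        swapped = labels.map({"NR": "Resp", "Resp": "NR"})
        a = response_gene_association(expr, labels, cov).set_index("gene")["log2_odds"]
        b = response_gene_association(expr, swapped, cov).set_index("gene")["log2_odds"]
        assert np.allclose(a, -b, atol=1e-8)

    def test_single_class_rejected(self):
        expr, labels, cov = _assoc_data(seed=4)
        with pytest.raises(ValueError):
            response_gene_association(expr, pd.Series("Resp", index=labels.index), cov)

    def test_confounded_signal_absorbed_by_covariate(self):
        # arm fully explains the labels; genes correlated with arm only
        rng = np.random.default_rng(6)
        n = 80
        samples = [f"s{i}" for i in range(n)]
        arm = np.array(["mono"] * (n // 2) + ["combo"] * (n // 2))
        labels = pd.Series(np.where(arm == "mono", "NR", "Resp"), index=samples)
        expr = pd.DataFrame(
            rng.normal(size=(6, n)) + (arm == "combo") * 0.8,
            index=[f"g{j}" for j in range(6)],
            columns=samples,
        )
        cov = pd.DataFrame({"arm": arm}, index=samples)
        out = response_gene_association(expr, labels, cov)
        clean = out[~out["separated"]]
        assert (clean["fdr"] > 0.05).all()


class TestTfEnrichment:
    def test_targets_equal_query(self):
        universe = [f"g{j}" for j in range(50)]
        query = universe[:10]
        out = tf_enrichment(query, {"TF1": set(query)}, universe).set_index("tf")
        assert out.loc["TF1", "odds_ratio"] == math.inf
        assert out.loc["TF1", "p"] < 1e-6

    def test_disjoint_targets(self):
        universe = [f"g{j}" for j in range(50)]
        out = tf_enrichment(
            universe[:10], {"TF1": set(universe[20:30])}, universe
        ).set_index("tf")
        assert out.loc["TF1", "odds_ratio"] <= 1.0
        assert out.loc["TF1", "p"] >= 0.5

    def test_p_matches_hypergeometric_oracle(self):
        universe = [f"g{j}" for j in range(100)]
        query = universe[:10]
        targets = universe[2:10] + universe[50:62]  # overlap 8, 20 targets
        out = tf_enrichment(query, {"TF1": targets}, universe).set_index("tf")
        assert out.loc["TF1", "n_overlap"] == 8
        expected = hypergeom_tail_oracle(8, 2, 12, 78)
        assert out.loc["TF1", "p"] == pytest.approx(expected, abs=1e-10)

    def test_top_k_selection_and_query_validation(self):
        universe = [f"g{j}" for j in range(60)]
        lib = {f"TF{k}": universe[k : k + 15] for k in range(5)}
        out = tf_enrichment(universe[:15], lib, universe)
        assert out["selected"].sum() <= 10
        with pytest.raises(ValueError):
            tf_enrichment(["NOT_IN_UNIVERSE"], lib, universe)
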