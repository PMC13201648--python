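"""Expression-response association statistics.

Four analyses on bulk expression matrices:

* paired differential expression (on-treatment vs baseline) with a
  per-gene paired t-test on log2 values;
* preranked gene-set enrichment (classic weighted Kolmogorov-Smirnov
  running sum, gene-label permutation null);
* per-gene logistic association of response with standardized expression,
  adjusting for treatment arm and intrinsic subtype, reported in
  log2-odds units;
* transcription-factor target enrichment via one-sided Fisher tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .config import ThresholdConfig
from .signatures import GeneSignature
from .stats import TwoByTwoTable, bh_fdr, fisher_exact_one_sided

__all__ = [
    "differential_expression_paired",
    "GseaResult",
    "gsea_preranked",
    "response_gene_association",
    "tf_enrichment",
    "SEPARATION_SENTINEL",
]

_LN2 = float(np.log(2.0))

#: log2-odds value reported for a gene with complete separation
SEPARATION_SENTINEL = float("inf")


# ---------------------------------------------------------------------------
# paired differential expression
# ---------------------------------------------------------------------------

def differential_expression_paired(
    base: pd.DataFrame,
    treated: pd.DataFrame,
    pairs: dict[str, str],
    cfg: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Per-gene paired differential expression on log2-scale matrices.

    ``pairs`` maps baseline sample id -> treated sample id. For each gene,
    log2FC is the mean paired difference (treated - baseline) and the
    p-value comes from a two-sided paired t-test; FDR is Benjamini-
    Hochberg. A gene is flagged significant at |log2FC| >= de_lfc_cut and
    fdr < de_fdr_cut. Genes with zero variance of differences get p = 1
    when the shift is zero and p = 0 otherwise.
    """
    cfg = cfg or ThresholdConfig()
    if len(pairs) < 3:
        raise ValueError("need at least 3 baseline/treated pairs")
    missing_base = [s for s in pairs if s not in base.columns]
    missing_treated = [s for s in pairs.values() if s not in treated.columns]
    if missing_base or missing_treated:
        raise ValueError(
            f"unpaired samples: baseline missing {missing_base}, "
            f"treated missing {missing_treated}"
        )
    genes = base.index.intersection(treated.index)
    if genes.empty:
        raise ValueError("no shared genes between matrices")
    b = base.loc[genes, list(pairs.keys())].to_numpy(dtype=float)
    t = treated.loc[genes, list(pairs.values())].to_numpy(dtype=float)
    diff = t - b
    n = diff.shape[1]
    lfc = diff.mean(axis=1)
    sd = diff.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = lfc / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(tstat), df=n - 1)
    degenerate = sd == 0
    p[degenerate & (lfc == 0)] = 1.0
    p[degenerate & (lfc != 0)] = 0.0
    out = pd.DataFrame({"gene": genes, "log2fc": lfc, "p": p})
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = (np.abs(out["log2fc"]) >= cfg.de_lfc_cut) & (
        out["fdr"] < cfg.de_fdr_cut
    )
    return out


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GseaResult:
    name: str
    es: float
    nes: float
    p: float
    fdr: float
    n_genes: int
    leading_edge: tuple[str, ...]


def _es_from_hits(hit_idx: np.ndarray, w: np.ndarray, n_genes: int):
    """Enrichment score(s) from sorted hit positions in a ranked list.

    ``hit_idx``: (P, k) int array of hit positions per permutation, each
    row ascending. ``w``: per-position weights |metric|^p over the ranked
    universe. Returns (es, argpos) where argpos is the rank index at which
    the extremum is attained.
    """
    k = hit_idx.shape[1]
    if k >= n_genes:
        raise ValueError("gene set must be a strict subset of the universe")
    miss = 1.0 / (n_genes - k)
    wh = w[hit_idx]
    cw = np.cumsum(wh, axis=1)
    denom = cw[:, -1:]
    if np.any(denom == 0):
        raise ValueError("all hit weights are zero; use unit weights instead")
    j = np.arange(k)
    drift = (hit_idx - j) * miss
    s_after = cw / denom - drift
    s_before = (cw - wh) / denom - drift
    mx = s_after.max(axis=1)
    mn = s_before.min(axis=1)
    take_pos = mx >= -mn
    es = np.where(take_pos, mx, mn)
    arg = np.where(take_pos, s_after.argmax(axis=1), s_before.argmin(axis=1))
    return es, arg


def gsea_preranked(
    ranked: pd.Series,
    sets: list[GeneSignature],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> list[GseaResult]:
    """Preranked gene-set enrichment with a gene-label permutation null.

    Genes are ordered by decreasing metric (ties broken by symbol for
    determinism). Hits increment the running sum proportionally to
    |metric|^weight (uniformly when ``weight`` is 0); misses decrement
    uniformly. ES is the maximum deviation from zero; NES divides ES by
    the mean magnitude of same-sign permutation scores; the permutation p
    is the sign-matched tail probability doubled and capped at 1. Sets
    with fewer than 2 genes in the universe are skipped with a warning.
    """
    if not np.isfinite(ranked.to_numpy(dtype=float)).all():
        raise ValueError("ranking metric must be finite")
    order = sorted(ranked.index, key=lambda g: (-ranked[g], str(g)))
    metric = ranked.loc[order].to_numpy(dtype=float)
    n_genes = len(order)
    w = np.abs(metric) ** weight if weight != 0 else np.ones(n_genes)
    pos_of = {str(g).strip().upper(): i for i, g in enumerate(order)}
    rng = np.random.default_rng(seed)

    results: list[GseaResult] = []
    pvals: list[float] = []
    for sig in sets:
        hits = sorted(
            pos_of[g] for g in (str(x).strip().upper() for x in sig.genes) if g in pos_of
        )
        if len(hits) < 2:
            warnings.warn(
                f"set {sig.name!r}: fewer than 2 genes in universe; skipped",
                stacklevel=2,
            )
            continue
        k = len(hits)
        obs = np.array([hits])
        es, arg = _es_from_hits(obs, w, n_genes)
        es, arg = float(es[0]), int(arg[0])
        # permutation null: random gene labels, same set size
        perm = np.empty((n_perm, k), dtype=np.int64)
        for i in range(n_perm):
            perm[i] = rng.choice(n_genes, size=k, replace=False)
        perm.sort(axis=1)
        es_perm, _ = _es_from_hits(perm, w, n_genes)
        if es >= 0:
            same = es_perm[es_perm >= 0]
            n_extreme = int(np.sum(es_perm >= es))
        else:
            same = es_perm[es_perm < 0]
            n_extreme = int(np.sum(es_perm <= es))
        p = min(1.0, 2.0 * (1 + n_extreme) / (1 + n_perm))
        denom_nes = float(np.mean(np.abs(same))) if len(same) else float("nan")
        nes = es / denom_nes if denom_nes and np.isfinite(denom_nes) else float("nan")
        if es >= 0:
            le = tuple(order[i] for i in hits if i <= hits[arg])
        else:
            le = tuple(order[i] for i in hits if i >= hits[arg])
        results.append(GseaResult(sig.name, es, nes, p, float("nan"), k, le))
        pvals.append(p)
    if results:
        fdrs = bh_fdr(np.array(pvals))
        results = [
            GseaResult(r.name, r.es, r.nes, r.p, float(f), r.n_genes, r.leading_edge)
            for r, f in zip(results, fdrs)
        ]
    return results


# ---------------------------------------------------------------------------
# logistic response association
# ---------------------------------------------------------------------------

def response_gene_association(
    expr: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    cfg: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Per-gene logistic association between response and expression.

    ``labels`` holds "NR"/"Resp" per sample; ``covariates`` optional factor
    columns (e.g. arm, subtype) dummy-encoded internally. Expression is
    standardized per gene, so coefficients are log-odds per SD; they are
    reported divided by ln 2 as log2-odds. Genes with complete separation
    or non-convergent fits carry a signed infinity sentinel and NaN p.
    Enrichment group calls use fdr < de_fdr_cut with the coefficient sign
    (positive = Resp-enriched).
    """
    cfg = cfg or ThresholdConfig()
    labels = labels.loc[expr.columns]
    classes = set(labels.unique())
    if not classes <= {"NR", "Resp"}:
        raise ValueError(f"labels must be NR/Resp, got {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError("both NR and Resp must be present")
    if len(labels) < 10:
        raise ValueError("need at least 10 samples")
    y = (labels == "Resp").astype(float).to_numpy()
    base_cols = [np.ones(len(y))]
    if covariates is not None:
        dummies = pd.get_dummies(
            covariates.loc[expr.columns].astype("category"), drop_first=True
        )
        base_cols.extend(dummies[c].to_numpy(dtype=float) for c in dummies.columns)
    base_x = np.column_stack(base_cols)

    records = []
    x = np.empty((len(y), base_x.shape[1] + 1))
    x[:, 1:] = base_x
    for gene in expr.index:
        v = expr.loc[gene].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            records.append((gene, 0.0, np.nan, False))
            continue
        x[:, 0] = (v - v.mean()) / sd
        coef = np.nan
        p = np.nan
        separated = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
            coef = float(fit.params[0])
            p = float(fit.pvalues[0])
            if not fit.mle_retvals.get("converged", False) or abs(coef) > 15:
                separated = True
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separated = True
        if separated:
            sign = 1.0 if np.nanmean(v[y == 1]) >= np.nanmean(v[y == 0]) else -1.0
            records.append((gene, sign * SEPARATION_SENTINEL, np.nan, True))
        else:
            records.append((gene, coef / _LN2, p, False))

    out = pd.DataFrame(records, columns=["gene", "log2_odds", "p", "separated"])
    out["fdr"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "fdr"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["group"] = "none"
    sig = ok & (out["fdr"] < cfg.de_fdr_cut)
    out.loc[sig & (out["log2_odds"] > 0), "group"] = "Resp-enriched"
    out.loc[sig & (out["log2_odds"] < 0), "group"] = "NR-enriched"
    return out


# ---------------------------------------------------------------------------
# TF-target enrichment
# ---------------------------------------------------------------------------

def tf_enrichment(
    query,
    library: dict[str, set[str] | list[str]],
    universe,
    cfg: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Enrichment of a query gene list in TF target sets over a universe.

    For each TF, a 2x2 of query membership x target membership is tested
    one-sided for enrichment. Returns one row per TF with odds ratio,
    Fisher p, BH FDR, overlap genes, and a ``selected`` flag marking the
    top ``tf_top_k`` TFs by odds ratio among those with fdr < de_fdr_cut.
    """
    cfg = cfg or ThresholdConfig()
    if not library:
        raise ValueError("TF library is empty")
    uni = {str(g).strip().upper() for g in universe}
    q = {str(g).strip().upper() for g in query}
    if not q <= uni:
        raise ValueError(f"query genes outside universe: {sorted(q - uni)[:5]}")
    rows = []
    for tf, targets in library.items():
        t = {str(g).strip().upper() for g in targets} & uni
        a = len(q & t)
        b = len(q - t)
        c = len(t - q)
        d = len(uni) - a - b - c
        res = fisher_exact_one_sided(TwoByTwoTable(a, b, c, d), haldane=cfg.haldane)
        rows.append(
            {
                "tf": tf,
                "odds_ratio": res.odds_ratio,
                "p": res.p,
                "n_overlap": a,
                "n_targets": len(t),
                "overlap_genes": ",".join(sorted(q & t)),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["selected"] = False
    eligible = out[out["fdr"] < cfg.de_fdr_cut].sort_values(
        ["odds_ratio", "p"], ascending=[False, True]
    )
    out.loc[eligible.index[: cfg.tf_top_k], "selected"] = True
    return out.sort_values("p", ignore_index=True)
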