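"""Differential chromatin peak classification and motif analyses.

Peaks follow the BED convention (0-based, half-open). Differential classes
use per-peak log2 fold change (resistant vs parental) and FDR from an
upstream differential-binding analysis. Motif enrichment is the percent of
foreground peaks with a motif minus the percent of background peaks with
it, alongside a one-sided Fisher p; co-occurrence partitions classify
peaks carrying motif A only, motif B only, or both. Peak-to-gene mapping
uses the distance from a gene's TSS to the peak interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ThresholdConfig
from .stats import TwoByTwoTable, bh_fdr, fisher_exact_one_sided, wilcoxon_paired_two_sided

__all__ = [
    "classify_differential_peaks",
    "cap_peaks",
    "motif_enrichment",
    "CooccurrencePartition",
    "motif_cooccurrence_partition",
    "map_peaks_to_genes",
    "expression_trend_test",
]

_PEAK_COLS = ("chrom", "start", "end", "peak_id", "log2fc", "fdr")


def _check_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    missing = set(_PEAK_COLS) - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError("peaks must satisfy start < end")
    return peaks


def classify_differential_peaks(
    peaks: pd.DataFrame, cfg: ThresholdConfig | None = None
) -> tuple[pd.Series, dict[str, int]]:
    """Classify peaks up / down / unchanged / excluded.

    up: log2FC >= +cut and fdr < fdr_cut; down: log2FC <= -cut and
    fdr < fdr_cut; unchanged: -cut < log2FC < cut at any FDR below 1
    (effectively no FDR filter); excluded: everything else (large fold
    change that misses the FDR gate, or boundary fold changes). Returns
    per-peak classes and the class counts.
    """
    cfg = cfg or ThresholdConfig()
    _check_peaks(peaks)
    lfc = peaks["log2fc"].to_numpy(dtype=float)
    fdr = peaks["fdr"].to_numpy(dtype=float)
    if not (np.isfinite(lfc).all() and np.isfinite(fdr).all()):
        raise ValueError("log2fc and fdr must be finite")
    cls = np.full(len(peaks), "excluded", dtype=object)
    cls[(lfc >= cfg.de_lfc_cut) & (fdr < cfg.de_fdr_cut)] = "up"
    cls[(lfc <= -cfg.de_lfc_cut) & (fdr < cfg.de_fdr_cut)] = "down"
    cls[(np.abs(lfc) < cfg.de_lfc_cut) & (fdr < 1.0)] = "unchanged"
    classes = pd.Series(cls, index=peaks["peak_id"].to_numpy(), name="peak_class")
    counts = classes.value_counts().to_dict()
    for k in ("up", "down", "unchanged", "excluded"):
        counts.setdefault(k, 0)
    return classes, counts


def cap_peaks(
    peaks: pd.DataFrame, cfg: ThresholdConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Down-sample a peak set to at most ``peak_cap`` rows.

    Identity when already within the cap; otherwise a seeded uniform
    sample without replacement of exactly ``peak_cap`` peaks, keeping the
    original row order.
    """
    cfg = cfg or ThresholdConfig()
    if len(peaks) <= cfg.peak_cap:
        return peaks
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    keep = np.sort(rng.choice(len(peaks), size=cfg.peak_cap, replace=False))
    return peaks.iloc[keep]


def _hit_lookup(hits: pd.DataFrame) -> pd.DataFrame:
    if "peak_id" in hits.columns:
        hits = hits.set_index("peak_id")
    return hits.astype(bool)


def motif_enrichment(
    fg, bg, hits: pd.DataFrame, cfg: ThresholdConfig | None = None
) -> pd.DataFrame:
    """Per-motif foreground-vs-background enrichment.

    ``hits`` is a peak x motif boolean table. For each motif: pct_tp is
    the percentage of foreground peaks with the motif, pct_fp the same in
    the background, score = pct_tp - pct_fp (in [-100, 100]), p the
    one-sided Fisher test on the 2x2, fdr Benjamini-Hochberg across
    motifs.
    """
    cfg = cfg or ThresholdConfig()
    fg = list(fg)
    bg = list(bg)
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    if set(fg) & set(bg):
        raise ValueError("foreground and background must be disjoint")
    table = _hit_lookup(hits)
    missing = (set(fg) | set(bg)) - set(table.index)
    if missing:
        raise ValueError(f"peaks absent from motif-hit table: {sorted(missing)[:5]}")
    f = table.loc[fg]
    b = table.loc[bg]
    rows = []
    for motif in table.columns:
        tp = int(f[motif].sum())
        fp = int(b[motif].sum())
        pct_tp = 100.0 * tp / len(fg)
        pct_fp = 100.0 * fp / len(bg)
        res = fisher_exact_one_sided(
            TwoByTwoTable(tp, len(fg) - tp, fp, len(bg) - fp), haldane=cfg.haldane
        )
        rows.append(
            {
                "motif": motif,
                "pct_tp": pct_tp,
                "pct_fp": pct_fp,
                "score": pct_tp - pct_fp,
                "odds_ratio": res.odds_ratio,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


@dataclass(frozen=True)
class CooccurrencePartition:
    a_only: int
    b_only: int
    both: int

    @property
    def total(self) -> int:
        return self.a_only + self.b_only + self.both

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {
            "a_only": self.a_only / t,
            "b_only": self.b_only / t,
            "both": self.both / t,
        }


def motif_cooccurrence_partition(
    peaks, hits: pd.DataFrame, motif_a: str, motif_b: str
) -> CooccurrencePartition:
    """Partition peaks carrying motif A and/or B into exclusive categories.

    Restricted to peaks with at least one of the two motifs; the three
    fractions (A only, B only, both) sum to 1 over that restriction.
    """
    table = _hit_lookup(hits)
    for m in (motif_a, motif_b):
        if m not in table.columns:
            raise ValueError(f"motif {m!r} not in hit table")
    sub = table.loc[list(peaks), [motif_a, motif_b]]
    has_a = sub[motif_a].to_numpy()
    has_b = sub[motif_b].to_numpy()
    either = has_a | has_b
    if not either.any():
        raise ValueError("no peak carries either motif; partition undefined")
    return CooccurrencePartition(
        a_only=int((has_a & ~has_b).sum()),
        b_only=int((~has_a & has_b).sum()),
        both=int((has_a & has_b).sum()),
    )


def tss_to_peak_distance(tss: int, start: int, end: int) -> int:
    """Distance (bp) from a TSS to a half-open interval; 0 if inside."""
    if start <= tss < end:
        return 0
    if tss < start:
        return start - tss
    return tss - end + 1


def map_peaks_to_genes(
    peaks: pd.DataFrame, genes: pd.DataFrame, cfg: ThresholdConfig | None = None
) -> pd.DataFrame:
    """Genes proximal to at least ``min_sites_per_gene`` peaks.

    A gene is proximal to a peak when the distance from its TSS to the
    peak interval (0 inside the peak) is at most ``gene_window`` bp;
    strand is ignored. Returns the retained genes with their proximal-site
    counts. Raises if the chromosome vocabularies of the two inputs are
    disjoint.
    """
    cfg = cfg or ThresholdConfig()
    if not {"chrom", "start", "end"} <= set(peaks.columns):
        raise ValueError("peak table needs chrom, start, end")
    if not {"gene", "chrom", "tss"} <= set(genes.columns):
        raise ValueError("gene table needs gene, chrom, tss")
    pk_chroms = set(peaks["chrom"].unique())
    gn_chroms = set(genes["chrom"].unique())
    if not pk_chroms & gn_chroms:
        raise ValueError(
            f"no shared chromosome names: peaks {sorted(pk_chroms)[:5]} vs "
            f"genes {sorted(gn_chroms)[:5]}"
        )
    rows = []
    for chrom, gsub in genes.groupby("chrom"):
        psub = peaks[peaks["chrom"] == chrom]
        if psub.empty:
            continue
        starts = psub["start"].to_numpy(dtype=np.int64)
        ends = psub["end"].to_numpy(dtype=np.int64)
        for _, g in gsub.iterrows():
            tss = int(g["tss"])
            dist = np.where(
                (starts <= tss) & (tss < ends),
                0,
                np.where(tss < starts, starts - tss, tss - ends + 1),
            )
            n_sites = int((dist <= cfg.gene_window).sum())
            if n_sites >= cfg.min_sites_per_gene:
                rows.append({"gene": g["gene"], "n_sites": n_sites})
    return pd.DataFrame(rows, columns=["gene", "n_sites"])


def expression_trend_test(
    gene_sets: dict[str, list[str]],
    expr: pd.DataFrame,
    conditions: tuple[str, str, str] = ("parental", "two_month", "resistant"),
) -> pd.DataFrame:
    """Paired trend tests of gene expression across three conditions.

    ``expr`` is genes x conditions. For each named gene set and each of
    the three condition pairs, a paired two-sided Wilcoxon signed-rank
    test across the set's genes, with the median paired difference as the
    effect direction.
    """
    for c in conditions:
        if c not in expr.columns:
            raise ValueError(f"condition column {c!r} missing from expression table")
    pairs = [
        (conditions[0], conditions[1]),
        (conditions[0], conditions[2]),
        (conditions[1], conditions[2]),
    ]
    rows = []
    for name, gene_list in gene_sets.items():
        missing = [g for g in gene_list if g not in expr.index]
        if missing:
            raise ValueError(f"set {name!r}: genes missing from table: {missing[:5]}")
        sub = expr.loc[gene_list]
        for c0, c1 in pairs:
            before = sub[c0].to_numpy(dtype=float)
            after = sub[c1].to_numpy(dtype=float)
            res = wilcoxon_paired_two_sided(before, after)
            rows.append(
                {
                    "gene_set": name,
                    "from": c0,
                    "to": c1,
                    "n_genes": len(gene_list),
                    "median_change": float(np.median(after - before)),
                    "p": res.p,
                }
            )
    return pd.DataFrame(rows)
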