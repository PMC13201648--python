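"""Synthetic cohorts with planted effects.

Every input the pipeline consumes can be generated here, with known ground
truth: a clinical trial cohort with survival and paired expression (planted
responder/non-responder signature shifts and a planted hazard contrast),
read pileups at planted allele fractions, IHC intensity tables, and a
synthetic chromosome of accessibility peaks with planted motif structure
and expression trends. All generators are pure functions of their config
and seed.

Default cohort conditions mirror a phase-1a/b biomarker setting: 54
baseline biopsies split evenly between a responder-like, luminal-high
latent state and a non-responder-like, luminal-low state (the monotherapy
biomarker subset of such trials is balanced, and 30-50% of patients
progress by the first scan); 30% receive a CDK4/6-inhibitor combination;
median progression-free survival is 6 months in the luminal-low state
versus 22 in the luminal-high state (hazard ratio 6/22); a 138-sample ER+
reference cohort is emitted for z-normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signatures import ERA_INDUCED, ERA_REPRESSED, LUMINAL_TF, MAPK_TARGETS

__all__ = [
    "CohortSimConfig",
    "CohortData",
    "simulate_cohort",
    "simulate_pileups",
    "simulate_ihc",
    "ChromatinSimConfig",
    "ChromatinData",
    "simulate_peaks_and_motifs",
    "write_cohort",
    "write_chromatin",
]


# ---------------------------------------------------------------------------
# clinical cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """Conditions for the synthetic trial cohort.

    ``sig_effect`` is the planted mean shift (z-units of the background
    noise) applied to estrogen-induced and luminal-TF genes in responders
    and to MAPK-target genes in non-responders. ``hazard_ratio`` is the
    responder-vs-non-responder event hazard ratio; with exponential
    survival, median PFS scales as 1/hazard, so the default 6/22
    reproduces a 22-versus-6-month median contrast.
    """

    n_patients: int = 54
    frac_nr: float = 0.50
    frac_combo: float = 0.30
    sig_effect: float = 1.0
    hazard_ratio: float = 6.0 / 22.0
    median_pfs_lumlow: float = 6.0
    censor_rate: float = 0.2
    n_background_genes: int = 500
    noise_sd: float = 1.0
    n_reference: int = 138
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_nr", "frac_combo", "censor_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.n_reference < 2:
            raise ValueError("n_reference must be >= 2")


@dataclass(frozen=True)
class CohortData:
    clinical: pd.DataFrame
    expr_baseline: pd.DataFrame
    expr_c2d8: pd.DataFrame
    reference: pd.DataFrame
    pairs: dict[str, str]  # baseline sample id -> on-treatment sample id


def _gene_universe(n_background: int) -> list[str]:
    genes: list[str] = []
    for sig in (ERA_INDUCED, ERA_REPRESSED, LUMINAL_TF, MAPK_TARGETS):
        for g in sig.genes:
            if g not in genes:
                genes.append(g)
    genes.extend(f"BG{i:04d}" for i in range(1, n_background + 1))
    return genes


def simulate_cohort(config: CohortSimConfig | None = None) -> CohortData:
    """Simulate a trial cohort with paired expression and survival.

    Responders carry ``+sig_effect`` on estrogen-induced and luminal-TF
    genes at baseline; non-responders carry ``+sig_effect`` on MAPK-target
    genes. On-treatment (C2D8) profiles of responders lose the
    estrogen-induced boost, emulating on-target drug effect. Survival is
    exponential per latent group with independent uniform censoring. The
    clinical table carries the latent group as ``true_group``.
    """
    cfg = config or CohortSimConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    patients = [f"P{i:03d}" for i in range(1, n + 1)]
    responder = rng.random(n) >= cfg.frac_nr
    arm = np.where(rng.random(n) < cfg.frac_combo, "combo", "mono")
    prior = rng.random(n) < np.where(arm == "combo", 0.05, 0.30)

    rate_nr = math.log(2.0) / cfg.median_pfs_lumlow
    rate = np.where(responder, cfg.hazard_ratio * rate_nr, rate_nr)
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(n) < cfg.censor_rate
    pfs = np.where(censored, rng.random(n) * t_event, t_event)
    event = (~censored).astype(int)

    cbor = np.where(
        responder,
        rng.choice(["CR", "PR", "SD"], size=n, p=[0.1, 0.5, 0.4]),
        "PD",
    )

    clinical = pd.DataFrame(
        {
            "patient": patients,
            "arm": arm,
            "pfs_months": np.round(pfs, 3),
            "event": event,
            "cbor": cbor,
            "prior_cdk46i": prior.astype(int),
            "true_group": np.where(responder, "responder", "non-responder"),
        }
    )

    genes = _gene_universe(cfg.n_background_genes)
    gidx = {g: i for i, g in enumerate(genes)}
    mu = rng.normal(7.0, 1.0, size=len(genes))

    resp_boost = np.zeros(len(genes))
    for g in set(ERA_INDUCED.genes) | set(LUMINAL_TF.genes):
        resp_boost[gidx[g]] = cfg.sig_effect
    nr_boost = np.zeros(len(genes))
    for g in MAPK_TARGETS.genes:
        nr_boost[gidx[g]] = cfg.sig_effect
    era_idx = np.array([gidx[g] for g in ERA_INDUCED.genes])

    mean_base = mu[:, None] + np.where(responder, 1.0, 0.0) * resp_boost[:, None]
    mean_base += np.where(responder, 0.0, 1.0) * nr_boost[:, None]
    base = mean_base + rng.normal(0.0, cfg.noise_sd, size=(len(genes), n))

    mean_c2d8 = mean_base.copy()
    mean_c2d8[np.ix_(era_idx, np.nonzero(responder)[0])] -= cfg.sig_effect
    c2d8 = mean_c2d8 + rng.normal(0.0, cfg.noise_sd, size=(len(genes), n))

    ref = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(len(genes), cfg.n_reference))

    expr_baseline = pd.DataFrame(base, index=genes, columns=patients)
    c2d8_cols = [f"{p}_C2D8" for p in patients]
    expr_c2d8 = pd.DataFrame(c2d8, index=genes, columns=c2d8_cols)
    reference = pd.DataFrame(
        ref, index=genes, columns=[f"REF{i:03d}" for i in range(1, cfg.n_reference + 1)]
    )
    return CohortData(
        clinical=clinical,
        expr_baseline=expr_baseline,
        expr_c2d8=expr_c2d8,
        reference=reference,
        pairs=dict(zip(patients, c2d8_cols)),
    )


# ---------------------------------------------------------------------------
# pileups and IHC
# ---------------------------------------------------------------------------

def simulate_pileups(
    vaf_table: pd.DataFrame, depth: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Binomial read pileups at planted allele fractions.

    ``vaf_table`` needs columns sample, gene, variant, vaf and may carry a
    per-row depth column overriding the scalar ``depth``. Returns one
    pileup row per input row with mutant reads drawn Binomial(depth, vaf).
    """
    required = {"sample", "gene", "variant", "vaf"}
    missing = required - set(vaf_table.columns)
    if missing:
        raise ValueError(f"vaf_table missing columns: {sorted(missing)}")
    vafs = vaf_table["vaf"].to_numpy(dtype=float)
    if ((vafs < 0) | (vafs > 1)).any():
        raise ValueError("vaf values must lie in [0, 1]")
    if "depth" in vaf_table.columns:
        depths = vaf_table["depth"].to_numpy(dtype=np.int64)
    else:
        depths = np.full(len(vaf_table), int(depth), dtype=np.int64)
    if (depths < 0).any():
        raise ValueError("depths must be non-negative")
    rng = np.random.default_rng(seed)
    mut = rng.binomial(depths, vafs)
    return pd.DataFrame(
        {
            "sample": vaf_table["sample"].to_numpy(),
            "gene": vaf_table["gene"].to_numpy(),
            "variant": vaf_table["variant"].to_numpy(),
            "depth": depths,
            "mut_reads": mut,
        }
    )


def simulate_ihc(
    n_samples: int,
    concentration=(2.0, 2.0, 2.0, 2.0),
    seed: int = 0,
    group: str = "all",
) -> pd.DataFrame:
    """Dirichlet-distributed IHC intensity tables.

    ``concentration`` is the 4-vector of Dirichlet parameters for the
    0/1+/2+/3+ buckets; zero entries pin the corresponding bucket at 0%,
    so a one-hot vector puts all mass at one intensity. Percentages sum
    to 100 per sample.
    """
    alpha = np.asarray(concentration, dtype=float)
    if alpha.shape != (4,) or (alpha < 0).any() or alpha.sum() == 0:
        raise ValueError("concentration must be 4 non-negative values, not all zero")
    rng = np.random.default_rng(seed)
    # gamma draws with shape 0 are exactly 0, supporting degenerate buckets
    draws = np.stack([rng.gamma(a, 1.0, size=n_samples) if a > 0 else np.zeros(n_samples) for a in alpha], axis=1)
    pct = 100.0 * draws / draws.sum(axis=1, keepdims=True)
    out = pd.DataFrame(pct, columns=["pct0", "pct1", "pct2", "pct3"])
    out.insert(0, "sample", [f"{group}_{i:03d}" for i in range(1, n_samples + 1)])
    out.insert(1, "group", group)
    return out


# ---------------------------------------------------------------------------
# chromatin peaks, motifs, and expression trends
# ---------------------------------------------------------------------------

def _default_motif_probs() -> dict[str, dict[str, float]]:
    # Per-class motif occurrence probabilities. Repressed ("down") peaks are
    # enriched for the ERα motif mostly without FOXA1; induced ("up") peaks
    # for FOX/TEAD/MEF2/STAT motifs mostly without ERα.
    return {
        "ESR1": {"down": 0.78, "up": 0.18, "unchanged": 0.15},
        "FOXA1": {"down": 0.24, "up": 0.50, "unchanged": 0.20},
        "FOXM1": {"down": 0.10, "up": 0.45, "unchanged": 0.12},
        "TEAD1": {"down": 0.08, "up": 0.40, "unchanged": 0.10},
        "MEF2B": {"down": 0.08, "up": 0.35, "unchanged": 0.10},
        "STAT5B": {"down": 0.08, "up": 0.35, "unchanged": 0.10},
    }


@dataclass(frozen=True)
class ChromatinSimConfig:
    """Conditions for the synthetic chromatin landscape.

    One synthetic chromosome of 0-based half-open peaks. ``frac_up`` and
    ``frac_down`` plant the differential classes (gains outnumber losses,
    as seen after long-term ERα inhibition); ``motif_probs`` gives
    per-class motif occurrence probabilities; ``trend_effect`` is the
    planted expression shift per condition step (parental -> 2-month ->
    resistant) for genes placed near co-occurring FOXA1+partner sites.
    """

    n_peaks: int = 6000
    n_genes: int = 800
    chrom_length: int = 60_000_000
    frac_up: float = 0.25
    frac_down: float = 0.06
    peak_width: int = 400
    motif_probs: dict[str, dict[str, float]] = field(default_factory=_default_motif_probs)
    trend_effect: float = 1.0
    trend_noise_sd: float = 0.3
    n_planted_genes: int = 50  # per co-occurrence pair
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_up < 0 or self.frac_down < 0 or self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up/frac_down must be non-negative with sum <= 1")
        for motif, probs in self.motif_probs.items():
            for cls, p in probs.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"motif_probs[{motif}][{cls}] outside [0, 1]")
        if self.n_peaks < 1 or self.n_genes < 1:
            raise ValueError("n_peaks and n_genes must be positive")
        if self.peak_width < 1 or self.peak_width >= self.chrom_length:
            raise ValueError("peak_width must be in [1, chrom_length)")


@dataclass(frozen=True)
class ChromatinData:
    peaks: pd.DataFrame        # chrom,start,end,peak_id,log2fc,fdr,true_class
    motif_hits: pd.DataFrame   # peak_id x motif boolean
    genes: pd.DataFrame        # gene,chrom,tss,strand
    trend_expr: pd.DataFrame   # genes x (parental, two_month, resistant)
    planted_trend_genes: dict[str, tuple[str, ...]]

    #: co-occurrence pairs planted near genes (FOXA1 with each partner)
    PAIRS = (("FOXA1", "MEF2B"), ("FOXA1", "TEAD1"), ("FOXA1", "STAT5B"))


_CHROM = "chrS"


def _stats_for_class(cls: np.ndarray, rng: np.random.Generator):
    n = len(cls)
    lfc = np.empty(n)
    fdr = np.empty(n)
    up = cls == "up"
    down = cls == "down"
    unch = cls == "unchanged"
    lfc[up] = rng.uniform(1.2, 3.0, up.sum())
    lfc[down] = -rng.uniform(1.2, 3.0, down.sum())
    lfc[unch] = rng.uniform(-0.95, 0.95, unch.sum())
    fdr[up | down] = rng.uniform(1e-6, 0.049, (up | down).sum())
    fdr[unch] = rng.uniform(0.0, 0.99, unch.sum())
    return lfc, fdr


def simulate_peaks_and_motifs(config: ChromatinSimConfig | None = None) -> ChromatinData:
    """Synthetic peaks, motif hits, gene annotation, and trend expression.

    Background peaks are placed uniformly on one synthetic chromosome and
    assigned up/down/unchanged classes with per-class differential stats
    and Bernoulli motif occurrences. For each planted gene, two extra
    "up" peaks carrying FOXA1 plus one partner motif are placed within the
    proximity window of its TSS, and the gene's expression rises by
    ``trend_effect`` per condition step.
    """
    cfg = config or ChromatinSimConfig()
    rng = np.random.default_rng(cfg.seed)
    motifs = list(cfg.motif_probs)

    # background peaks
    cls = rng.choice(
        ["down", "unchanged", "up"],
        size=cfg.n_peaks,
        p=[cfg.frac_down, 1.0 - cfg.frac_down - cfg.frac_up, cfg.frac_up],
    )
    starts = np.sort(
        rng.integers(0, cfg.chrom_length - cfg.peak_width, size=cfg.n_peaks)
    )
    lfc, fdr = _stats_for_class(cls, rng)
    hit_rows = {
        m: rng.random(cfg.n_peaks) < np.vectorize(cfg.motif_probs[m].get)(cls)
        for m in motifs
    }

    # genes
    gene_names = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    tss = rng.integers(0, cfg.chrom_length, size=cfg.n_genes)
    strand = rng.choice(["+", "-"], size=cfg.n_genes)

    # planted co-occurrence peaks near selected genes
    n_plant_total = cfg.n_planted_genes * len(ChromatinData.PAIRS)
    if n_plant_total > cfg.n_genes:
        raise ValueError("n_planted_genes exceeds the gene budget")
    planted_order = rng.permutation(cfg.n_genes)[:n_plant_total]
    planted_sets: dict[str, tuple[str, ...]] = {}
    extra = {
        "start": [], "cls": [], "hits": {m: [] for m in motifs},
    }
    up_probs = {m: cfg.motif_probs[m]["up"] for m in motifs}
    for i, (anchor, partner) in enumerate(ChromatinData.PAIRS):
        lo = i * cfg.n_planted_genes
        sel = planted_order[lo: lo + cfg.n_planted_genes]
        planted_sets[f"{anchor}+{partner}"] = tuple(gene_names[j] for j in sel)
        for j in sel:
            for offset in (-1500, 800):  # both within a 3 kb window of the TSS
                s = int(np.clip(tss[j] + offset, 0, cfg.chrom_length - cfg.peak_width))
                extra["start"].append(s)
                extra["cls"].append("up")
                for m in motifs:
                    if m in (anchor, partner):
                        extra["hits"][m].append(True)
                    else:
                        extra["hits"][m].append(rng.random() < up_probs[m])

    n_extra = len(extra["start"])
    all_starts = np.concatenate([starts, np.array(extra["start"], dtype=np.int64)])
    all_cls = np.concatenate([cls, np.array(extra["cls"], dtype=object)])
    lfc_x, fdr_x = _stats_for_class(np.array(extra["cls"], dtype=object), rng)
    all_lfc = np.concatenate([lfc, lfc_x])
    all_fdr = np.concatenate([fdr, fdr_x])
    peak_ids = [f"peak_{i:06d}" for i in range(1, cfg.n_peaks + n_extra + 1)]

    peaks = pd.DataFrame(
        {
            "chrom": _CHROM,
            "start": all_starts,
            "end": all_starts + cfg.peak_width,
            "peak_id": peak_ids,
            "log2fc": all_lfc,
            "fdr": all_fdr,
            "true_class": all_cls,
        }
    )
    motif_hits = pd.DataFrame(
        {m: np.concatenate([hit_rows[m], np.array(extra["hits"][m], dtype=bool)]) for m in motifs},
        index=pd.Index(peak_ids, name="peak_id"),
    )
    genes = pd.DataFrame(
        {"gene": gene_names, "chrom": _CHROM, "tss": tss, "strand": strand}
    )

    planted_mask = np.zeros(cfg.n_genes, dtype=bool)
    planted_mask[planted_order] = True
    base = rng.normal(7.0, 1.0, size=cfg.n_genes)
    step = np.where(planted_mask, cfg.trend_effect, 0.0)
    noise = rng.normal(0.0, cfg.trend_noise_sd, size=(cfg.n_genes, 3))
    trend_expr = pd.DataFrame(
        {
            "parental": base + noise[:, 0],
            "two_month": base + step + noise[:, 1],
            "resistant": base + 2.0 * step + noise[:, 2],
        },
        index=gene_names,
    )
    return ChromatinData(
        peaks=peaks,
        motif_hits=motif_hits,
        genes=genes,
        trend_expr=trend_expr,
        planted_trend_genes=planted_sets,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cohort(data: CohortData, outdir: str | Path) -> None:
    """Write cohort files: clinical.csv, expression/reference TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data.clinical.to_csv(out / "clinical.csv", index=False)
    data.expr_baseline.to_csv(out / "expr_baseline.tsv", sep="\t")
    data.expr_c2d8.to_csv(out / "expr_c2d8.tsv", sep="\t")
    data.reference.to_csv(out / "reference.tsv", sep="\t")
    pd.DataFrame(
        {"baseline": list(data.pairs), "treated": list(data.pairs.values())}
    ).to_csv(out / "pairs.tsv", sep="\t", index=False)


def write_chromatin(data: ChromatinData, outdir: str | Path) -> None:
    """Write chromatin files: peaks.bed + stats TSV, hits, genes, trends."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bed = data.peaks[["chrom", "start", "end", "peak_id"]].copy()
    bed["score"] = 0
    bed["strand"] = "."
    bed.to_csv(out / "peaks.bed", sep="\t", header=False, index=False)
    data.peaks[["peak_id", "log2fc", "fdr", "true_class"]].to_csv(
        out / "peak_stats.tsv", sep="\t", index=False
    )
    data.motif_hits.to_csv(out / "motif_hits.tsv", sep="\t")
    data.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    data.trend_expr.rename_axis("gene").to_csv(out / "trend_expr.tsv", sep="\t")
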