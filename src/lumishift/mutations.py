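"""Mutation inference from read pileups and CNV classification.

A (sample, gene) is called mutant when any clinically annotated panel
variant shows a variant allele fraction of at least ``vaf_mutant_min``
(default 5%, inclusive) at covered depth; NMD ("no mutation detected")
when all covered variants fall below the threshold; and no-call when no
panel variant reaches the minimum coverage floor. Copy-number classes use
log2 copy-ratio cutoffs: amplified at >= +1, loss at <= -1.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .config import ThresholdConfig

__all__ = [
    "ESR1_PANEL",
    "PIK3CA_PANEL",
    "BUILTIN_PANEL",
    "infer_mutation_status",
    "classify_cnv",
    "filter_cancer_genes",
]

# Clinical hotspot variants screened per gene (protein-level notation).
ESR1_PANEL: tuple[str, ...] = (
    "E380Q", "S463P", "V534E", "P535H",
    "L536H", "L536P", "L536R", "L536Q",
    "Y537N", "Y537S", "Y537C", "D538G",
)
PIK3CA_PANEL: tuple[str, ...] = (
    "C420R", "E542K", "E545K", "E545G", "Q546K",
    "M1043I", "H1047Y", "H1047R", "H1047L",
)
BUILTIN_PANEL: dict[str, tuple[str, ...]] = {
    "ESR1": ESR1_PANEL,
    "PIK3CA": PIK3CA_PANEL,
}

_PILEUP_COLS = ("sample", "gene", "variant", "depth", "mut_reads")


def _normalize_variant(gene: str, variant: str) -> str:
    """Accept either 'Y537S' or 'ESR1:Y537S'; return the bare variant."""
    v = str(variant).strip()
    if ":" in v:
        prefix, v = v.split(":", 1)
        if prefix.strip().upper() != str(gene).strip().upper():
            return f"{prefix}:{v}"  # mismatched prefix: leave for panel check to reject
    return v


def infer_mutation_status(
    pileups: pd.DataFrame,
    panel: dict[str, tuple[str, ...]] | None = None,
    cfg: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Per (sample, gene) mutation status from pileup rows.

    ``pileups`` needs columns sample, gene, variant, depth, mut_reads.
    Returns a table with columns sample, gene, status in
    {mutant, NMD, no-call}, max_vaf, n_covered. Rows whose variant is not
    in the gene's panel are excluded with a warning.
    """
    cfg = cfg or ThresholdConfig()
    panel = panel if panel is not None else BUILTIN_PANEL
    missing = set(_PILEUP_COLS) - set(pileups.columns)
    if missing:
        raise ValueError(f"pileups missing columns: {sorted(missing)}")
    df = pileups.loc[:, list(_PILEUP_COLS)].copy()
    if (df["depth"] < 0).any() or (df["mut_reads"] < 0).any():
        raise ValueError("depth and mut_reads must be non-negative")
    if (df["mut_reads"] > df["depth"]).any():
        raise ValueError("mut_reads exceeds depth in some rows")

    df["gene"] = df["gene"].astype(str).str.strip().str.upper()
    df["variant"] = [
        _normalize_variant(g, v) for g, v in zip(df["gene"], df["variant"])
    ]
    panel_norm = {
        str(g).strip().upper(): {str(v).strip() for v in vs} for g, vs in panel.items()
    }
    in_panel = [
        g in panel_norm and v in panel_norm[g]
        for g, v in zip(df["gene"], df["variant"])
    ]
    n_bad = len(df) - sum(in_panel)
    if n_bad:
        bad = df.loc[[not ok for ok in in_panel], ["gene", "variant"]]
        uniq = sorted(set(map(tuple, bad.itertuples(index=False))))
        warnings.warn(
            f"excluding {n_bad} pileup row(s) with off-panel variants: {uniq[:5]}",
            stacklevel=2,
        )
        df = df.loc[in_panel]

    records = []
    for (sample, gene), grp in df.groupby(["sample", "gene"], sort=True):
        covered = grp[grp["depth"] >= cfg.min_depth]
        if covered.empty:
            status, max_vaf = "no-call", float("nan")
        else:
            vafs = covered["mut_reads"] / covered["depth"]
            max_vaf = float(vafs.max())
            status = "mutant" if max_vaf >= cfg.vaf_mutant_min else "NMD"
        records.append(
            {
                "sample": sample,
                "gene": gene,
                "status": status,
                "max_vaf": max_vaf,
                "n_covered": int(len(covered)),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["sample", "gene", "status", "max_vaf", "n_covered"]
    )


def classify_cnv(records: pd.DataFrame, cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Classify genes amplified / loss / neutral from log2 copy ratios.

    ``records`` needs columns gene, log2_ratio. Amplified iff
    ratio >= cnv_amp_min; loss iff ratio <= cnv_loss_max; neutral otherwise.
    """
    cfg = cfg or ThresholdConfig()
    if not {"gene", "log2_ratio"} <= set(records.columns):
        raise ValueError("records need columns gene, log2_ratio")
    ratios = records["log2_ratio"].astype(float)
    if not ratios.map(lambda v: v == v and abs(v) != float("inf")).all():
        raise ValueError("log2_ratio must be finite")
    out = records.loc[:, ["gene", "log2_ratio"]].copy()
    out["cnv_class"] = "neutral"
    out.loc[ratios >= cfg.cnv_amp_min, "cnv_class"] = "amplified"
    out.loc[ratios <= cfg.cnv_loss_max, "cnv_class"] = "loss"
    return out


def filter_cancer_genes(
    calls: pd.DataFrame, cancer_genes, gene_col: str = "gene"
) -> tuple[pd.DataFrame, int]:
    """Keep only rows whose gene is in a user-supplied cancer gene list.

    No gene list ships with the package; callers provide their own (e.g. a
    curated cancer gene census). Returns the filtered table and the number
    of rows retained.
    """
    allowed = {str(g).strip().upper() for g in cancer_genes}
    keep = calls[gene_col].astype(str).str.strip().str.upper().isin(allowed)
    filtered = calls.loc[keep].copy()
    return filtered, int(keep.sum())
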