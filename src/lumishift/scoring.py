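"""Signature scoring and luminal classification.

Expression is z-normalized gene-wise against a reference cohort of ER+
tumors; a signature score is the unweighted mean of the z-scores of the
signature's genes; a tumor is "Lum-high" when it strictly exceeds the
cohort median on both the ERα-activity score (estrogen-induced genes) and
the luminal-TF score, and "Lum-low" otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signatures import ERA_INDUCED, LUMINAL_TF, GeneSignature

__all__ = [
    "zscore_to_reference",
    "ZScoreReport",
    "score_signature",
    "SignatureScore",
    "era_activity",
    "classify_luminal",
    "LuminalCall",
]


def _canon(symbols) -> pd.Index:
    """Case-insensitive, whitespace-stripped gene-symbol canonicalization."""
    return pd.Index([str(s).strip().upper() for s in symbols])


@dataclass(frozen=True)
class ZScoreReport:
    n_shared_genes: int
    dropped_constant: tuple[str, ...]


def zscore_to_reference(
    expr: pd.DataFrame, reference: pd.DataFrame
) -> tuple[pd.DataFrame, ZScoreReport]:
    """z-score ``expr`` gene-wise against a reference cohort.

    Both inputs are genes x samples on a log scale. For each gene in the
    intersection, z = (x - mean_ref) / sd_ref (sample sd, ddof=1). Genes
    constant in the reference are dropped with a warning.
    """
    if reference.shape[1] < 2:
        raise ValueError("reference must have at least 2 samples")
    expr = expr.set_axis(_canon(expr.index), axis=0)
    reference = reference.set_axis(_canon(reference.index), axis=0)
    if expr.index.has_duplicates or reference.index.has_duplicates:
        raise ValueError("duplicate gene symbols after canonicalization")
    shared = expr.index.intersection(reference.index)
    if shared.empty:
        raise ValueError("no genes shared between expression and reference")
    e = expr.loc[shared].astype(float)
    r = reference.loc[shared].astype(float)
    mu = r.mean(axis=1)
    sd = r.std(axis=1, ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} gene(s) constant in reference", stacklevel=2
        )
    keep = sd.index.difference(constant)
    z = e.loc[keep].sub(mu.loc[keep], axis=0).div(sd.loc[keep], axis=0)
    # preserve input gene order
    z = z.loc[[g for g in shared if g in set(keep)]]
    return z, ZScoreReport(
        n_shared_genes=len(shared), dropped_constant=tuple(constant)
    )


@dataclass(frozen=True)
class SignatureScore:
    scores: pd.Series  # per-sample mean z
    n_genes_used: int
    missing_genes: tuple[str, ...]


def score_signature(z: pd.DataFrame, sig: GeneSignature) -> SignatureScore:
    """Per-sample mean z-score over the signature's available genes."""
    wanted = _canon(sig.genes)
    present = [g for g in wanted if g in z.index]
    missing = tuple(g for g in wanted if g not in z.index)
    if not present:
        raise ValueError(f"no genes of signature {sig.name!r} present in z-matrix")
    scores = z.loc[present].mean(axis=0)
    scores.name = sig.name
    return SignatureScore(
        scores=scores, n_genes_used=len(present), missing_genes=missing
    )


def era_activity(z: pd.DataFrame) -> SignatureScore:
    """ERα activity: the estrogen-induced signature score.

    The estrogen-repressed panel is scored separately when needed and is
    never subtracted from this score.
    """
    return score_signature(z, ERA_INDUCED)


@dataclass(frozen=True)
class LuminalCall:
    labels: pd.Series  # "Lum-high" / "Lum-low" per sample
    era_median: float
    lumtf_median: float


def classify_luminal(era_scores: pd.Series, lumtf_scores: pd.Series) -> LuminalCall:
    """Label samples Lum-high iff strictly above the median on both scores.

    Medians are computed over the supplied sample set; samples tied with a
    median fail the strict inequality and are Lum-low.
    """
    if not era_scores.index.equals(lumtf_scores.index):
        if set(era_scores.index) != set(lumtf_scores.index):
            raise ValueError("score vectors cover different sample sets")
        lumtf_scores = lumtf_scores.loc[era_scores.index]
    if len(era_scores) < 2:
        raise ValueError("need at least 2 samples to classify")
    m_era = float(era_scores.median())
    m_lum = float(lumtf_scores.median())
    high = (era_scores > m_era) & (lumtf_scores > m_lum)
    labels = pd.Series(
        np.where(high, "Lum-high", "Lum-low"), index=era_scores.index, name="luminal"
    )
    return LuminalCall(labels=labels, era_median=m_era, lumtf_median=m_lum)
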