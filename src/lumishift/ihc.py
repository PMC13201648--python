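"""Immunohistochemistry H-scores and on-treatment pharmacodynamic change.

An H-score summarizes a stained tumor section from the percentages of cells
at four staining intensities (0, 1+, 2+, 3+):

    H = 1*(% 1+) + 2*(% 2+) + 3*(% 3+),   range 0..300.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["IHCRecord", "h_score", "pd_change", "score_table", "RELATIVE_UNDEFINED"]

_SUM_TOL = 1e-6

#: sentinel for a relative change with zero baseline
RELATIVE_UNDEFINED = float("nan")


@dataclass(frozen=True)
class IHCRecord:
    """Percentages of tumor cells at each staining intensity for one sample."""

    sample: str
    pct0: float
    pct1: float
    pct2: float
    pct3: float

    def __post_init__(self) -> None:
        for name in ("pct0", "pct1", "pct2", "pct3"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")


def h_score(record: IHCRecord, renormalize: bool = False, tol: float = _SUM_TOL) -> float:
    """H-score of one IHC record.

    The four percentages must sum to 100 within ``tol`` unless
    ``renormalize`` is set, in which case they are rescaled to 100 first
    (useful for tables rounded to whole percent).
    """
    total = record.pct0 + record.pct1 + record.pct2 + record.pct3
    if renormalize:
        if total <= 0:
            raise ValueError(f"{record.sample}: percentages sum to {total}")
        scale = 100.0 / total
    else:
        if abs(total - 100.0) > tol:
            raise ValueError(
                f"{record.sample}: percentages sum to {total}, expected 100"
            )
        scale = 1.0
    return (1.0 * record.pct1 + 2.0 * record.pct2 + 3.0 * record.pct3) * scale


def pd_change(baseline: float, on_treatment: float) -> tuple[float, float]:
    """Absolute and relative H-score change from baseline to on-treatment.

    Relative change is NaN (undefined sentinel) when baseline is 0.
    """
    if baseline < 0 or on_treatment < 0:
        raise ValueError("scores must be non-negative")
    delta = on_treatment - baseline
    rel = delta / baseline if baseline > 0 else RELATIVE_UNDEFINED
    return delta, rel


def score_table(df: pd.DataFrame, renormalize: bool = False) -> pd.DataFrame:
    """Append an ``h_score`` column to a sample,pct0..pct3 table."""
    required = {"sample", "pct0", "pct1", "pct2", "pct3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = df.copy()
    out["h_score"] = [
        h_score(
            IHCRecord(str(r["sample"]), r["pct0"], r["pct1"], r["pct2"], r["pct3"]),
            renormalize=renormalize,
        )
        for _, r in df.iterrows()
    ]
    return out
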