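"""Global threshold registry.

Every decision rule in the pipeline (responder cutoffs, allele-fraction
thresholds, fold-change/FDR gates, peak caps, proximity windows) reads its
constant from a single :class:`ThresholdConfig` so that the rules can be
swept, overridden from the command line, or serialized alongside results.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ThresholdConfig"]


@dataclass
class ThresholdConfig:
    """Cutoffs and sizes used across the pipeline.

    Parameters
    ----------
    pfs_responder_min:
        Progression-free survival (months) at or above which a patient is a
        responder; progression below it marks a non-responder.
    vaf_mutant_min:
        Minimum variant allele fraction (mutant reads / depth) for a
        mutant call. Inclusive ("at least").
    de_lfc_cut:
        Absolute log2 fold-change cutoff for differential expression and
        differential peak classification.
    de_fdr_cut:
        FDR cutoff paired with ``de_lfc_cut``.
    cnv_amp_min / cnv_loss_max:
        log2 copy-ratio cutoffs for amplification (>=) and loss (<=).
    peak_cap:
        Maximum number of peaks evaluated per motif analysis; larger sets
        are randomly down-sampled to exactly this size.
    gene_window:
        Distance (bp) from a gene TSS to a peak interval within which the
        gene counts as proximal.
    min_sites_per_gene:
        Minimum number of proximal qualifying sites ("more than one" reads
        as >= 2) for a gene to be retained in peak-to-gene mapping.
    nes_display_cut:
        Absolute normalized enrichment score used when filtering gene-set
        results for display.
    tf_top_k:
        Number of top transcription factors reported per enrichment query.
    min_depth:
        Minimum read depth for a variant position to count as covered;
        below it the position contributes to a no-call.
    haldane:
        If True, add 0.5 to every cell of a 2x2 table before computing the
        odds ratio (display only); otherwise zero-cell tables yield an
        infinity sentinel.
    rng_seed:
        Seed used by any stochastic step (peak capping, permutations).
    """

    pfs_responder_min: float = 2.0
    vaf_mutant_min: float = 0.05
    de_lfc_cut: float = 1.0
    de_fdr_cut: float = 0.05
    cnv_amp_min: float = 1.0
    cnv_loss_max: float = -1.0
    peak_cap: int = 60_000
    gene_window: int = 3_000
    min_sites_per_gene: int = 2
    nes_display_cut: float = 2.0
    tf_top_k: int = 10
    min_depth: int = 1
    haldane: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.vaf_mutant_min <= 1.0):
            raise ValueError("vaf_mutant_min must lie in (0, 1]")
        if self.peak_cap < 1:
            raise ValueError("peak_cap must be >= 1")
        if self.gene_window < 0:
            raise ValueError("gene_window must be >= 0")
        if self.cnv_loss_max >= self.cnv_amp_min:
            raise ValueError("cnv_loss_max must be < cnv_amp_min")
        if self.min_sites_per_gene < 1:
            raise ValueError("min_sites_per_gene must be >= 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict[str, Any]) -> "ThresholdConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a flat mapping")
        return cls.from_dict(data)

    def replace(self, **overrides: Any) -> "ThresholdConfig":
        return dataclasses.replace(self, **overrides)
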