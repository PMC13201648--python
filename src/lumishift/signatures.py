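"""Built-in gene signatures.

Four fixed panels used throughout the pipeline: estrogen-induced and
estrogen-repressed genes (ERα pathway activity readouts derived from
preclinical ER+ models), luminal lineage transcription factors (enriched in
luminal vs basal breast cancer), and canonical MAPK target genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GeneSignature",
    "ERA_INDUCED",
    "ERA_REPRESSED",
    "LUMINAL_TF",
    "MAPK_TARGETS",
    "BUILTIN_SIGNATURES",
]


@dataclass(frozen=True)
class GeneSignature:
    """A named, non-empty list of unique gene symbols."""

    name: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.name!r} has no genes")
        object.__setattr__(self, "genes", tuple(self.genes))
        seen = set()
        for g in self.genes:
            key = g.strip().upper()
            if key in seen:
                raise ValueError(f"signature {self.name!r}: duplicate gene {g!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


ERA_INDUCED = GeneSignature(
    "era_induced",
    (
        "OLFM1", "NXPH3", "AMZ1", "CELSR2", "CT62", "RBM24", "FKBP4",
        "SGK3", "PPM1J", "FMN1", "IGFBP4", "AREG", "RAPGEFL1", "PGR",
        "RET", "TFF1", "ZNF703", "RERG", "SLC9A3R1", "GREB1", "NOS1AP",
    ),
)

ERA_REPRESSED = GeneSignature(
    "era_repressed",
    (
        "STON1", "EGLN3", "FAM171B", "LIPH", "SSPO", "BAMBI", "NBEA",
        "GRM4", "PNPLA7", "DDIT4", "TP53INP2", "TGFB3", "PSCA", "BCAS1",
        "CCNG2", "TP53INP1", "SEMA3E",
    ),
)

LUMINAL_TF = GeneSignature(
    "luminal_tf",
    (
        "XBP1", "ESR1", "FOXA1", "ZNF552", "PGR", "RARA", "GATA3",
        "CXXC5", "AR", "DACH1", "ZNF703", "ZNF467", "SPDEF", "ZBTB42",
        "CREB3L4",
    ),
)

MAPK_TARGETS = GeneSignature(
    "mapk_targets",
    (
        "SPRY2", "SPRY4", "ETV4", "ETV5", "DUSP4", "DUSP6", "CCND1",
        "EPHA2", "EPHA4",
    ),
)

BUILTIN_SIGNATURES: dict[str, GeneSignature] = {
    s.name: s for s in (ERA_INDUCED, ERA_REPRESSED, LUMINAL_TF, MAPK_TARGETS)
}
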