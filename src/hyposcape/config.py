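"""Simulation configuration for the synthetic study generator.

The defaults encode the study design the pipeline is built around: twelve
scored cell lines of which the three most hypoxia-responsive (HH) and the
three least responsive (HL) are carried forward, each profiled as two
biological replicates with two technical replicates per condition
(normoxia / hypoxia), expression arrays with ~2000 transcript clusters,
paired exome variant calls over a ~57.7 Mb panel, 50 kb read-depth windows,
and a patient cohort whose expression tracks a latent hypoxia factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import InvalidParameterError

#: MAF variant classifications the simulator knows how to emit.
VALID_VARIANT_CLASSES = frozenset(
    {
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Silent",
        "Splice_Site",
        "In_Frame_Ins",
        "In_Frame_Del",
    }
)

#: Variant classes realised as insertions / deletions; the rest are SNPs.
INSERTION_CLASSES = frozenset({"Frame_Shift_Ins", "In_Frame_Ins"})
DELETION_CLASSES = frozenset({"Frame_Shift_Del", "In_Frame_Del"})

DEFAULT_CLASS_MIXTURE: dict[str, float] = {
    "Frame_Shift_Ins": 0.35,
    "Missense_Mutation": 0.30,
    "Frame_Shift_Del": 0.10,
    "Nonsense_Mutation": 0.05,
    "Silent": 0.10,
    "Splice_Site": 0.04,
    "In_Frame_Ins": 0.03,
    "In_Frame_Del": 0.03,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study-design defaults.

    Every generator is a pure function of this object (including ``seed``):
    identical configs give byte-identical outputs.
    """

    seed: int = 0

    # --- signature fold-change experiment (cell-line scoring) ---
    n_cell_lines: int = 12
    n_signature_genes: int = 8
    #: replicate FC values per (cell line, gene): three experiments in duplicate
    n_replicate_experiments: int = 6
    #: multiplicative FC separation between sensitive and resistant lines
    group_effect: float = 4.0

    # --- expression arrays (per cell line, hypoxia vs normoxia) ---
    n_transcripts: int = 2000
    n_samples_per_condition: int = 4
    de_fraction: float = 0.05
    #: linear fold change planted in differentially expressed transcripts
    de_effect: float = 4.0
    splice_fraction: float = 0.05
    #: linear shift of the affected probe region relative to its gene
    splice_effect: float = 4.0

    # --- paired exome variant calls ---
    n_lines_per_group: int = 3
    n_biological_reps: int = 2
    n_technical_reps: int = 2
    background_shared_variants: int = 50
    hypoxia_rate_per_mb: Mapping[str, float] = field(
        default_factory=lambda: {"HH": 3.0, "HL": 1.6}
    )
    exome_size_mb: float = 57.7
    class_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    #: proportion of SNVs that are transitions (C>T or T>C after folding)
    transition_bias: float = 0.7
    n_gene_pool: int = 300

    # --- windowed coverage / CNV ---
    n_windows: int = 2000
    window_size_bp: int = 50_000
    depth_mean: float = 100.0
    #: (start window, end window, true copy number), half-open, non-overlapping
    cnv_segments: Sequence[tuple[int, int, int]] = field(
        default_factory=lambda: ((200, 400, 2), (900, 1100, 4), (1500, 1600, 2))
    )
    true_ploidy: int = 3

    # --- patient cohort ---
    n_patients: int = 50
    alteration_enrichment: float = 5.0
    n_alteration_genes: int = 30
    cohort_expression_coupling: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        counts = {
            "n_cell_lines": self.n_cell_lines,
            "n_signature_genes": self.n_signature_genes,
            "n_replicate_experiments": self.n_replicate_experiments,
            "n_transcripts": self.n_transcripts,
            "n_samples_per_condition": self.n_samples_per_condition,
            "n_lines_per_group": self.n_lines_per_group,
            "n_biological_reps": self.n_biological_reps,
            "n_technical_reps": self.n_technical_reps,
            "n_windows": self.n_windows,
            "window_size_bp": self.window_size_bp,
            "n_patients": self.n_patients,
            "n_gene_pool": self.n_gene_pool,
            "n_alteration_genes": self.n_alteration_genes,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise InvalidParameterError(f"{name} must be a positive integer, got {value!r}")
        if self.background_shared_variants < 0:
            raise InvalidParameterError("background_shared_variants must be >= 0")
        for name, value in {
            "de_fraction": self.de_fraction,
            "splice_fraction": self.splice_fraction,
            "transition_bias": self.transition_bias,
        }.items():
            if not 0.0 <= value <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {value!r}")
        if self.group_effect <= 0:
            raise InvalidParameterError("group_effect must be > 0")
        if self.de_effect < 1:
            raise InvalidParameterError("de_effect must be >= 1 (linear fold change)")
        if self.splice_effect < 1:
            raise InvalidParameterError("splice_effect must be >= 1 (linear fold change)")
        if self.depth_mean <= 0:
            raise InvalidParameterError("depth_mean must be > 0")
        if self.exome_size_mb <= 0:
            raise InvalidParameterError("exome_size_mb must be > 0")
        if self.alteration_enrichment <= 0:
            raise InvalidParameterError("alteration_enrichment must be > 0")
        if self.true_ploidy not in (2, 3, 4):
            raise InvalidParameterError("true_ploidy must be one of {2, 3, 4}")
        for group, rate in self.hypoxia_rate_per_mb.items():
            if rate < 0:
                raise InvalidParameterError(
                    f"hypoxia_rate_per_mb[{group!r}] must be >= 0, got {rate!r}"
                )

        total = math.fsum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"class_mixture probabilities must sum to 1 (got {total!r})"
            )
        unknown = set(self.class_mixture) - VALID_VARIANT_CLASSES
        if unknown:
            raise InvalidParameterError(
                f"class_mixture contains unknown variant classes: {sorted(unknown)}"
            )
        for cls, p in self.class_mixture.items():
            if p < 0:
                raise InvalidParameterError(f"class_mixture[{cls!r}] must be >= 0")

        last_end = -1
        for seg in self.cnv_segments:
            start, end, cn = seg
            if not (0 <= start < end <= self.n_windows):
                raise InvalidParameterError(
                    f"cnv segment {seg!r} must lie within [0, n_windows)"
                )
            if start < last_end:
                raise InvalidParameterError("cnv_segments must be non-overlapping and sorted")
            if cn < 0:
                raise InvalidParameterError("cnv segment copy number must be >= 0")
            last_end = end
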