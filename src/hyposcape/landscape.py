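"""Paired mutational-landscape analysis from MAF variant tables.

The study design behind this module: each cell line is sequenced after long
passaging in hypoxia and in matched normoxia, and only the variants private
to the hypoxia sample are retained ("hypoxia-only" normalization against the
matched control). From the retained variants the module computes the tumor
mutational burden (TMB, mutations per megabase of the sequenced exome),
variant-classification and six-class SNV spectra, transition/transversion
percentages, and top-mutated-gene tables at sample, cell-line and group
level.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError, FormatError, PairingError

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
    "Tumor_Sample_Barcode",
]

_SNV_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: six-class labels, pyrimidine-reference convention
SNV_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITION_CLASSES = frozenset({"C>T", "T>C"})


@dataclass(frozen=True)
class MafRecord:
    """One variant call in standard MAF semantics."""

    hugo_symbol: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    ref_allele: str
    alt_allele: str
    variant_classification: str
    variant_type: str  # SNP | INS | DEL
    sample: str

    def validate(self) -> None:
        if self.start > self.end:
            raise FormatError(f"start > end in record at {self.chromosome}:{self.start}")
        if self.variant_type == "SNP":
            if (
                self.ref_allele not in _SNV_BASES
                or self.alt_allele not in _SNV_BASES
                or self.ref_allele == self.alt_allele
            ):
                raise FormatError(
                    f"SNP requires distinct single-base alleles, got "
                    f"{self.ref_allele!r}>{self.alt_allele!r} at "
                    f"{self.chromosome}:{self.start}"
                )
        elif self.variant_type == "INS":
            if self.ref_allele != "-":
                raise FormatError(
                    f"INS requires ref allele '-', got {self.ref_allele!r} at "
                    f"{self.chromosome}:{self.start}"
                )
        elif self.variant_type == "DEL":
            if self.alt_allele != "-":
                raise FormatError(
                    f"DEL requires alt allele '-', got {self.alt_allele!r} at "
                    f"{self.chromosome}:{self.start}"
                )
        else:
            raise FormatError(f"unknown Variant_Type {self.variant_type!r}")

    @property
    def key(self) -> tuple:
        """Identity key for paired subtraction (annotation-free)."""
        return (
            self.chromosome,
            self.start,
            self.end,
            self.ref_allele,
            self.alt_allele,
            self.variant_type,
        )

    def with_sample(self, sample: str) -> "MafRecord":
        return replace(self, sample=sample)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_maf(path: str | Path) -> list[MafRecord]:
    """Read a tab-separated MAF file into validated records.

    Lines starting with ``#`` are skipped. Unknown extra columns are
    tolerated on read. A missing required column raises
    :class:`~hyposcape.errors.FormatError` naming it; a record violating the
    MAF invariants raises a record-level error with its line number.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"MAF file {path} is missing required columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = MafRecord(
            hugo_symbol=str(getattr(row, "Hugo_Symbol")),
            chromosome=str(getattr(row, "Chromosome")),
            start=int(getattr(row, "Start_Position")),
            end=int(getattr(row, "End_Position")),
            ref_allele=str(getattr(row, "Reference_Allele")),
            alt_allele=str(getattr(row, "Tumor_Seq_Allele2")),
            variant_classification=str(getattr(row, "Variant_Classification")),
            variant_type=str(getattr(row, "Variant_Type")),
            sample=str(getattr(row, "Tumor_Sample_Barcode")),
        )
        try:
            rec.validate()
        except FormatError as exc:
            raise FormatError(f"{path} line {i + 2}: {exc}") from exc
        records.append(rec)
    return records


def write_maf(records: Iterable[MafRecord], path: str | Path) -> None:
    """Write records as a tab-separated MAF file with the required columns."""
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def records_to_frame(records: Iterable[MafRecord]) -> pd.DataFrame:
    rows = [
        (
            r.hugo_symbol, r.chromosome, r.start, r.end, r.ref_allele,
            r.alt_allele, r.variant_classification, r.variant_type, r.sample,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=MAF_COLUMNS)


# ----------------------------------------------------------------------
# paired subtraction
# ----------------------------------------------------------------------

def _dedupe(records: Sequence[MafRecord], label: str) -> list[MafRecord]:
    seen: set[tuple] = set()
    out = []
    for r in records:
        if r.key in seen:
            warnings.warn(
                f"duplicate variant key {r.key} in {label}; collapsing", stacklevel=3
            )
            continue
        seen.add(r.key)
        out.append(r)
    return out


def subtract_paired(
    hypoxia: Sequence[MafRecord], normoxia: Sequence[MafRecord]
) -> list[MafRecord]:
    """Retain hypoxia records absent from the matched normoxia sample.

    Identity is the annotation-free key (chromosome, start, end, ref, alt,
    variant type), so annotation drift between the two calls cannot break
    the subtraction. Duplicate keys within a sample are collapsed with a
    warning. Output order is stable by (chromosome, start).
    """
    hypoxia = _dedupe(hypoxia, "hypoxia sample")
    normoxia_keys = {r.key for r in normoxia}
    private = [r for r in hypoxia if r.key not in normoxia_keys]
    return sorted(private, key=lambda r: (r.chromosome, r.start, r.end))


# ----------------------------------------------------------------------
# burden and spectra
# ----------------------------------------------------------------------

def compute_tmb(records: Sequence[MafRecord], exome_size_mb: float) -> float:
    """Mutations per megabase: retained variant count over the exome footprint."""
    if exome_size_mb <= 0:
        raise DomainError("exome_size_mb must be > 0")
    return len(records) / exome_size_mb


def classify_snv(ref: str, alt: str) -> tuple[str, str]:
    """Fold one SNV into its six-class label and transition/transversion kind.

    Purine-reference substitutions are complemented to the standard
    pyrimidine-reference classes (e.g. G>A folds to C>T).
    """
    if ref not in _SNV_BASES or alt not in _SNV_BASES or ref == alt:
        raise DomainError(f"not a valid SNV: {ref!r}>{alt!r}")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    label = f"{ref}>{alt}"
    kind = "transition" if label in TRANSITION_CLASSES else "transversion"
    return label, kind


@dataclass
class LandscapeSummary:
    """Per-pair mutational summary after hypoxia-only normalization."""

    pair_id: str
    cell_line: str
    group: str
    tmb: float
    class_counts: dict[str, int]
    snv_class_counts: dict[str, int]
    transition_pct: float
    transversion_pct: float
    n_retained: int


def summarize_records(records: Sequence[MafRecord], exome_size_mb: float) -> dict:
    """Burden and spectra of one retained-variant set."""
    class_counts = Counter(r.variant_classification for r in records)
    snv_counts: Counter[str] = Counter()
    for r in records:
        if r.variant_type == "SNP":
            label, _ = classify_snv(r.ref_allele, r.alt_allele)
            snv_counts[label] += 1
    n_snv = sum(snv_counts.values())
    n_ti = sum(snv_counts[c] for c in TRANSITION_CLASSES if c in snv_counts)
    ti_pct = 100.0 * n_ti / n_snv if n_snv else 0.0
    tv_pct = 100.0 - ti_pct if n_snv else 0.0
    return {
        "tmb": compute_tmb(records, exome_size_mb),
        "class_counts": dict(
            sorted(class_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ),
        "snv_class_counts": {c: snv_counts.get(c, 0) for c in SNV_CLASSES},
        "transition_pct": ti_pct,
        "transversion_pct": tv_pct,
        "n_retained": len(records),
    }


def resolve_pairs(manifest: pd.DataFrame) -> pd.DataFrame:
    """Match normoxia/hypoxia barcodes on (cell_line, biological_rep, technical_rep)."""
    required = {"sample_id", "cell_line", "condition", "biological_rep", "technical_rep"}
    missing = required - set(manifest.columns)
    if missing:
        raise FormatError(f"pairing manifest is missing columns: {sorted(missing)}")
    keys = ["cell_line", "biological_rep", "technical_rep"]
    nx = manifest[manifest["condition"] == "normoxia"].set_index(keys)["sample_id"]
    hx = manifest[manifest["condition"] == "hypoxia"].set_index(keys)["sample_id"]
    pairs = pd.concat(
        [nx.rename("normoxia_sample"), hx.rename("hypoxia_sample")], axis=1
    )
    if pairs.isna().any().any():
        orphans = pairs[pairs.isna().any(axis=1)].index.tolist()
        raise PairingError(f"unmatched samples in manifest: {orphans}")
    return pairs.reset_index()


def summarize_landscape(
    mafs: Mapping[str, Sequence[MafRecord]],
    manifest: pd.DataFrame,
    exome_size_mb: float,
    groups: Mapping[str, str] | None = None,
) -> tuple[list[LandscapeSummary], dict[str, list[MafRecord]]]:
    """Hypoxia-only subtraction plus per-pair landscape summaries.

    ``groups`` maps cell lines to their hypoxia group label (HH/HL); lines
    without a label are reported under group "NA". Returns the per-pair
    summaries and the retained (hypoxia-private) records per pair.
    """
    pairs = resolve_pairs(manifest)
    summaries: list[LandscapeSummary] = []
    retained: dict[str, list[MafRecord]] = {}
    for row in pairs.itertuples(index=False):
        nx, hx = row.normoxia_sample, row.hypoxia_sample
        if nx not in mafs or hx not in mafs:
            raise PairingError(f"pair barcodes not found in MAF set: {nx!r}, {hx!r}")
        private = subtract_paired(mafs[hx], mafs[nx])
        pair_id = f"{row.cell_line}_b{row.biological_rep}t{row.technical_rep}"
        retained[pair_id] = private
        stats = summarize_records(private, exome_size_mb)
        summaries.append(
            LandscapeSummary(
                pair_id=pair_id,
                cell_line=str(row.cell_line),
                group=(groups or {}).get(str(row.cell_line), "NA"),
                **stats,
            )
        )
    return summaries, retained


def top_mutated_genes(
    retained: Mapping[str, Sequence[MafRecord]], n: int = 10
) -> pd.DataFrame:
    """Rank genes by the number of pairs carrying at least one retained variant.

    Ties are broken by total variant count (descending) then gene label
    (ascending). The returned table carries per-class counts and the
    percentage of pairs mutated.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    n_pairs = len(retained)
    per_gene_samples: Counter[str] = Counter()
    per_gene_total: Counter[str] = Counter()
    per_gene_class: dict[str, Counter[str]] = {}
    for pair_id, records in retained.items():
        genes_here = set()
        for r in records:
            genes_here.add(r.hugo_symbol)
            per_gene_total[r.hugo_symbol] += 1
            per_gene_class.setdefault(r.hugo_symbol, Counter())[
                r.variant_classification
            ] += 1
        for g in genes_here:
            per_gene_samples[g] += 1
    ranked = sorted(
        per_gene_samples,
        key=lambda g: (-per_gene_samples[g], -per_gene_total[g], g),
    )[:n]
    rows = []
    for g in ranked:
        rows.append(
            {
                "gene": g,
                "samples_mutated": per_gene_samples[g],
                "pct_samples_mutated": 100.0 * per_gene_samples[g] / n_pairs
                if n_pairs
                else 0.0,
                "total_variants": per_gene_total[g],
                "class_counts": dict(per_gene_class[g]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "samples_mutated", "pct_samples_mutated", "total_variants", "class_counts"],
    )
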