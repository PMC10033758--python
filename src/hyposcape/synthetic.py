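"""Synthetic study generator.

Emulates the statistical structure of a chronic-hypoxia cell-line study so
that every pipeline stage can be exercised without any external download:

* replicate-level fold changes of hypoxia signature genes across a panel of
  cell lines, half of which are planted as hypoxia-sensitive;
* paired normoxia/hypoxia expression matrices with planted differential
  expression and cassette-exon splicing effects;
* paired normoxia/hypoxia MAF variant tables in which the hypoxia sample
  carries an excess of private mutations (Poisson per megabase) dominated by
  frameshift insertions and C>T / T>C transitions;
* matched case/control read-depth tracks in fixed-width windows with planted
  copy-number segments on a non-diploid baseline;
* a patient cohort whose signature-gene expression tracks a latent hypoxia
  factor and whose gene-alteration odds are enriched in the more hypoxic half.

Each generator is a pure function of its :class:`~hyposcape.config.SimulationConfig`
(including the seed) plus an optional ``instance`` index used to draw
independent replicates (e.g. one expression matrix per cell line): identical
arguments give byte-identical outputs. Truth tables carry everything needed
to score recovery downstream.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DELETION_CLASSES, INSERTION_CLASSES, SimulationConfig
from .errors import InvalidParameterError
from .landscape import MafRecord

# rng stream tags, one per scenario, so scenarios are independent
_STREAM_SIGNATURE = 1
_STREAM_EXPRESSION = 2
_STREAM_SPLICING = 3
_STREAM_MAF = 4
_STREAM_COVERAGE = 5
_STREAM_COHORT = 6

#: fixed candidate-event label order (also the tie-break order downstream)
EVENT_LABELS = (
    "cassette exon",
    "intron retention",
    "alt 5' donor",
    "alt 3' acceptor",
    "mutually exclusive exons",
    "alt first exon",
    "alt last exon",
    "complex",
)

_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: folded (pyrimidine-reference) SNV classes
_TRANSITION_CLASSES = ("C>T", "T>C")
_TRANSVERSION_CLASSES = ("C>A", "C>G", "T>A", "T>G")
#: share of transitions that are C>T (the study's dominant substitution)
_CT_SHARE = 0.6


def _rng(config: SimulationConfig, stream: int, instance: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream, int(instance)])


# ----------------------------------------------------------------------
# signature fold changes
# ----------------------------------------------------------------------

def simulate_signature_fc(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-level signature-gene fold changes for a cell-line panel.

    Returns ``(table, truth)`` where ``table`` has one row per
    (cell_line, gene, replicate) with a strictly positive linear
    ``fold_change`` and ``truth`` labels each line ``sensitive`` or not.
    Sensitive lines are drawn with per-gene FC medians ``group_effect``-fold
    higher (fold changes are log-normal; the planted shift is
    ``log2(group_effect)`` on the log2 scale).
    """
    if config.n_cell_lines < 2:
        raise InvalidParameterError("need at least 2 cell lines")
    if config.n_signature_genes < 1:
        raise InvalidParameterError("need at least 1 signature gene")
    rng = _rng(config, _STREAM_SIGNATURE)

    lines = [f"CL{i + 1:02d}" for i in range(config.n_cell_lines)]
    genes = [f"SG{j + 1:02d}" for j in range(config.n_signature_genes)]
    n_sensitive = config.n_cell_lines // 2
    sensitive = np.zeros(config.n_cell_lines, dtype=bool)
    sensitive[rng.permutation(config.n_cell_lines)[:n_sensitive]] = True

    # per-gene baseline induction, shared across lines (cancels in ranking)
    base = rng.normal(0.5, 0.3, size=config.n_signature_genes)
    shift = np.log2(config.group_effect)

    rows = []
    for i, line in enumerate(lines):
        mu = base + (shift if sensitive[i] else 0.0)
        noise = rng.normal(0.0, 0.5, size=(config.n_signature_genes, config.n_replicate_experiments))
        fc = 2.0 ** (mu[:, None] + noise)
        for j, gene in enumerate(genes):
            for r in range(config.n_replicate_experiments):
                rows.append((line, gene, r + 1, fc[j, r]))
    table = pd.DataFrame(rows, columns=["cell_line", "gene", "replicate", "fold_change"])
    truth = pd.DataFrame({"cell_line": lines, "sensitive": sensitive})
    return table, truth


# ----------------------------------------------------------------------
# expression matrices
# ----------------------------------------------------------------------

def simulate_expression_matrix(
    config: SimulationConfig, instance: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One paired normoxia/hypoxia expression matrix with planted DE effects.

    Returns ``(matrix, samples, truth)``: a linear-scale intensity matrix of
    ``n_transcripts`` rows by ``2 * n_samples_per_condition`` columns, a
    sample sheet with ``condition`` labels, and a truth table listing every
    planted transcript with its direction (+1 up in hypoxia, -1 down).
    Intensities are log-normal: log2 baseline uniform on [4, 12], per-sample
    noise sd 0.25 in log2; planted transcripts shift by ``±log2(de_effect)``
    in the hypoxia samples.
    """
    if config.n_samples_per_condition < 2:
        raise InvalidParameterError("need at least 2 samples per condition")
    rng = _rng(config, _STREAM_EXPRESSION, instance)

    n = config.n_transcripts
    m = config.n_samples_per_condition
    transcripts = [f"TC{instance}_{t + 1:05d}" for t in range(n)]
    samples = [f"N{instance}_{k + 1}" for k in range(m)] + [
        f"H{instance}_{k + 1}" for k in range(m)
    ]
    conditions = ["normoxia"] * m + ["hypoxia"] * m

    base = rng.uniform(4.0, 12.0, size=n)
    log2 = base[:, None] + rng.normal(0.0, 0.25, size=(n, 2 * m))

    n_de = int(round(config.de_fraction * n))
    de_idx = np.sort(rng.permutation(n)[:n_de])
    direction = rng.choice([-1, 1], size=n_de)
    log2[np.ix_(de_idx, np.arange(m, 2 * m))] += (
        direction[:, None] * np.log2(config.de_effect)
    )

    matrix = pd.DataFrame(2.0 ** log2, index=pd.Index(transcripts, name="transcript"), columns=samples)
    sheet = pd.DataFrame({"sample_id": samples, "condition": conditions})
    truth = pd.DataFrame(
        {"transcript": [transcripts[i] for i in de_idx], "direction": direction}
    )
    return matrix, sheet, truth


# ----------------------------------------------------------------------
# splicing signals
# ----------------------------------------------------------------------

def simulate_splicing_signals(
    config: SimulationConfig, instance: int = 0
) -> tuple[
    pd.DataFrame,
    pd.DataFrame,
    pd.DataFrame,
    pd.DataFrame,
    dict[str, list[tuple[str, float]]],
    pd.DataFrame,
]:
    """Gene-level and probe-region signals with planted cassette exons.

    Returns ``(probe_signals, probe_map, gene_signals, samples, events,
    truth)``. Each transcript carries a gene-level signal and two probe
    regions (exon/junction probes) whose signal is a transcript-specific
    fraction of the gene signal with independent log-normal noise. Planted
    transcripts have probe 1 shifted ``splice_effect``-fold (random sign)
    relative to the gene in hypoxia while the gene signal is unchanged.
    ``events`` maps each transcript to its candidate splicing events with
    scores in [0, 1]; for planted transcripts the true event ("cassette
    exon") scores highest, all other transcripts have no candidates.
    """
    if config.n_samples_per_condition < 2:
        raise InvalidParameterError("need at least 2 samples per condition")
    rng = _rng(config, _STREAM_SPLICING, instance)

    n = config.n_transcripts
    m = config.n_samples_per_condition
    transcripts = [f"TC{instance}_{t + 1:05d}" for t in range(n)]
    samples = [f"N{instance}_{k + 1}" for k in range(m)] + [
        f"H{instance}_{k + 1}" for k in range(m)
    ]
    conditions = ["normoxia"] * m + ["hypoxia"] * m

    gene_base = rng.uniform(6.0, 10.0, size=n)
    gene_log2 = gene_base[:, None] + rng.normal(0.0, 0.25, size=(n, 2 * m))

    probe_ids, probe_transcripts = [], []
    for t in transcripts:
        probe_ids.extend([f"{t}_P1", f"{t}_P2"])
        probe_transcripts.extend([t, t])
    frac = rng.uniform(-1.5, -0.3, size=(n, 2))  # log2 probe/gene fraction
    probe_noise = rng.normal(0.0, 0.2, size=(n, 2, 2 * m))
    probe_log2 = gene_log2[:, None, :] + frac[:, :, None] + probe_noise

    n_spliced = int(round(config.splice_fraction * n))
    spliced_idx = np.sort(rng.permutation(n)[:n_spliced])
    direction = rng.choice([-1, 1], size=n_spliced)
    probe_log2[np.ix_(spliced_idx, [0], np.arange(m, 2 * m))] += (
        direction[:, None, None] * np.log2(config.splice_effect)
    )

    events: dict[str, list[tuple[str, float]]] = {t: [] for t in transcripts}
    truth_rows = []
    decoy_labels = [lab for lab in EVENT_LABELS if lab != "cassette exon"]
    for k, idx in enumerate(spliced_idx):
        t = transcripts[idx]
        true_score = rng.uniform(0.75, 0.95)
        cands = [("cassette exon", float(true_score))]
        for lab in rng.choice(decoy_labels, size=rng.integers(1, 3), replace=False):
            cands.append((str(lab), float(rng.uniform(0.05, 0.6))))
        events[t] = cands
        truth_rows.append((t, f"{t}_P1", int(direction[k]), "cassette exon"))

    probe_signals = pd.DataFrame(
        2.0 ** probe_log2.reshape(2 * n, 2 * m),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=samples,
    )
    probe_map = pd.DataFrame({"probe_id": probe_ids, "transcript": probe_transcripts})
    gene_signals = pd.DataFrame(
        2.0 ** gene_log2, index=pd.Index(transcripts, name="transcript"), columns=samples
    )
    sheet = pd.DataFrame({"sample_id": samples, "condition": conditions})
    truth = pd.DataFrame(
        truth_rows, columns=["transcript", "probe_id", "direction", "event"]
    )
    return probe_signals, probe_map, gene_signals, sheet, events, truth


# ----------------------------------------------------------------------
# paired MAFs
# ----------------------------------------------------------------------

def _draw_snv_alleles(rng: np.random.Generator, transition_bias: float) -> tuple[str, str]:
    """Draw (ref, alt) for one SNV honouring the transition bias.

    Folded-class frequencies: transitions split ``_CT_SHARE`` C>T vs T>C;
    transversions uniform. The reference strand is then chosen uniformly, so
    e.g. a folded C>T is emitted as C>T or G>A with equal probability.
    """
    if rng.random() < transition_bias:
        folded = "C>T" if rng.random() < _CT_SHARE else "T>C"
    else:
        folded = _TRANSVERSION_CLASSES[rng.integers(len(_TRANSVERSION_CLASSES))]
    ref, alt = folded.split(">")
    if rng.random() < 0.5:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt


def _draw_variants(
    rng: np.random.Generator,
    n: int,
    config: SimulationConfig,
    genes: np.ndarray,
    gene_weights: np.ndarray,
    sample: str,
    used_positions: set[int],
) -> list[MafRecord]:
    """Draw ``n`` variant records on contig chrS with unique positions."""
    contig_len = int(config.exome_size_mb * 1e6)
    classes = list(config.class_mixture)
    probs = np.array([config.class_mixture[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    records = []
    for _ in range(n):
        pos = int(rng.integers(1, contig_len + 1))
        while pos in used_positions:  # MAF identity keys must be unique per sample
            pos = int(rng.integers(1, contig_len + 1))
        used_positions.add(pos)
        cls = classes[rng.choice(len(classes), p=probs)]
        gene = str(genes[rng.choice(len(genes), p=gene_weights)])
        if cls in INSERTION_CLASSES:
            length = 3 if cls == "In_Frame_Ins" else int(rng.integers(1, 3))
            alt = "".join(rng.choice(_BASES, size=length))
            rec = MafRecord(gene, "chrS", pos, pos + 1, "-", alt, cls, "INS", sample)
        elif cls in DELETION_CLASSES:
            length = 3 if cls == "In_Frame_Del" else int(rng.integers(1, 3))
            ref = "".join(rng.choice(_BASES, size=length))
            rec = MafRecord(gene, "chrS", pos, pos + length - 1, ref, "-", cls, "DEL", sample)
        else:
            ref, alt = _draw_snv_alleles(rng, config.transition_bias)
            rec = MafRecord(gene, "chrS", pos, pos, ref, alt, cls, "SNP", sample)
        records.append(rec)
    return records


def simulate_paired_mafs(
    config: SimulationConfig,
    lines_per_group: Mapping[str, Sequence[str]] | None = None,
) -> tuple[dict[str, list[MafRecord]], pd.DataFrame, pd.DataFrame]:
    """Paired normoxia/hypoxia MAFs for every cell line of both groups.

    Returns ``(mafs, manifest, truth)``. For each pair the two samples share
    exactly ``background_shared_variants`` identical records; the hypoxia
    sample additionally carries ``K ~ Poisson(rate * exome_size_mb)`` private
    records whose classes follow ``class_mixture`` and whose SNVs follow
    ``transition_bias``. ``truth`` records K per pair along with the pairing.
    """
    if lines_per_group is None:
        lines_per_group = {
            group: [f"{group}{i + 1}" for i in range(config.n_lines_per_group)]
            for group in config.hypoxia_rate_per_mb
        }
    rng = _rng(config, _STREAM_MAF)

    genes = np.array([f"G{i + 1:03d}" for i in range(config.n_gene_pool)])
    gene_weights = 1.0 / (np.arange(config.n_gene_pool) + 5.0)
    gene_weights /= gene_weights.sum()

    mafs: dict[str, list[MafRecord]] = {}
    manifest_rows, truth_rows = [], []
    for group, lines in lines_per_group.items():
        rate = float(config.hypoxia_rate_per_mb[group])
        for line in lines:
            for b in range(1, config.n_biological_reps + 1):
                for t in range(1, config.n_technical_reps + 1):
                    nx = f"{line}_N_b{b}t{t}"
                    hx = f"{line}_H_b{b}t{t}"
                    used: set[int] = set()
                    shared = _draw_variants(
                        rng, config.background_shared_variants, config,
                        genes, gene_weights, nx, used,
                    )
                    k = int(rng.poisson(rate * config.exome_size_mb))
                    private = _draw_variants(
                        rng, k, config, genes, gene_weights, hx, used
                    )
                    mafs[nx] = shared
                    mafs[hx] = [r.with_sample(hx) for r in shared] + private
                    manifest_rows.append((nx, line, "normoxia", b, t))
                    manifest_rows.append((hx, line, "hypoxia", b, t))
                    truth_rows.append((line, group, b, t, nx, hx, k))
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["sample_id", "cell_line", "condition", "biological_rep", "technical_rep"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "cell_line", "group", "biological_rep", "technical_rep",
            "normoxia_sample", "hypoxia_sample", "n_private",
        ],
    )
    return mafs, manifest, truth


# ----------------------------------------------------------------------
# coverage tracks
# ----------------------------------------------------------------------

def simulate_coverage(
    config: SimulationConfig, instance: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Matched case/control depth tracks in fixed-width windows on chrS.

    Control depth is Poisson(``depth_mean``) per window; case depth is
    Poisson(``depth_mean * CN / true_ploidy``) with CN from the planted
    ``cnv_segments`` (baseline ``true_ploidy`` elsewhere). Mappability is 1.
    Returns ``(case, control, truth_segments)``.
    """
    rng = _rng(config, _STREAM_COVERAGE, instance)
    n = config.n_windows
    cn = np.full(n, config.true_ploidy, dtype=float)
    truth_rows = []
    for start, end, seg_cn in config.cnv_segments:
        cn[start:end] = seg_cn
        status = (
            "gain" if seg_cn > config.true_ploidy
            else "loss" if seg_cn < config.true_ploidy
            else "neutral"
        )
        truth_rows.append(("chrS", start, end, seg_cn, status))

    starts = np.arange(n) * config.window_size_bp
    control_depth = rng.poisson(config.depth_mean, size=n).astype(float)
    case_depth = rng.poisson(config.depth_mean * cn / config.true_ploidy).astype(float)

    def _track(depth: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": "chrS",
                "start": starts,
                "end": starts + config.window_size_bp,
                "depth": depth,
                "mappability": 1.0,
            }
        )

    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start_window", "end_window", "copy_number", "status"]
    )
    return _track(case_depth), _track(control_depth), truth


# ----------------------------------------------------------------------
# patient cohort
# ----------------------------------------------------------------------

def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cohort expression and per-patient gene-alteration tables.

    Each patient has a latent hypoxia factor ``z ~ N(0, 1)``; signature-gene
    log2 expression is ``baseline + coupling * z + noise``. Binary alteration
    events in the alteration genes have baseline probability 0.15 with odds
    multiplied by ``alteration_enrichment`` for patients in the top half of
    the latent factor. Returns ``(expression, alterations, truth)``.
    """
    if config.n_patients < 4:
        raise InvalidParameterError("need at least 4 patients")
    rng = _rng(config, _STREAM_COHORT)

    patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    genes = [f"SG{j + 1:02d}" for j in range(config.n_signature_genes)]
    z = rng.normal(0.0, 1.0, size=config.n_patients)

    base = rng.uniform(4.0, 12.0, size=config.n_signature_genes)
    log2 = (
        base[None, :]
        + config.cohort_expression_coupling * z[:, None]
        + rng.normal(0.0, 0.5, size=(config.n_patients, config.n_signature_genes))
    )
    expression = pd.DataFrame(
        2.0 ** log2, index=pd.Index(patients, name="patient"), columns=genes
    )

    alt_genes = [f"G{i + 1:03d}" for i in range(config.n_alteration_genes)]
    p0 = 0.15
    odds = p0 / (1 - p0)
    p1 = odds * config.alteration_enrichment / (1 + odds * config.alteration_enrichment)
    top_half = z > np.median(z)
    p = np.where(top_half[:, None], p1, p0)
    alterations = pd.DataFrame(
        (rng.random(size=(config.n_patients, config.n_alteration_genes)) < p).astype(int),
        index=pd.Index(patients, name="patient"),
        columns=alt_genes,
    )
    truth = pd.DataFrame({"patient": patients, "factor": z, "top_half": top_half})
    return expression, alterations, truth
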