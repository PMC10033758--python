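"""Differential expression and alternative-splicing index analysis.

Array-style conventions throughout: tests run on log2 intensities, fold
changes are reported as signed linear ratios (r if r >= 1, else -1/r), and a
transcript is differentially expressed when its signed FC is <= -2 or >= 2
with Benjamini-Hochberg FDR <= 0.05. Variance moderation shrinks each
transcript's variance toward the across-transcript mean variance with a
configurable prior degrees of freedom, reducing to the ordinary two-sample
t-test at prior_df = 0.

Splicing follows the exon/junction-probe construction: probe-region signals
are normalized by their gene-level signal per sample, the splicing index
(SI) is the signed fold change of normalized means (hypoxia vs normoxia),
and a transcript is differentially spliced when |SI| > 2 with exon FDR
< 0.05 (thresholds differ from the DE rule at the boundary, as conventional
for the two analyses). Each flagged transcript's splicing mode is the
candidate event with the highest event score; transcripts with no scored
candidate event are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DomainError

#: splicing event labels in canonical order; earlier wins score ties
EVENT_ORDER = (
    "cassette exon",
    "intron retention",
    "alt 5' donor",
    "alt 3' acceptor",
    "mutually exclusive exons",
    "alt first exon",
    "alt last exon",
    "complex",
)

DE_FC_THRESHOLD = 2.0
DE_FDR_THRESHOLD = 0.05
SI_THRESHOLD = 2.0
SI_FDR_THRESHOLD = 0.05


@dataclass
class DifferentialResult:
    transcript: str
    signed_fc: float
    p_value: float
    fdr: float
    significant: bool


@dataclass
class SplicingResult:
    transcript: str
    splicing_index: float
    exon_fdr: float
    significant: bool
    event: str | None
    event_score: float | None
    excluded: bool


def signed_fold_change(mean_case: float, mean_control: float) -> float:
    """Signed linear fold change: r when r >= 1, else -1/r."""
    if mean_case <= 0 or mean_control <= 0:
        raise DomainError("group means must be strictly positive")
    r = mean_case / mean_control
    return r if r >= 1 else -1.0 / r


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise DomainError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _split_conditions(
    columns: Sequence[str], conditions: Mapping[str, str] | pd.DataFrame
) -> tuple[list[str], list[str]]:
    if isinstance(conditions, pd.DataFrame):
        conditions = dict(zip(conditions["sample_id"], conditions["condition"]))
    case = [c for c in columns if conditions.get(c) == "hypoxia"]
    control = [c for c in columns if conditions.get(c) == "normoxia"]
    unknown = [c for c in columns if c not in conditions]
    if unknown:
        raise ConfigurationError(f"samples without condition labels: {unknown}")
    if len(case) < 2 or len(control) < 2:
        raise DomainError("each condition needs at least 2 samples")
    return case, control


def moderated_de_test(
    matrix: pd.DataFrame,
    conditions: Mapping[str, str] | pd.DataFrame,
    prior_df: float = 4.0,
) -> list[DifferentialResult]:
    """Moderated two-sample comparison of hypoxia vs normoxia per transcript.

    ``matrix`` holds strictly positive linear intensities (transcripts x
    samples); testing is on log2 values. Per transcript the pooled variance
    s2 (df d = n1 + n2 - 2) is shrunk toward the across-transcript mean
    variance s0_2 as s~2 = (d0*s0_2 + d*s2) / (d0 + d) with d0 = ``prior_df``;
    the statistic Delta / (s~ * sqrt(1/n1 + 1/n2)) is referred to a t
    distribution with d + d0 degrees of freedom. Significance combines the
    signed-FC rule (<= -2 or >= 2) with BH FDR <= 0.05.
    """
    if prior_df < 0:
        raise DomainError("prior_df must be >= 0")
    if (matrix.to_numpy() <= 0).any():
        raise DomainError("expression matrix must be strictly positive")
    case_cols, control_cols = _split_conditions(list(matrix.columns), conditions)

    case = matrix[case_cols].to_numpy(dtype=float)
    control = matrix[control_cols].to_numpy(dtype=float)
    log_case, log_control = np.log2(case), np.log2(control)
    n1, n2 = case.shape[1], control.shape[1]
    d = n1 + n2 - 2

    delta = log_case.mean(axis=1) - log_control.mean(axis=1)
    ss = log_case.var(axis=1, ddof=1) * (n1 - 1) + log_control.var(axis=1, ddof=1) * (
        n2 - 1
    )
    s2 = ss / d
    s0_2 = float(s2.mean())
    s2_tilde = (prior_df * s0_2 + d * s2) / (prior_df + d)

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=d + prior_df)
    fdr = bh_fdr(p)

    fc = np.array(
        [signed_fold_change(mc, mn) for mc, mn in zip(case.mean(axis=1), control.mean(axis=1))]
    )
    significant = (np.abs(fc) >= DE_FC_THRESHOLD) & (fdr <= DE_FDR_THRESHOLD)
    return [
        DifferentialResult(str(tid), float(fc[i]), float(p[i]), float(fdr[i]), bool(significant[i]))
        for i, tid in enumerate(matrix.index)
    ]


def de_results_to_frame(results: Iterable[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript": [r.transcript for r in results],
            "signed_fc": [r.signed_fc for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "significant": [r.significant for r in results],
        }
    )


def deg_set_algebra(
    per_line_sets: Mapping[str, set],
    group_assignment: Mapping[str, str],
) -> tuple[set, set, set]:
    """Common and group-specific differentially expressed gene sets.

    ``common_all`` is the intersection over every cell line; each group's
    specific set is the intersection over that group's lines minus
    ``common_all``. The three outputs are pairwise disjoint.
    """
    labels = sorted(set(group_assignment.values()))
    if len(labels) != 2:
        raise ConfigurationError(f"expected exactly 2 group labels, got {labels}")
    unknown = [l for l in per_line_sets if l not in group_assignment]
    if unknown:
        raise ConfigurationError(f"lines without group assignment: {unknown}")
    by_group: dict[str, list[set]] = {lab: [] for lab in labels}
    for line, s in per_line_sets.items():
        by_group[group_assignment[line]].append(set(s))
    for lab in labels:
        if not by_group[lab]:
            raise ConfigurationError(f"group {lab!r} has no cell lines")

    all_sets = [set(s) for s in per_line_sets.values()]
    common_all = set.intersection(*all_sets) if all_sets else set()
    specific_a = set.intersection(*by_group[labels[0]]) - common_all
    specific_b = set.intersection(*by_group[labels[1]]) - common_all
    return common_all, specific_a, specific_b


def splicing_index(
    psr_signals: pd.DataFrame,
    probe_map: pd.DataFrame,
    gene_signals: pd.DataFrame,
    conditions: Mapping[str, str] | pd.DataFrame,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Per-transcript splicing index with exon-level FDR.

    Probe signals are divided by their transcript's gene signal per sample;
    the SI of a probe is the signed fold change of normalized means
    (hypoxia vs normoxia), tested with the moderated statistic on log2
    normalized signals and BH-adjusted across probes. The transcript-level
    SI is taken from the probe with the largest |SI| (ties: first probe id).
    Returns a frame with columns transcript, probe_id, splicing_index,
    exon_fdr.
    """
    mapping = dict(zip(probe_map["probe_id"], probe_map["transcript"]))
    missing = [p for p in psr_signals.index if mapping.get(p) not in gene_signals.index]
    if missing:
        raise DomainError(f"probes without a gene-level signal: {missing[:5]}")
    transcripts = [mapping[p] for p in psr_signals.index]
    gene = gene_signals.loc[transcripts, psr_signals.columns].to_numpy(dtype=float)
    if (gene <= 0).any() or (psr_signals.to_numpy() <= 0).any():
        raise DomainError("signals must be strictly positive")
    normalized = pd.DataFrame(
        psr_signals.to_numpy(dtype=float) / gene,
        index=psr_signals.index,
        columns=psr_signals.columns,
    )
    probe_results = moderated_de_test(normalized, conditions, prior_df=prior_df)
    frame = pd.DataFrame(
        {
            "probe_id": psr_signals.index,
            "transcript": transcripts,
            "splicing_index": [r.signed_fc for r in probe_results],
            "exon_fdr": [r.fdr for r in probe_results],
        }
    )
    frame["abs_si"] = frame["splicing_index"].abs()
    best = (
        frame.sort_values(["abs_si", "probe_id"], ascending=[False, True])
        .groupby("transcript", sort=True)
        .head(1)
        .drop(columns="abs_si")
        .reset_index(drop=True)
    )
    return best[["transcript", "probe_id", "splicing_index", "exon_fdr"]]


def select_event(
    candidates: Sequence[tuple[str, float]]
) -> tuple[str, float] | None:
    """Pick the candidate event with the highest score, or None (excluded).

    Ties are broken by the fixed label order of :data:`EVENT_ORDER`.
    """
    if not candidates:
        return None
    order = {label: i for i, label in enumerate(EVENT_ORDER)}
    for label, score in candidates:
        if not 0.0 <= score <= 1.0:
            raise DomainError(f"event score {score!r} outside [0, 1] for {label!r}")
        if label not in order:
            raise DomainError(f"unknown event label {label!r}")
    best = min(candidates, key=lambda c: (-c[1], order[c[0]]))
    return best[0], float(best[1])


def call_splicing(
    psr_signals: pd.DataFrame,
    probe_map: pd.DataFrame,
    gene_signals: pd.DataFrame,
    conditions: Mapping[str, str] | pd.DataFrame,
    events: Mapping[str, Sequence[tuple[str, float]]],
    prior_df: float = 4.0,
) -> list[SplicingResult]:
    """Full splicing stage: index, significance, event selection, exclusion."""
    si = splicing_index(psr_signals, probe_map, gene_signals, conditions, prior_df)
    results = []
    for row in si.itertuples(index=False):
        significant = (
            abs(row.splicing_index) > SI_THRESHOLD and row.exon_fdr < SI_FDR_THRESHOLD
        )
        chosen = select_event(list(events.get(row.transcript, [])))
        excluded = chosen is None  # no scored candidate event
        results.append(
            SplicingResult(
                transcript=str(row.transcript),
                splicing_index=float(row.splicing_index),
                exon_fdr=float(row.exon_fdr),
                significant=bool(significant),
                event=chosen[0] if chosen else None,
                event_score=chosen[1] if chosen else None,
                excluded=bool(excluded),
            )
        )
    return results


def splicing_results_to_frame(results: Iterable[SplicingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript": [r.transcript for r in results],
            "splicing_index": [r.splicing_index for r in results],
            "exon_fdr": [r.exon_fdr for r in results],
            "significant": [r.significant for r in results],
            "event": [r.event for r in results],
            "event_score": [r.event_score for r in results],
            "excluded": [r.excluded for r in results],
        }
    )
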