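"""Hypoxia scoring and HH/HL stratification.

Two variants of the score are used:

* **Cell lines** — signature-gene fold changes (hypoxia vs normoxia) are
  averaged over replicates per (cell line, gene); the hypoxia score of a
  line is the geometric mean of its per-gene mean fold changes. The
  relative score is the score minus the geometric mean of all line scores;
  lines with relative score > 0 form the hypoxia-high (HH) group, the rest
  the hypoxia-low (HL) group.
* **Cohorts** — each signature gene is dichotomized at its cohort median
  (+1 above, -1 at or below); a patient's hypoxia score is the sum of gene
  scores, and patients with score > 0 are HH, otherwise HL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .errors import ConfigurationError, DomainError


@dataclass
class CellLineScore:
    cell_line: str
    gene_means: dict[str, float]
    score: float
    relative_score: float
    group: str  # HH | HL


@dataclass
class CohortCall:
    patient: str
    gene_scores: dict[str, int]
    hypoxia_score: int
    group: str  # HH | HL


def average_gene_fold_changes(table: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of replicate fold changes per (cell_line, gene).

    ``table`` needs columns ``cell_line``, ``gene``, ``fold_change`` (a
    ``replicate`` column is allowed but not required). Any non-positive fold
    change is a domain error naming the offending entry.
    """
    if table.empty:
        raise DomainError("fold-change table is empty")
    bad = table[table["fold_change"] <= 0]
    if not bad.empty:
        first = bad.iloc[0]
        raise DomainError(
            f"non-positive fold change {first['fold_change']!r} for cell line "
            f"{first['cell_line']!r}, gene {first['gene']!r}"
        )
    return table.groupby(["cell_line", "gene"], sort=True)["fold_change"].mean()


def hypoxia_score(gene_means: Mapping[str, float] | Sequence[float]) -> float:
    """Geometric mean of the per-gene mean fold changes of one cell line."""
    values = np.asarray(
        list(gene_means.values()) if isinstance(gene_means, Mapping) else gene_means,
        dtype=float,
    )
    if values.size == 0:
        raise DomainError("cannot score an empty gene set")
    if np.any(values <= 0):
        raise DomainError("gene means must be strictly positive")
    return float(gmean(values))


def relative_scores(scores: Mapping[str, float]) -> dict[str, tuple[float, str]]:
    """Relative score (score minus geometric mean of all scores) and group.

    Lines with relative score > 0 are hypoxia high (HH); the rest hypoxia
    low (HL). Ranking by relative score equals ranking by score.
    """
    if len(scores) < 2:
        raise DomainError("need at least 2 cell lines to compare")
    values = np.asarray(list(scores.values()), dtype=float)
    if np.any(values <= 0):
        raise DomainError("scores must be strictly positive")
    center = float(gmean(values))
    return {
        line: (score - center, "HH" if score - center > 0 else "HL")
        for line, score in scores.items()
    }


def score_cell_lines(table: pd.DataFrame) -> list[CellLineScore]:
    """Full cell-line scoring: replicate averaging, geometric mean, relative score."""
    means = average_gene_fold_changes(table)
    per_line: dict[str, dict[str, float]] = {}
    for (line, gene), value in means.items():
        per_line.setdefault(str(line), {})[str(gene)] = float(value)
    scores = {line: hypoxia_score(gm) for line, gm in per_line.items()}
    rel = relative_scores(scores)
    return [
        CellLineScore(line, per_line[line], scores[line], rel[line][0], rel[line][1])
        for line in sorted(scores, key=lambda l: -scores[l])
    ]


def score_cohort(
    expression: pd.DataFrame, genes: Sequence[str] | None = None
) -> list[CohortCall]:
    """Median-dichotomized cohort hypoxia scores and HH/HL stratification.

    ``expression`` is patients x genes. Per gene the cohort median is
    computed (midpoint median for even cohorts); a patient scores +1 on a
    gene when expression is strictly above the median, else -1. The hypoxia
    score is the sum over genes; score > 0 is HH, otherwise HL.
    """
    if genes is None:
        genes = list(expression.columns)
    missing = [g for g in genes if g not in expression.columns]
    if missing:
        raise ConfigurationError(f"missing signature gene columns: {missing}")
    if len(expression) < 2:
        raise DomainError("need at least 2 patients")
    sub = expression[list(genes)]
    if sub.isna().any().any():
        raise DomainError("missing values among signature genes")
    medians = sub.median(axis=0)
    signs = np.where(sub.to_numpy() > medians.to_numpy()[None, :], 1, -1)
    calls = []
    for i, patient in enumerate(expression.index):
        gene_scores = {g: int(signs[i, j]) for j, g in enumerate(genes)}
        total = int(signs[i].sum())
        calls.append(
            CohortCall(str(patient), gene_scores, total, "HH" if total > 0 else "HL")
        )
    return calls


def calls_to_frame(calls: Sequence[CohortCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient": [c.patient for c in calls],
            "hypoxia_score": [c.hypoxia_score for c in calls],
            "group": [c.group for c in calls],
        }
    )


def scores_to_frame(scores: Sequence[CellLineScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_line": [s.cell_line for s in scores],
            "score": [s.score for s in scores],
            "relative_score": [s.relative_score for s in scores],
            "group": [s.group for s in scores],
        }
    )
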