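"""Group statistics used throughout the pipeline's reports.

Covers the study's reporting conventions: t-based 95% confidence intervals
on group means, unpaired two-sided t-tests (Student pooled-variance by
default, Welch optional), one-way ANOVA with Sidak-adjusted pairwise
comparisons, and the HH-vs-HL alteration-frequency concordance count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, DomainError


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    ci95: tuple[tuple[float, float], tuple[float, float]]
    t_statistic: float
    df: float
    p_value: float
    test_flavor: str  # student | welch


@dataclass
class ConcordanceResult:
    genes: list[str]
    freq_high: dict[str, float]
    freq_low: dict[str, float]
    concordant_count: int
    total: int


def mean_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float, float]:
    """Mean with t-based confidence interval (sample sd, n-1 df)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError("need at least 2 values for a confidence interval")
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return m, m, m
    half = sps.t.ppf((1 + level) / 2, df=x.size - 1) * sd / np.sqrt(x.size)
    return m, m - float(half), m + float(half)


def t_test_unpaired(
    a: Sequence[float],
    b: Sequence[float],
    flavor: str = "student",
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Unpaired two-sided t-test with per-group means and 95% CIs.

    Student (pooled variance) by default; Welch with ``flavor="welch"``.
    When both groups have zero variance and equal means, t = 0 and p = 1 by
    convention.
    """
    if flavor not in ("student", "welch"):
        raise DomainError(f"unknown test flavor {flavor!r}")
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise DomainError("each group needs at least 2 values")
    na, nb = xa.size, xb.size
    ma, mb = float(xa.mean()), float(xb.mean())
    va, vb = float(xa.var(ddof=1)), float(xb.var(ddof=1))

    if va == 0.0 and vb == 0.0:
        if ma == mb:
            t, df, p = 0.0, float(na + nb - 2), 1.0
        else:
            t = float(np.inf) if ma > mb else float(-np.inf)
            df, p = float(na + nb - 2), 0.0
    elif flavor == "student":
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        t = (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p = float(2 * sps.t.sf(abs(t), df=df))
    else:
        sea, seb = va / na, vb / nb
        df = float((sea + seb) ** 2 / (sea**2 / (na - 1) + seb**2 / (nb - 1)))
        t = (ma - mb) / np.sqrt(sea + seb)
        p = float(2 * sps.t.sf(abs(t), df=df))

    return GroupComparison(
        labels=labels,
        n=(na, nb),
        means=(ma, mb),
        ci95=(mean_ci(xa)[1:], mean_ci(xb)[1:]),
        t_statistic=float(t),
        df=df,
        p_value=p,
        test_flavor=flavor,
    )


def anova_sidak(
    groups: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """One-way ANOVA with Sidak-adjusted pooled-variance pairwise t-tests.

    Pairwise statistics use the ANOVA residual mean square and residual
    degrees of freedom; the Sidak adjustment for m comparisons is
    ``1 - (1 - p)^m`` clamped to [0, 1]. When every observation is
    identical the degenerate zero-variance case is reported as p = 1.
    """
    if len(groups) < 2:
        raise DomainError("need at least 2 groups")
    if not comparisons:
        raise DomainError("empty comparisons list")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, x in arrays.items():
        if x.size < 2:
            raise DomainError(f"group {k!r} needs at least 2 values")
    for a, b in comparisons:
        if a not in arrays or b not in arrays:
            raise ConfigurationError(f"comparison ({a!r}, {b!r}) names an unknown group")

    all_x = np.concatenate(list(arrays.values()))
    n_total = all_x.size
    k = len(arrays)
    grand = all_x.mean()
    ssb = sum(x.size * (x.mean() - grand) ** 2 for x in arrays.values())
    ssw = sum(((x - x.mean()) ** 2).sum() for x in arrays.values())
    df_b, df_w = k - 1, n_total - k

    if ssw == 0.0 and ssb == 0.0:
        f_stat, anova_p = 0.0, 1.0
    elif ssw == 0.0:
        f_stat, anova_p = float(np.inf), 0.0
    else:
        f_stat = (ssb / df_b) / (ssw / df_w)
        anova_p = float(sps.f.sf(f_stat, df_b, df_w))

    mse = ssw / df_w if df_w > 0 else 0.0
    m = len(comparisons)
    rows = []
    for a, b in comparisons:
        xa, xb = arrays[a], arrays[b]
        diff = xa.mean() - xb.mean()
        if mse == 0.0:
            t = 0.0 if diff == 0 else float(np.sign(diff)) * float(np.inf)
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / np.sqrt(mse * (1 / xa.size + 1 / xb.size))
            p = float(2 * sps.t.sf(abs(t), df=df_w))
        adjusted = float(min(1.0, 1.0 - (1.0 - p) ** m))
        rows.append((a, b, float(diff), float(t), p, adjusted))
    out = pd.DataFrame(
        rows, columns=["group_a", "group_b", "mean_diff", "t", "p_raw", "p_sidak"]
    )
    out.attrs["anova_f"] = float(f_stat)
    out.attrs["anova_p"] = anova_p
    out.attrs["df"] = (df_b, df_w)
    return out


def alteration_concordance(
    alterations: pd.DataFrame,
    groups: Mapping[str, str],
    gene_list: Sequence[str],
) -> ConcordanceResult:
    """Per-gene alteration frequencies in HH vs HL and the concordance count.

    ``alterations`` is a patients x genes 0/1 table; ``groups`` maps every
    patient to "HH" or "HL". A gene is concordant when its alteration
    frequency is strictly higher in the HH group.
    """
    missing = [g for g in gene_list if g not in alterations.columns]
    if missing:
        raise ConfigurationError(f"genes absent from alteration table: {missing}")
    labels = pd.Series({p: groups[p] for p in alterations.index})
    hh = alterations.loc[labels == "HH", list(gene_list)]
    hl = alterations.loc[labels == "HL", list(gene_list)]
    if hh.empty or hl.empty:
        raise DomainError("both HH and HL groups must be non-empty")
    freq_hh = hh.mean(axis=0)
    freq_hl = hl.mean(axis=0)
    concordant = int((freq_hh > freq_hl).sum())
    return ConcordanceResult(
        genes=list(gene_list),
        freq_high={g: float(freq_hh[g]) for g in gene_list},
        freq_low={g: float(freq_hl[g]) for g in gene_list},
        concordant_count=concordant,
        total=len(gene_list),
    )
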