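"""Bias analysis of the ArI error across patient groups.

The per-record ArI error (absolute difference between predicted and
manually scored arousal index) is compared across metadata groups — sex,
age bins, and sleep-disorder categories — to detect whether the detector
is systematically worse for some patients:

1. Shapiro-Wilk per group (the ArI error is typically non-normal, which
   motivates rank-based omnibus testing);
2. Kruskal-Wallis omnibus across groups;
3. Dunn's post-hoc z-tests with Bonferroni correction for pairwise
   differences;
4. Cohen's d (pooled-SD) of each group against the reference
   ("NormalFinding"), binned none / small / moderate / large at the
   conventional 0.2 / 0.5 / 0.8 cut points.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "cohens_d",
    "effect_bin",
    "dunn_posthoc",
    "group_bias_analysis",
    "ari_vs_error_correlation",
    "GroupComparison",
    "GroupResult",
    "DEFAULT_AGE_BINS",
]

# decade age bins for the age-bias analysis (18-29, 30-39, ..., 80+)
DEFAULT_AGE_BINS = (18, 30, 40, 50, 60, 70, 80)

_EFFECT_EDGES = (0.2, 0.5, 0.8)
_EFFECT_NAMES = ("none", "small", "moderate", "large")


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Classical Cohen's d: ``(mean(a) - mean(b)) / pooled_sd`` with
    (n-1)-weighted pooling of the two sample variances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2))
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled SD with unequal means: effect size undefined")
    return float((a.mean() - b.mean()) / pooled)


def effect_bin(d: float) -> str:
    """Bin |d| at 0.2 / 0.5 / 0.8 into none / small / moderate / large."""
    mag = abs(d)
    for edge, name in zip(_EFFECT_EDGES, _EFFECT_NAMES):
        if mag < edge:
            return name
    return _EFFECT_NAMES[-1]


def dunn_posthoc(groups: Mapping[str, Sequence[float]]) -> dict[tuple[str, str], float]:
    """Dunn's pairwise z-tests on joint ranks, Bonferroni-adjusted.

    For groups i, j with mean joint ranks ``Ri, Rj`` over N pooled values,

        z = (Ri - Rj) / sqrt((N(N+1)/12 - C) (1/ni + 1/nj))

    where ``C = sum(t^3 - t) / (12 (N - 1))`` corrects for ties.  Two-sided
    normal p-values are multiplied by the number of pairs and capped at 1.
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(data)
    n_total = len(pooled)
    ranks = _st.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    pos = 0
    for g, x in zip(names, data):
        mean_rank[g] = ranks[pos : pos + len(x)].mean()
        pos += len(x)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_c = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_c
    pairs = list(itertools.combinations(names, 2))
    out: dict[tuple[str, str], float] = {}
    for gi, gj in pairs:
        se = np.sqrt(base_var * (1.0 / len(groups[gi]) + 1.0 / len(groups[gj])))
        if se == 0:
            p = 1.0
        else:
            z = (mean_rank[gi] - mean_rank[gj]) / se
            p = 2.0 * _st.norm.sf(abs(z))
        out[(gi, gj)] = min(1.0, p * len(pairs))
    return out


@dataclass(frozen=True)
class GroupResult:
    """Per-group outcome of the bias analysis (vs the reference group)."""

    n: int
    cohens_d: float
    effect_bin: str
    significant: bool
    shapiro_p: float
    dunn_p_vs_reference: float | None


@dataclass(frozen=True)
class GroupComparison:
    reference: str
    results: dict[str, GroupResult]
    kruskal_stat: float
    kruskal_p: float
    dunn: dict[tuple[str, str], float]


def group_bias_analysis(
    errors_by_group: Mapping[str, Sequence[float]],
    reference: str = "NormalFinding",
    alpha: float = 0.05,
    min_n: int = 3,
) -> GroupComparison:
    """Full group-bias analysis of ArI errors.

    Groups with fewer than ``min_n`` observations are excluded with a
    warning.  A group is flagged significant when its Bonferroni-adjusted
    Dunn p-value against the reference is below ``alpha``.
    """
    groups: dict[str, np.ndarray] = {}
    for g, vals in errors_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < min_n:
            warnings.warn(f"group {g!r} has n={len(vals)} < {min_n}; excluded")
            continue
        groups[g] = vals
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} missing or too small")
    if len(groups) < 2:
        raise ValueError("need at least two usable groups")

    kw = _st.kruskal(*groups.values())
    dunn = dunn_posthoc(groups)

    def dunn_p(a: str, b: str) -> float:
        return dunn.get((a, b), dunn.get((b, a), 1.0))

    results: dict[str, GroupResult] = {}
    for g, vals in groups.items():
        shapiro_p = float(_st.shapiro(vals).pvalue) if len(vals) >= 3 else float("nan")
        if g == reference:
            d, bin_, p_ref, sig = 0.0, "none", None, False
        else:
            d = cohens_d(vals, groups[reference])
            bin_ = effect_bin(d)
            p_ref = dunn_p(g, reference)
            sig = p_ref < alpha
        results[g] = GroupResult(
            n=len(vals),
            cohens_d=d,
            effect_bin=bin_,
            significant=sig,
            shapiro_p=shapiro_p,
            dunn_p_vs_reference=p_ref,
        )
    return GroupComparison(
        reference=reference,
        results=results,
        kruskal_stat=float(kw.statistic),
        kruskal_p=float(kw.pvalue),
        dunn=dunn,
    )


def ari_vs_error_correlation(
    ari_true: Sequence[float], ari_error: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation (with two-sided p) between the annotated arousal
    index and the ArI error — a positive r means the detector's absolute
    error grows with sleep fragmentation."""
    a = np.asarray(ari_true, dtype=float)
    e = np.asarray(ari_error, dtype=float)
    if len(a) < 3:
        raise ValueError("need at least three records")
    if np.ptp(a) == 0 or np.ptp(e) == 0:
        raise ValueError("zero variance; correlation undefined")
    res = _st.pearsonr(a, e)
    return float(res.statistic), float(res.pvalue)


def bin_ages(
    ages: Sequence[float], edges: Sequence[float] = DEFAULT_AGE_BINS
) -> list[str]:
    """Map ages to decade-bin labels ("18-29", ..., "80+")."""
    labels = []
    edges = list(edges)
    for age in ages:
        if age < edges[0]:
            labels.append(f"<{edges[0]:.0f}")
            continue
        for lo, hi in zip(edges[:-1], edges[1:]):
            if lo <= age < hi:
                labels.append(f"{lo:.0f}-{hi - 1:.0f}")
                break
        else:
            labels.append(f"{edges[-1]:.0f}+")
    return labels
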