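"""Group-comparison statistics for the fibrosis study design.

Four tissue groups (sham/infarct x close/far section) are compared per
metric with a one-way omnibus test followed by all pairwise contrasts:

* parametric branch -- one-way ANOVA, then pairwise Welch-free t tests
  with Holm--Sidak step-down adjustment;
* nonparametric branch -- Kruskal--Wallis, then Dunn's rank-based
  pairwise z tests (tie-corrected) with Holm adjustment.

The branch is chosen by a per-group Shapiro--Wilk normality check
(parametric only when every group passes), and can be forced.  Group
summaries are reported as mean +/- standard error.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupTable",
    "PairwiseResult",
    "ComparisonReport",
    "holm_sidak",
    "holm",
    "dunn_pairwise",
    "choose_branch",
    "omnibus_and_pairwise",
]

GROUPS = ("sham_close", "sham_far", "mi_close", "mi_far")


@dataclass
class GroupTable:
    """Long-format (sample, group, value) table for one metric."""

    data: pd.DataFrame          # columns: sample, group, value
    metric: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        need = {"sample", "group", "value"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"table needs columns {need}")
        counts = self.data.groupby("group")["value"].count()
        if len(counts) < 2 or (counts < 2).any():
            raise ValueError("need >= 2 groups with >= 2 samples each")

    def groups(self) -> dict[str, np.ndarray]:
        return {g: sub["value"].to_numpy(float)
                for g, sub in self.data.groupby("group", sort=False)}


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class ComparisonReport:
    metric: str
    branch: str                         # "parametric" | "nonparametric"
    omnibus_test: str                   # "anova" | "kruskal_wallis"
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseResult]
    group_summary: pd.DataFrame         # mean, se, n per group
    alpha: float
    notes: list[str] = field(default_factory=list)

    def pair(self, a: str, b: str) -> PairwiseResult:
        for pr in self.pairwise:
            if {pr.group_a, pr.group_b} == {a, b}:
                return pr
        raise KeyError(f"no contrast {a} vs {b}")


def holm_sidak(p_values: np.ndarray) -> np.ndarray:
    """Holm--Sidak step-down adjusted p-values.

    With the raw p-values sorted ascending, the i-th adjusted value is
    ``max_{j<=i} [1 - (1 - p_(j))^(m - j + 1)]``, reported back in the
    input order and clipped to 1.
    """
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = np.clip(adj_sorted, 0.0, 1.0)
    return out


def holm(p_values: np.ndarray) -> np.ndarray:
    """Holm (Bonferroni step-down) adjusted p-values."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = np.clip(adj_sorted, 0.0, 1.0)
    return out


def _ranks_with_ties(values: np.ndarray) -> tuple[np.ndarray, float]:
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    return ranks, tie_sum


def dunn_pairwise(groups: dict[str, np.ndarray]) -> list[tuple[str, str, float, float]]:
    """Dunn's rank-based pairwise comparisons (two-sided, tie-corrected).

    Returns (group_a, group_b, z, p_raw) per pair; adjust externally.
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks, tie_sum = _ranks_with_ties(pooled)
    mean_ranks = {}
    pos = 0
    for g in names:
        n = groups[g].size
        mean_ranks[g] = float(np.mean(ranks[pos : pos + n]))
        pos += n
    var_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    out = []
    for a, b in itertools.combinations(names, 2):
        na, nb = groups[a].size, groups[b].size
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        out.append((a, b, float(z), float(min(p, 1.0))))
    return out


def choose_branch(table: GroupTable, normality_alpha: float = 0.05,
                  *, force: str | None = None) -> str:
    """Pick the parametric or nonparametric branch for a table.

    Parametric when every group passes a Shapiro--Wilk normality check.
    ``normality_alpha`` is the family-wise rate at which a fully normal
    table is demoted to ranks: the per-group level is Sidak-split,
    ``1 - (1 - alpha)^(1/k)`` over the k groups, so normal data stay on
    the parametric branch in about ``1 - alpha`` of runs regardless of
    the group count.  Groups smaller than 3 cannot be tested and force
    the nonparametric branch with a warning.  ``force`` overrides.
    """
    if force in ("parametric", "nonparametric"):
        return force
    groups = table.groups()
    for g, v in groups.items():
        if v.size < 3:
            warnings.warn(f"group {g!r} has n < 3; forcing nonparametric branch",
                          stacklevel=2)
            return "nonparametric"
    alpha_group = 1.0 - (1.0 - normality_alpha) ** (1.0 / len(groups))
    for v in groups.values():
        if np.ptp(v) == 0:
            return "nonparametric"  # Shapiro undefined on constant data
        if sps.shapiro(v).pvalue < alpha_group:
            return "nonparametric"
    return "parametric"


def _summary(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for g, v in groups.items():
        sd = np.std(v, ddof=1) if v.size > 1 else 0.0
        rows.append({"group": g, "n": v.size, "mean": float(np.mean(v)),
                     "se": float(sd / np.sqrt(v.size))})
    return pd.DataFrame(rows).set_index("group")


def omnibus_and_pairwise(table: GroupTable, branch: str | None = None,
                         alpha: float = 0.05,
                         *, normality_alpha: float = 0.05,
                         dunn_adjustment: str = "holm") -> ComparisonReport:
    """Omnibus test plus all pairwise contrasts for one metric.

    Parametric: one-way ANOVA F, pairwise two-sample t tests with
    Holm--Sidak adjustment.  Nonparametric: Kruskal--Wallis H, Dunn
    pairwise with Holm (default) or Holm--Sidak adjustment.  Zero
    within-group variance in every group degenerates the parametric
    branch and falls back to ranks with a note.
    """
    notes: list[str] = []
    if branch is None:
        branch = choose_branch(table, normality_alpha)
    groups = table.groups()
    values = list(groups.values())
    if branch == "parametric" and all(np.ptp(v) == 0 for v in values):
        notes.append("zero within-group variance; fell back to nonparametric")
        branch = "nonparametric"

    if branch == "parametric":
        f_stat, p_omni = sps.f_oneway(*values)
        test = "anova"
        raw = []
        pairs = list(itertools.combinations(groups, 2))
        for a, b in pairs:
            t, p = sps.ttest_ind(groups[a], groups[b])
            raw.append((a, b, float(t), float(p)))
        p_adj = holm_sidak(np.array([r[3] for r in raw]))
    else:
        h_stat, p_omni = sps.kruskal(*values)
        f_stat = h_stat
        test = "kruskal_wallis"
        raw = dunn_pairwise(groups)
        adjuster = holm if dunn_adjustment == "holm" else holm_sidak
        p_adj = adjuster(np.array([r[3] for r in raw]))

    pairwise = [
        PairwiseResult(a, b, stat, p, float(pa), bool(pa < alpha))
        for (a, b, stat, p), pa in zip(raw, p_adj)
    ]
    return ComparisonReport(
        metric=table.metric, branch=branch, omnibus_test=test,
        omnibus_statistic=float(f_stat), omnibus_p=float(p_omni),
        pairwise=pairwise, group_summary=_summary(groups),
        alpha=alpha, notes=notes,
    )
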