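"""Rank-based group comparison of per-grain parameters.

Interspecific differences between strains are tested with the two-sided
Mann-Whitney U test: ``U = min(U1, U2)`` with midrank ties, an exact p-value
by full enumeration of group labelings for small samples, and the normal
approximation (tie-corrected variance, continuity correction) otherwise.
Significance is annotated with the conventional star codes (p < 0.05 *,
< 0.01 **, < 0.001 ***, < 0.0001 ****).  Pairwise p-values are reported raw
— no multiple-testing correction — matching common practice in descriptive
morphometry; an optional Holm adjustment is available behind a flag.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

log = logging.getLogger(__name__)

#: exact enumeration is used when n1 + n2 is at most this (auto mode)
EXACT_LIMIT = 14

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def _u_min_from_ranks(rank_sum_x: float, n1: int, n2: int) -> float:
    u1 = rank_sum_x - n1 * (n1 + 1) / 2.0
    return min(u1, n1 * n2 - u1)


def mann_whitney_u(
    x, y, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with ``U = min(U1, U2)`` under midrank ties.  In
    exact mode the p-value is ``P(min(U1, U2) <= U_obs)`` over all
    ``C(n1+n2, n1)`` group labelings of the pooled sample; in normal mode it
    is the tie-corrected, continuity-corrected normal approximation.
    ``mode='auto'`` switches at a pooled size of 14.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = _u_min_from_ranks(float(ranks[:n1].sum()), n1, n2)

    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if n1 + n2 <= EXACT_LIMIT else "normal"

    if mode == "exact":
        n = n1 + n2
        hits = total = 0
        for idx in itertools.combinations(range(n), n1):
            u = _u_min_from_ranks(float(ranks[list(idx)].sum()), n1, n2)
            total += 1
            if u <= u_obs + 1e-9:
                hits += 1
        return u_obs, hits / total

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = (u_obs + 0.5 - mu) / np.sqrt(var)
    return u_obs, float(min(1.0, 2.0 * norm.cdf(z)))


def star_code(p: float) -> str:
    """Significance stars for a p-value ('ns' when p >= 0.05)."""
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


@dataclass
class GroupTable:
    """Per-grain records grouped by strain label."""

    data: pd.DataFrame
    strain_column: str = "strain"
    parameters: tuple[str, ...] = ("V_pl", "S_um2", "SI", "starch_ng")

    def __post_init__(self) -> None:
        if self.strain_column not in self.data.columns:
            raise ValueError(f"missing column {self.strain_column!r}")
        labels = self.data[self.strain_column]
        if labels.isna().any() or (labels.astype(str) == "").any():
            raise ValueError("every record needs a non-empty strain label")

    @classmethod
    def from_records(cls, records, **kwargs) -> "GroupTable":
        rows = [r.to_dict() if hasattr(r, "to_dict") else dict(r) for r in records]
        return cls(pd.DataFrame(rows), **kwargs)

    def groups(self, parameter: str) -> dict[str, np.ndarray]:
        return {
            str(name): grp[parameter].to_numpy(dtype=float)
            for name, grp in self.data.groupby(self.strain_column, sort=True)
        }


@dataclass
class ComparisonResult:
    """Outcome of one pairwise Mann-Whitney comparison."""

    strain_a: str
    strain_b: str
    parameter: str
    u_statistic: float
    p_value: float
    stars: str
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        n1n2_bound_ok = self.u_statistic >= 0
        if not n1n2_bound_ok or not (0 < self.p_value <= 1):
            raise ValueError("invalid comparison statistics")
        if self.stars != star_code(self.p_value):
            raise ValueError("star code inconsistent with p-value")


def compare_all(
    table: GroupTable,
    parameter: str,
    mode: str = "auto",
    holm: bool = False,
) -> list[ComparisonResult]:
    """All unordered pairwise strain comparisons for one parameter.

    Raw pairwise p-values are reported (a log note records this); with
    ``holm=True`` Holm-adjusted p-values are attached alongside without
    changing the star annotation of the raw values.
    """
    groups = table.groups(parameter)
    if len(groups) < 2:
        raise ValueError("need at least two strains to compare")
    log.info("pairwise p-values are reported without multiplicity correction")
    results = []
    for (na, xa), (nb, xb) in itertools.combinations(groups.items(), 2):
        u, p = mann_whitney_u(xa, xb, mode=mode)
        results.append(
            ComparisonResult(na, nb, parameter, u, p, star_code(p))
        )
    if holm:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(
            [r.p_value for r in results], method="holm"
        )
        for r, pa in zip(results, p_adj):
            r.p_adjusted = float(pa)
    return results


def summarize(table: GroupTable, parameter: str) -> pd.DataFrame:
    """Per-strain mean, sample SD (n-1 denominator) and n.

    Single-record groups report SD = 0 and are flagged in the ``qc``
    column.
    """
    rows = []
    for name, vals in table.groups(parameter).items():
        n = len(vals)
        rows.append(
            {
                "strain": name,
                "parameter": parameter,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if n > 1 else 0.0,
                "n": n,
                "qc": "single-record group" if n == 1 else "",
            }
        )
    return pd.DataFrame(rows)


def comparisons_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain_a": r.strain_a,
                "strain_b": r.strain_b,
                "parameter": r.parameter,
                "U": r.u_statistic,
                "p": r.p_value,
                "stars": r.stars,
                "p_holm": r.p_adjusted,
            }
            for r in results
        ]
    )
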