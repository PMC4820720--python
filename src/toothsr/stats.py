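"""Nonparametric inference over grouped tooth measurements.

Tie-corrected Kruskal-Wallis H (chi-square approximation, with an optional
exact full-enumeration mode for small samples) and Spearman rank
correlation with midranks.  Tooth records are grouped into deciduous molars
(DM1–3), molars (M1–3) and premolars (P1–3), or by residence area, with
fallen-out and failed-separation records excluded rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import comb, factorial
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedSample",
    "TestResult",
    "kruskal_wallis",
    "spearman",
    "group_teeth",
    "TOOTH_GROUP_MAP",
]

TOOTH_GROUP_MAP = {
    "DM1": "DM", "DM2": "DM", "DM3": "DM",
    "M1": "M", "M2": "M", "M3": "M",
    "P1": "P", "P2": "P", "P3": "P",
}


@dataclass(frozen=True)
class GroupedSample:
    """Measurements partitioned into named groups."""

    labels: tuple[str, ...]
    groups: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.groups):
            raise ValueError("labels and groups must align")
        if any(len(g) == 0 for g in self.groups):
            raise ValueError("groups must be non-empty")

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(g) for g in self.groups)

    @property
    def n_total(self) -> int:
        return sum(self.sizes)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float
    p_one_tailed: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def _kw_statistic(values: np.ndarray, sizes: Sequence[int]) -> float:
    """Tie-corrected Kruskal-Wallis H for concatenated group values.

    H = [12/(N(N+1)) Σ R_i²/n_i − 3(N+1)] / [1 − ΣT/(N³−N)], T = t³−t per
    tie group of size t, with midranks.  All-tied data give H = 0.
    """
    N = values.size
    ranks = sps.rankdata(values)
    H = 0.0
    start = 0
    for n_i in sizes:
        R = ranks[start : start + n_i].sum()
        H += R * R / n_i
        start += n_i
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    correction = 1.0 - tie_sum / (N**3 - N)
    if correction <= 0.0:  # all values identical
        return 0.0
    return H / correction


def _kw_exact_p(values: np.ndarray, sizes: Sequence[int], h_obs: float) -> float:
    """Exact permutation p: P(H >= H_obs) over all assignments of the observed
    values to groups of the given sizes, enumerated by distinct permutations
    of the group-label vector.  Feasible for small N only."""
    N = values.size
    n_assign = factorial(N)
    for n_i in sizes:
        n_assign //= factorial(n_i)
    if n_assign > 200_000:
        raise ValueError("sample too large for exact enumeration")
    labels = np.concatenate([[k] * n for k, n in enumerate(sizes)])
    seen: set[tuple[int, ...]] = set()
    hits = 0
    total = 0
    for perm in permutations(range(N)):
        key = tuple(labels[list(perm)])
        if key in seen:
            continue
        seen.add(key)
        perm_vals = np.empty(N)
        pos = 0
        lab = np.array(key)
        for k in range(len(sizes)):
            perm_vals[pos : pos + sizes[k]] = values[lab == k]
            pos += sizes[k]
        h = _kw_statistic(perm_vals, sizes)
        total += 1
        if h >= h_obs - 1e-12:
            hits += 1
    return hits / total


def kruskal_wallis(sample: GroupedSample, method: str = "asymptotic") -> TestResult:
    """Kruskal-Wallis test with midranks and the standard tie correction.

    ``method="asymptotic"`` refers H to the chi-square upper tail with k−1
    degrees of freedom (its only tail — the test is inherently one-sided);
    ``method="exact"`` enumerates the full permutation distribution of H,
    practical only for small total N.
    """
    k = len(sample.groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if sample.n_total < 3:
        raise ValueError("need total N >= 3")
    values = np.concatenate([np.asarray(g, dtype=float) for g in sample.groups])
    H = _kw_statistic(values, sample.sizes)
    df = k - 1
    if method == "asymptotic":
        p = float(sps.chi2.sf(H, df))
    elif method == "exact":
        p = _kw_exact_p(values, sample.sizes, H)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(statistic=H, df=df, p=p, method=f"kruskal-wallis/{method}")


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with midranks.

    ρ is the Pearson correlation of the midranks; the two-sided p uses the
    t approximation with n−2 degrees of freedom and the one-tailed value
    (upper tail for ρ>0, lower for ρ<0) is reported alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d arrays")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("rank correlation undefined for zero-variance input")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p_two, p_one = 0.0, 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p_two = float(2.0 * sps.t.sf(abs(t), n - 2))
        p_one = float(sps.t.sf(t, n - 2)) if rho >= 0 else float(sps.t.cdf(t, n - 2))
    return TestResult(
        statistic=rho, df=n - 2, p=p_two, p_one_tailed=p_one, method="spearman"
    )


def group_teeth(
    teeth: pd.DataFrame,
    factor: str = "tooth_group",
    response: str = "activity_conc",
) -> GroupedSample:
    """Group tooth records for testing.

    ``factor`` is ``"tooth_group"`` (DM1–3 → DM, M1–3 → M, P1–3 → P) or
    ``"area"``.  Records whose status is not ``ok`` (fallen out, failed
    separation) and missing responses are excluded before grouping.
    """
    df = teeth
    if "status" in df.columns:
        df = df[df["status"] == "ok"]
    df = df.dropna(subset=[response])
    if df.empty:
        raise ValueError("no usable records after status/NA filtering")
    if factor == "tooth_group":
        unknown = set(df["tooth_class"]) - set(TOOTH_GROUP_MAP)
        if unknown:
            raise ValueError(f"unknown tooth codes: {sorted(unknown)}")
        keys = df["tooth_class"].map(TOOTH_GROUP_MAP)
        order = ["DM", "M", "P"]
    elif factor == "area":
        keys = df["area"]
        order = ["H", "L", "C"]
    else:
        raise ValueError(f"unknown grouping factor {factor!r}")
    labels, groups = [], []
    for key in order:
        vals = df.loc[keys == key, response]
        if len(vals):
            labels.append(key)
            groups.append(tuple(float(v) for v in vals))
    return GroupedSample(labels=tuple(labels), groups=tuple(groups))
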