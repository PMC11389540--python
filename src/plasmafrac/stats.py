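"""Cohort assembly and paired nonparametric group comparisons.

Per-sample summary metrics (tumor fraction, P20_150, end-motif Gini
diversity, mtDNA percentage, modal fragment length) are collected into a
cohort table keyed by (patient, group).  Group contrasts use the two-sided
paired Wilcoxon signed-rank test, pairing samples by patient: zero
differences are dropped (the classic Wilcoxon convention), the null is
enumerated exactly up to 25 informative pairs, and the normal approximation
with continuity correction is used above.  P values are reported unadjusted;
a Benjamini-Hochberg column is available on request.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .simulate import GROUPS

METRICS = ("tumor_fraction", "p20_150", "gini", "mtdna_percent", "modal_length")

EXACT_MAX_PAIRS = 25


@dataclasses.dataclass(frozen=True)
class PairedTestResult:
    metric: str
    group_a: str
    group_b: str
    n_pairs: int
    statistic: float  # signed rank-sum difference W+ - W-
    p_value: float
    method: str = "wilcoxon"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value outside [0, 1]")


def paired_wilcoxon(values_a, values_b, metric: str = "", group_a: str = "a", group_b: str = "b",
                    exact_max_pairs: int = EXACT_MAX_PAIRS) -> PairedTestResult:
    """Two-sided paired Wilcoxon signed-rank test on patient-matched values.

    The reported statistic is the signed difference of positive and negative
    rank sums, so swapping the two groups negates it and leaves p unchanged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples differ in length")
    d = a - b
    d = d[d != 0]  # drop zero differences
    n = len(d)
    if n < 2:
        raise ValueError("no informative pairs: fewer than 2 non-zero differences")
    ranks = scipy.stats.rankdata(np.abs(d))
    signed_stat = float(ranks[d > 0].sum() - ranks[d < 0].sum())
    use_exact = n <= exact_max_pairs
    method = "exact" if use_exact else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = scipy.stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                                       alternative="two-sided", method=method)
            p = float(res.pvalue)
        except (ValueError, TypeError):
            p, method = None, "approx"
        if use_exact and _has_ties(ranks):
            # tied absolute differences: the standard exact null does not
            # apply, so enumerate the 2^n sign-flip distribution directly
            p = _exact_signflip_p(d)
            method = "exact-permutation"
        elif p is None:
            res = scipy.stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                                       alternative="two-sided", method="approx")
            p = float(res.pvalue)
    return PairedTestResult(metric=metric, group_a=group_a, group_b=group_b,
                            n_pairs=n, statistic=signed_stat, p_value=min(p, 1.0),
                            method=f"wilcoxon-{method}")


def _has_ties(ranks: np.ndarray) -> bool:
    return len(np.unique(ranks)) != len(ranks)


def _exact_signflip_p(d: np.ndarray) -> float:
    """Exact two-sided p over the 2^n sign assignments of |d|.

    Uses the shift-algorithm convolution over doubled (hence integer)
    average ranks, which remains exact in the presence of ties.
    """
    n = len(d)
    ranks = scipy.stats.rankdata(np.abs(d))
    ranks2 = np.rint(2 * ranks).astype(np.int64)
    observed2 = int(np.rint(2 * ranks[d > 0].sum()))
    total2 = int(ranks2.sum())
    dist = np.zeros(total2 + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total2 + 1 - r]
        dist = dist + shifted
    dist /= 2.0**n
    lo = min(observed2, total2 - observed2)
    return float(dist[: lo + 1].sum() + dist[total2 - lo :].sum())


def build_cohort_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble per-sample metric rows into the cohort table.

    Each row must carry ``patient_id`` and ``group``; metric columns are
    whatever subset of :data:`METRICS` was computed.
    """
    table = pd.DataFrame(list(rows))
    if table.empty:
        raise ValueError("empty cohort")
    for col in ("patient_id", "group"):
        if col not in table.columns:
            raise ValueError(f"cohort rows lack required column {col!r}")
    bad = set(table["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown groups in cohort: {sorted(bad)}")
    if table.duplicated(["patient_id", "group"]).any():
        raise ValueError("duplicate (patient_id, group) rows in cohort")
    return table.reset_index(drop=True)


def default_group_pairs() -> list[tuple[str, str]]:
    """Each SEC fraction vs unfractionated cfDNA, and all fraction pairs."""
    return list(itertools.combinations(GROUPS, 2))


def compare_all(cohort: pd.DataFrame, metrics: Sequence[str] | None = None,
                group_pairs: Sequence[tuple[str, str]] | None = None,
                adjust: bool = False) -> pd.DataFrame:
    """One paired Wilcoxon per metric x group pair; long-format result table.

    Patients missing from either group of a pair are dropped pairwise.
    Pairs with no informative differences are reported with NaN p values and
    a note rather than failing the whole comparison.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    metrics = list(metrics) if metrics is not None else [m for m in METRICS if m in cohort.columns]
    for m in metrics:
        if m not in cohort.columns:
            raise KeyError(f"unknown metric {m!r}")
    group_pairs = list(group_pairs) if group_pairs is not None else default_group_pairs()
    known = set(GROUPS)
    for ga, gb in group_pairs:
        if ga not in known or gb not in known:
            raise ValueError(f"unknown group in pair ({ga!r}, {gb!r})")
    wide = cohort.set_index(["patient_id", "group"])
    rows = []
    for metric in metrics:
        series = wide[metric].unstack("group")
        for ga, gb in group_pairs:
            if ga not in series.columns or gb not in series.columns:
                rows.append(dict(metric=metric, group_a=ga, group_b=gb, n_pairs=0,
                                 statistic=np.nan, p_value=np.nan, method="no-data"))
                continue
            sub = series[[ga, gb]].dropna()
            try:
                r = paired_wilcoxon(sub[ga], sub[gb], metric=metric, group_a=ga, group_b=gb)
                rows.append(dataclasses.asdict(r))
            except ValueError as err:
                rows.append(dict(metric=metric, group_a=ga, group_b=gb, n_pairs=len(sub),
                                 statistic=np.nan, p_value=np.nan, method=f"failed: {err}"))
    out = pd.DataFrame(rows)
    if adjust:
        out["p_adj_bh"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    pv = p[ok]
    m = len(pv)
    if m:
        order = np.argsort(pv)
        ranked = pv[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        q[ok] = adj
    return q
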