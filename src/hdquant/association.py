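"""Instability-phenotype association statistics.

Per-mouse instability, expansion and contraction indices (per tissue) are
correlated with behavioural phenotype scores by Pearson correlation, and
index distributions are compared between treatment groups with a one-tailed
Mann-Whitney U test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pearson",
    "mannwhitney_one_tailed",
    "correlate_matrix",
]

INDEX_KINDS = ("instability", "expansion", "contraction")


def pearson(x, y) -> tuple[float, float, int]:
    """Sample Pearson correlation with its two-sided p-value.

    p comes from the t transform t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees
    of freedom.  Requires n >= 3 finite pairs; zero variance in either
    vector is rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n

def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2)


_ENUM_LIMIT = 200_000  # max combinations for the tie-handling enumeration


def mannwhitney_one_tailed(a, b, alternative: str = "less") -> tuple[float, float]:
    """One-tailed Mann-Whitney U test of group ``a`` against group ``b``.

    ``alternative='less'`` tests whether values in ``a`` tend to be smaller
    than in ``b`` ('greater' the reverse).  Without ties (and for feasible
    sizes) the p-value is exact from the null U distribution.  With ties,
    midranks are used and, when the number of group assignments is small
    enough to enumerate, the exact permutation p-value is computed with the
    mid-p rule (assignments tied with the observed statistic contribute
    half their mass, removing the conservativeness midrank ties induce);
    otherwise the normal approximation with tie-corrected variance and
    continuity correction is used.

    Returns ``(U, p)`` with U the statistic of group ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a)
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties and n_a * n_b <= 400:
        res = stats.mannwhitneyu(a, b, alternative=alternative, method="exact")
        return u_obs, float(res.pvalue)
    if has_ties and comb(n_a + n_b, n_a) <= _ENUM_LIMIT:
        lower, equal, total = 0.0, 0.0, 0
        for idx in combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks[list(idx)], n_a)
            total += 1
            if np.isclose(u, u_obs):
                equal += 1
            elif (u < u_obs) == (alternative == "less"):
                lower += 1
        return u_obs, (lower + 0.5 * equal) / total
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return u_obs, float(res.pvalue)


def correlate_matrix(records: pd.DataFrame, tissues, index_kinds=INDEX_KINDS,
                     phenotypes=("rotarod", "open_field", "hanging_wire", "clasping"),
                     bh_correct: bool = False) -> pd.DataFrame:
    """Pearson correlation of every (tissue, index, phenotype) combination.

    ``records`` is a wide per-mouse table with columns ``{tissue}_{kind}``
    for each tissue and index kind plus one column per phenotype.  Missing
    values are handled pairwise-complete; combinations with fewer than 3
    complete pairs are reported with NaN statistics and flagged.  Raw
    p-values are reported by default; ``bh_correct`` adds a BH-adjusted
    column across all testable rows.
    """
    rows = []
    for tissue in tissues:
        for kind in index_kinds:
            col = f"{tissue}_{kind}"
            if col not in records.columns:
                raise ValueError(f"missing index column {col!r}")
            for ph in phenotypes:
                if ph not in records.columns:
                    raise ValueError(f"missing phenotype column {ph!r}")
                x = records[col].to_numpy(dtype=float)
                y = records[ph].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                row = {"tissue": tissue, "index_kind": kind, "phenotype": ph,
                       "n": int(ok.sum())}
                if ok.sum() >= 3 and np.ptp(x[ok]) > 0 and np.ptp(y[ok]) > 0:
                    r, p, n = pearson(x[ok], y[ok])
                    row.update(r=r, p=p, testable=True)
                else:
                    row.update(r=np.nan, p=np.nan, testable=False)
                rows.append(row)
    out = pd.DataFrame(rows)
    if bh_correct:
        from .degs import bh_adjust

        mask = out["testable"]
        q = np.full(len(out), np.nan)
        q[mask.to_numpy()] = bh_adjust(out.loc[mask, "p"].to_numpy())
        out["q"] = q
    return out
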