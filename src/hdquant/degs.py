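"""Differential-expression gene (DEG) calling and set accounting.

A gene is called differentially expressed between two conditions when its
|log2 fold change| exceeds 0.5 and its Benjamini-Hochberg-adjusted q-value
falls below 0.05 (both strict).  DEG sets from different contrasts are
partitioned into unique and shared components per direction, and fixed gene
sets can be summarised by histograms of log2 fold change against a
reference group to quantify rescue toward reference expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "call_degs",
    "partition_sets",
    "percent_reduction",
    "rescue_histogram",
    "zscore",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    For sorted p-values, q_(i) = min_{j>=i} p_(j) * m / j, capped at 1 and
    returned in the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(table: pd.DataFrame, lfc_threshold: float = 0.5,
              q_threshold: float = 0.05) -> pd.DataFrame:
    """Call per-gene DEG status from a (gene, log2fc, pvalue) table.

    BH adjustment runs over the table's full p-value vector.  Status is
    'up' when log2fc > +lfc_threshold and q < q_threshold, 'down' when
    log2fc < -lfc_threshold and q < q_threshold, else 'ns'; both
    inequalities are strict, so a fold change sitting exactly on the
    threshold is not called.
    """
    for col in ("gene", "log2fc", "pvalue"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    if table["gene"].duplicated().any():
        raise ValueError("duplicate gene ids in DE table")
    out = table.copy()
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    sig = out["qvalue"] < q_threshold
    out["status"] = np.select(
        [sig & (out["log2fc"] > lfc_threshold), sig & (out["log2fc"] < -lfc_threshold)],
        ["up", "down"], default="ns",
    )
    return out


def partition_sets(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Partition two contrasts' DEG sets into unique/shared, per direction.

    Both inputs are `call_degs` outputs over the same gene universe.
    Returns one row per (direction, part) with counts and sorted gene lists,
    satisfying a_only + shared = total(A) and b_only + shared = total(B).
    """
    ua, ub = set(calls_a["gene"]), set(calls_b["gene"])
    if ua != ub:
        raise ValueError(
            f"gene universes differ; symmetric difference size {len(ua ^ ub)}: "
            f"{sorted(ua ^ ub)[:10]}..."
        )
    rows = []
    for direction in ("up", "down"):
        a = set(calls_a.loc[calls_a["status"] == direction, "gene"])
        b = set(calls_b.loc[calls_b["status"] == direction, "gene"])
        for part, genes in (("a_only", a - b), ("shared", a & b), ("b_only", b - a)):
            rows.append({"direction": direction, "part": part,
                         "count": len(genes), "genes": sorted(genes)})
    return pd.DataFrame(rows)


def percent_reduction(total_a: int, total_b: int) -> tuple[float, int]:
    """Percent reduction in DEG burden from contrast A to contrast B.

    Returns ``(exact_percent, rounded_percent)`` where the exact value is
    100 * (total_a - total_b) / total_a.
    """
    if total_a <= 0:
        raise ValueError("total_a must be positive")
    exact = 100.0 * (total_a - total_b) / total_a
    return exact, int(round(exact))


def rescue_histogram(gene_set, lfc_by_group: dict[str, pd.Series],
                     bin_width: float = 0.25) -> dict:
    """Histogram each group's log2FC-vs-reference over a fixed gene set.

    ``lfc_by_group`` maps a group label to a gene-indexed Series of log2
    fold changes against the reference condition.  Bins of ``bin_width``
    are centred on zero and shared across groups; the summary for each
    group includes mean log2FC and mean |log2FC|, the latter being the
    "distance from reference" used to rank groups.
    """
    genes = sorted(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    vals = {}
    for g, ser in lfc_by_group.items():
        missing = set(genes) - set(ser.index)
        if missing:
            raise ValueError(f"group {g!r} missing genes: {sorted(missing)[:10]}")
        vals[g] = ser.loc[genes].to_numpy(dtype=float)
    vmax = max(np.abs(v).max() for v in vals.values())
    half = int(np.ceil(vmax / bin_width + 0.5))
    edges = (np.arange(-half, half + 1) - 0.5) * bin_width  # zero-centred bins
    out = {"bin_edges": edges, "groups": {}}
    for g, v in vals.items():
        counts, _ = np.histogram(v, bins=edges)
        out["groups"][g] = {
            "counts": counts,
            "mean_lfc": float(v.mean()),
            "mean_abs_lfc": float(np.abs(v).mean()),
            "n": len(v),
        }
    ranked = sorted(out["groups"], key=lambda g: out["groups"][g]["mean_abs_lfc"])
    out["closest_to_reference"] = ranked[0]
    return out


def zscore(expression: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Standardise each gene row to mean 0 and sample s.d. 1.

    Constant rows are emitted as zeros; the returned Series flags them.
    """
    if expression.shape[1] < 2:
        raise ValueError("z-scores require at least 2 samples")
    mean = expression.mean(axis=1)
    sd = expression.std(axis=1, ddof=1)
    constant = sd == 0
    safe_sd = sd.mask(constant, 1.0)
    z = expression.sub(mean, axis=0).div(safe_sd, axis=0)
    z[constant] = 0.0
    return z, constant
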