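"""Marker-panel estimation of cell-type composition from bulk RNA-seq.

The procedure builds pseudobulk expression profiles per annotated cell type
from a reference single-cell dataset, scores each gene's cell-type
specificity by normalised Shannon entropy, selects a small marker panel per
cell type, and reads relative cell-type abundance in bulk libraries as the
mean reference-normalised expression of the panel.

Specificity of a gene with pseudobulk abundance distribution p over N cell
types is s = 1 - H(p)/log2(N), where H is the Shannon entropy in bits:
s = 1 for a gene expressed in a single type, s = 0 for uniform expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "DEFAULT_MERGE_MAP",
    "build_pseudobulk",
    "compute_specificity",
    "select_markers",
    "estimate_composition",
    "compare_composition",
]

# Coarse grouping used for the striatal reference annotation: direct- and
# indirect-pathway medium spiny neurons form one MSN class, interneuron and
# progenitor subtypes form "other_neuron", and rare non-neural vascular /
# ependymal types are pooled as "other".
DEFAULT_MERGE_MAP: dict[str, str] = {
    "dMSN": "MSN",
    "iMSN": "MSN",
    "GABAergic_interneuron": "other_neuron",
    "cholinergic_interneuron": "other_neuron",
    "parvalbumin_interneuron": "other_neuron",
    "Foxp2_neuron": "other_neuron",
    "neural_progenitor": "other_neuron",
    "astrocyte": "astrocyte",
    "microglia": "microglia",
    "oligodendrocyte": "oligodendrocyte",
    "ependymal": "other",
    "mural": "other",
    "endothelial": "other",
}


def build_pseudobulk(
    sc: ad.AnnData,
    merge: dict[str, str] | None = None,
    pseudocount: float = 1.0,
    gene_lengths: pd.Series | None = None,
    cell_type_key: str = "cell_type",
    condition_key: str = "condition",
) -> dict[str, pd.DataFrame]:
    """Sum single-cell counts into per-cell-type pseudobulk TPM, per condition.

    Counts are summed over all cells of each (merged) type within each
    condition, a pseudocount is added to every gene, and each column is
    scaled to sum to one million.  When ``gene_lengths`` is given, summed
    counts are divided by length (in kb) before the per-million scaling,
    i.e. classical TPM; by default no length term is applied, the natural
    reading for UMI counts.

    Returns ``{condition: genes x coarse-types DataFrame}``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    labels = sc.obs[cell_type_key].astype(str)
    if merge is not None:
        unknown = sorted(set(labels) - set(merge))
        if unknown:
            raise ValueError(f"cell labels missing from merge map: {unknown}")
        labels = labels.map(merge)
    conditions = sc.obs[condition_key].astype(str)

    X = sc.X
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)

    out: dict[str, pd.DataFrame] = {}
    for cond in conditions.unique():
        cmask = (conditions == cond).to_numpy()
        cols = {}
        for ct in sorted(labels.unique()):
            mask = cmask & (labels == ct).to_numpy()
            cols[ct] = X[mask].sum(axis=0) + pseudocount
        df = pd.DataFrame(cols, index=sc.var_names)
        if gene_lengths is not None:
            df = df.div(gene_lengths.reindex(df.index).to_numpy() / 1e3, axis=0)
        df = df / df.sum(axis=0) * 1e6
        out[cond] = df
    return out


def compute_specificity(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-gene entropy H (bits) and specificity s over cell types.

    ``profile`` is a genes x cell-types pseudobulk TPM table for the
    reference condition.  Each gene's row is normalised to a probability
    vector p; H = -sum p_i log2 p_i (0 log 0 := 0) and s = 1 - H/log2 N.
    Returns a frame with columns H, s, home_type (argmax type, first-index
    tie-break) and home_tpm.
    """
    n_types = profile.shape[1]
    if n_types < 2:
        raise ValueError("specificity requires at least 2 cell types")
    vals = profile.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative abundances")
    p = vals / vals.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    H = -plogp.sum(axis=1)
    s = 1.0 - H / np.log2(n_types)
    home_idx = np.argmax(vals, axis=1)
    return pd.DataFrame(
        {"H": H, "s": s,
         "home_type": profile.columns.to_numpy()[home_idx],
         "home_tpm": vals[np.arange(len(profile)), home_idx]},
        index=profile.index,
    )


def select_markers(
    spec: pd.DataFrame,
    bulk_detected: pd.Series | None = None,
    min_tpm: float = 50.0,
    min_specificity: float = 0.40,
    top_k: int = 20,
) -> pd.DataFrame:
    """Choose up to ``top_k`` marker genes per cell type.

    A gene is a candidate only for its home (argmax-abundance) type and must
    be detected in every bulk sample (``bulk_detected``), reach ``min_tpm``
    in its home type (inclusive), and exceed ``min_specificity`` (strict).
    Candidates are ranked by s descending, ties by home_tpm descending then
    gene name, and truncated to ``top_k``.

    Returns a long frame (cell_type, rank, gene, s, home_tpm); cell types
    with no candidate are absent and trigger a warning.
    """
    df = spec.copy()
    if bulk_detected is not None:
        df = df[bulk_detected.reindex(df.index).fillna(False).astype(bool)]
    df = df[(df["home_tpm"] >= min_tpm) & (df["s"] > min_specificity)]
    rows = []
    for ct in spec["home_type"].unique():
        sub = df[df["home_type"] == ct].copy()
        if sub.empty:
            warnings.warn(f"no marker candidates for cell type {ct!r}")
            continue
        sub["_gene"] = sub.index
        sub = sub.sort_values(by=["s", "home_tpm", "_gene"],
                              ascending=[False, False, True], kind="mergesort")
        sub = sub.head(top_k)
        for rank, (gene, r) in enumerate(sub.iterrows(), start=1):
            rows.append({"cell_type": ct, "rank": rank, "gene": gene,
                         "s": r["s"], "home_tpm": r["home_tpm"]})
    return pd.DataFrame(rows, columns=["cell_type", "rank", "gene", "s", "home_tpm"])


def estimate_composition(
    bulk: pd.DataFrame,
    panel: pd.DataFrame,
    reference_samples: list[str],
) -> pd.DataFrame:
    """Relative cell-type abundance per bulk sample (1 = reference mean).

    Each marker's TPM is divided by its mean over the reference samples;
    a sample's composition for a cell type is the mean of its normalised
    markers.  Markers with zero reference mean are dropped with a warning.
    Returns a samples x cell-types frame.
    """
    if not reference_samples:
        raise ValueError("reference_samples must be non-empty")
    missing = set(reference_samples) - set(bulk.columns)
    if missing:
        raise ValueError(f"reference samples absent from bulk: {sorted(missing)}")
    absent = set(panel["gene"]) - set(bulk.index)
    if absent:
        raise ValueError(f"panel genes absent from bulk: {sorted(absent)}")

    ref_mean = bulk.loc[:, reference_samples].mean(axis=1)
    comp = {}
    for ct, sub in panel.groupby("cell_type", sort=True):
        genes = [g for g in sub["gene"] if ref_mean[g] > 0]
        dropped = set(sub["gene"]) - set(genes)
        if dropped:
            warnings.warn(f"markers with zero reference mean dropped: {sorted(dropped)}")
        if not genes:
            continue
        norm = bulk.loc[genes].div(ref_mean[genes], axis=0)
        comp[ct] = norm.mean(axis=0)
    return pd.DataFrame(comp)


def compare_composition(
    composition: pd.DataFrame,
    groups: pd.Series,
    confidence: float = 0.95,
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Group means, t-based confidence intervals and CI-overlap flags.

    ``groups`` maps sample id to group label.  For each cell type and group
    the mean and a two-sided t interval (n-1 df) over per-sample composition
    values is computed; zero-variance groups give degenerate point
    intervals.  ``overlaps_reference`` reports whether each group's interval
    intersects the ``reference_group``'s interval (first label in sorted
    order when not given) for that cell type.
    """
    groups = groups.reindex(composition.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    if reference_group is not None and reference_group not in set(groups):
        raise ValueError(f"reference group {reference_group!r} not present")
    rows = []
    for ct in composition.columns:
        cis = {}
        for g, sub in composition.groupby(groups.to_numpy(), sort=True)[ct]:
            n = len(sub)
            if n < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
            m = sub.mean()
            se = sub.std(ddof=1) / np.sqrt(n)
            tq = stats.t.ppf(0.5 + confidence / 2, df=n - 1)
            cis[g] = (m, m - tq * se, m + tq * se, n)
        ref_group = reference_group if reference_group is not None else sorted(cis)[0]
        for g, (m, lo, hi, n) in cis.items():
            rlo, rhi = cis[ref_group][1], cis[ref_group][2]
            rows.append({
                "cell_type": ct, "group": g, "n": n, "mean": m,
                "ci_low": lo, "ci_high": hi,
                "overlaps_reference": bool(max(lo, rlo) <= min(hi, rhi)),
            })
    return pd.DataFrame(rows)
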