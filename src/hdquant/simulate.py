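"""Synthetic-data generators mirroring the structure of each analysis input.

Every generator takes an explicit seed, stores its analytic ground truth
alongside the noisy realisation, and never recomputes the truth from the
data.  Defaults emulate the study system: an inherited (CAG)120 allele with
expansion-biased somatic mosaicism in striatum, single-cell striatal
reference data with ~50% depletion of medium spiny neurons (MSNs) in the
disease condition, three bulk RNA-seq libraries per group, and per-nucleus
fluorescence with a known nuclear-retention ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .instability import InstabilityIndices, PeakTable

__all__ = [
    "FLASimConfig",
    "SCSimConfig",
    "DESimConfig",
    "simulate_fla",
    "simulate_sc",
    "simulate_bulk",
    "simulate_de",
    "simulate_nuclei",
    "simulate_sequences",
    "biased_delta_distribution",
]


# ---------------------------------------------------------------------------
# fragment length analysis


def biased_delta_distribution(mean_delta: float, spread: int = 4) -> dict[int, float]:
    """Discrete repeat-change distribution with a given mean.

    A discretised Gaussian (s.d. ``spread``/2 repeat units) truncated at
    ±``spread`` around ``mean_delta`` and renormalised.  Truncation at two
    standard deviations keeps every peak of the cluster above 13.5% of the
    modal height, i.e. above the conventional 10% analysis threshold, so
    the height-weighted index of the noise-free cluster equals the
    distribution mean; the mass is nearly symmetric about the centre and
    the mean matches ``mean_delta`` to about 1e-3 of a repeat unit.
    Convenient for building expansion-biased (``mean_delta > 0``) or
    contraction-biased cohorts.
    """
    ks = np.arange(int(np.ceil(mean_delta - spread)),
                   int(np.floor(mean_delta + spread)) + 1)
    w = np.exp(-0.5 * ((ks - mean_delta) / (spread / 2.0)) ** 2)
    w /= w.sum()
    return {int(k): float(p) for k, p in zip(ks, w) if p > 0}


@dataclass
class FLASimConfig:
    """Electropherogram simulation around an inherited allele.

    ``repeat_delta_distribution`` is a probability mass over integer
    repeat-unit changes; ``stutter_decay`` is the height fraction carried by
    the minus-one-repeat PCR stutter satellite of each true peak.
    """

    inherited_repeat: int = 120
    repeat_delta_distribution: dict[int, float] = field(default_factory=lambda: {0: 1.0})
    stutter_decay: float = 0.0
    bp_per_repeat: float = 3.0
    peak_sd_bp: float = 0.35
    noise_sd: float = 0.0
    n_scan_points: int = 4000
    inherited_peak_bp: float = 360.0
    peak_scale: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.repeat_delta_distribution.values())
        if total <= 0:
            raise ValueError("repeat delta distribution has zero total mass")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("repeat delta distribution must sum to 1")
        if any(p < 0 for p in self.repeat_delta_distribution.values()):
            raise ValueError("negative probability mass")
        if not 0 <= self.stutter_decay < 1:
            raise ValueError("stutter_decay must lie in [0, 1)")
        if self.bp_per_repeat <= 0:
            raise ValueError("bp_per_repeat must be positive")


def _ground_truth_indices(dist: dict[int, float]) -> InstabilityIndices:
    exp = sum(p * d for d, p in dist.items() if d > 0)
    con = sum(p * d for d, p in dist.items() if d < 0)
    return InstabilityIndices(
        expansion_index=exp, contraction_index=con,
        instability_index=exp + con, threshold_fraction=0.0,
        n_peaks_used=len(dist),
    )


def simulate_fla(config: FLASimConfig):
    """Simulate one capillary trace.

    Returns ``(positions_bp, intensities, truth_peaks, truth_indices)``.
    The true peak table places a Gaussian at the inherited size plus
    ``delta * bp_per_repeat`` for each delta, with height proportional to its
    probability mass; each true peak sheds a minus-one-unit stutter
    satellite carrying ``stutter_decay`` of its height.  Ground-truth
    indices are the analytic expectations over the delta distribution,
    computed before stutter and noise are applied.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    truth_indices = _ground_truth_indices(cfg.repeat_delta_distribution)

    heights: dict[int, float] = {}
    for d, p in cfg.repeat_delta_distribution.items():
        heights[d] = heights.get(d, 0.0) + cfg.peak_scale * p
    if cfg.stutter_decay > 0:
        for d in sorted(heights, reverse=True):
            heights[d - 1] = heights.get(d - 1, 0.0) + cfg.stutter_decay * heights[d]

    deltas = np.array(sorted(heights))
    centers = cfg.inherited_peak_bp + deltas * cfg.bp_per_repeat
    hvec = np.array([heights[d] for d in deltas])
    truth_peaks = PeakTable(centers, hvec)

    span = max(np.abs(deltas).max(initial=0) + 5, 10) * cfg.bp_per_repeat
    pos = np.linspace(cfg.inherited_peak_bp - span, cfg.inherited_peak_bp + span,
                      cfg.n_scan_points)
    sig = np.zeros_like(pos)
    for c, h in zip(centers, hvec):
        sig += h * np.exp(-0.5 * ((pos - c) / cfg.peak_sd_bp) ** 2)
    if cfg.noise_sd > 0:
        sig = np.clip(sig + rng.normal(0, cfg.noise_sd, sig.shape), 0, None)
    return pos, sig, truth_peaks, truth_indices


# ---------------------------------------------------------------------------
# single-cell reference and bulk mixtures


@dataclass
class SCSimConfig:
    """Cell-type-structured single-cell counts with planted markers.

    One designated cell type (the first, "MSN" by default) is depleted by
    ``depletion_factor`` in the disease condition, emulating MSN loss.
    """

    n_cell_types: int = 4
    n_genes: int = 600
    markers_per_type: int = 25
    marker_fold: float = 30.0
    cells_per_type_per_condition: int = 120
    depletion_factor: float = 0.5
    depleted_type_index: int = 0
    library_size: float = 2000.0
    dispersion: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.depletion_factor <= 1:
            raise ValueError("depletion_factor must lie in (0, 1]")
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError("more planted markers than genes")
        if min(self.n_cell_types, self.n_genes, self.cells_per_type_per_condition) < 1:
            raise ValueError("counts must be >= 1")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_sc(config: SCSimConfig) -> ad.AnnData:
    """Simulate an annotated single-cell count matrix.

    Returns an AnnData with obs columns ``cell_type`` (fine label) and
    ``condition`` ('reference' / 'disease'), var column ``marker_of`` naming
    each planted marker's home type (empty string otherwise), and
    ``uns['truth']`` holding the config-derived ground truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    types = [f"type{i}" for i in range(cfg.n_cell_types)]

    # per-type relative expression profiles: lognormal baseline shared
    # across types, markers up-weighted marker_fold in their home type
    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    rel = np.tile(base, (cfg.n_cell_types, 1))
    marker_of = np.array([""] * cfg.n_genes, dtype=object)
    gi = 0
    for t in range(cfg.n_cell_types):
        for _ in range(cfg.markers_per_type):
            rel[t, gi] *= cfg.marker_fold
            marker_of[gi] = types[t]
            gi += 1
    rel = rel / rel.sum(axis=1, keepdims=True)

    blocks, obs_type, obs_cond = [], [], []
    for cond in ("reference", "disease"):
        for t in range(cfg.n_cell_types):
            n_cells = cfg.cells_per_type_per_condition
            if cond == "disease" and t == cfg.depleted_type_index:
                n_cells = max(1, int(round(n_cells * cfg.depletion_factor)))
            mu = cfg.library_size * rel[t]
            blocks.append(_nb_counts(rng, np.tile(mu, (n_cells, 1)), cfg.dispersion))
            obs_type += [types[t]] * n_cells
            obs_cond += [cond] * n_cells

    X = np.vstack(blocks)
    adata = ad.AnnData(
        X=X.astype(np.int64),
        obs=pd.DataFrame({"cell_type": obs_type, "condition": obs_cond},
                         index=[f"cell{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame({"marker_of": marker_of},
                         index=[f"gene{i}" for i in range(cfg.n_genes)]),
    )
    adata.uns["truth"] = {
        "depleted_type": types[cfg.depleted_type_index],
        "depletion_factor": cfg.depletion_factor,
        "marker_genes": {
            t: [g for g, m in zip(adata.var_names, marker_of) if m == t] for t in types
        },
    }
    return adata


def simulate_bulk(proportions: pd.DataFrame, profiles: pd.DataFrame,
                  noise_cv: float = 0.1, seed: int = 0) -> pd.DataFrame:
    """Simulate bulk TPM libraries as noisy mixtures of cell-type profiles.

    ``proportions``: samples x cell types, each row summing to 1.
    ``profiles``: genes x cell types expression.  Each sample is the
    proportion-weighted sum of profiles, perturbed per gene by lognormal
    multiplicative noise with coefficient of variation ``noise_cv`` (mean
    exactly 1), then rescaled to sum to 1e6.  Ground-truth proportions are
    attached as ``result.attrs['true_proportions']``.
    """
    if (proportions.to_numpy() < 0).any():
        raise ValueError("negative proportions")
    if not np.allclose(proportions.sum(axis=1), 1.0):
        raise ValueError("each sample's proportions must sum to 1")
    missing = set(proportions.columns) - set(profiles.columns)
    if missing:
        raise ValueError(f"profiles missing cell types: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    P = profiles[proportions.columns].to_numpy()  # genes x types
    W = proportions.to_numpy()                    # samples x types
    X = P @ W.T                                   # genes x samples
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=X.shape)
        X = X * noise
    X = X / X.sum(axis=0, keepdims=True) * 1e6
    out = pd.DataFrame(X, index=profiles.index, columns=proportions.index)
    out.attrs["true_proportions"] = proportions.copy()
    return out


# ---------------------------------------------------------------------------
# differential expression statistics


@dataclass
class DESimConfig:
    """Two-group log-expression experiment yielding a DE statistics table.

    Per-gene log2 expression is Gaussian with s.d. ``sqrt(dispersion)``;
    a ``true_de_fraction`` of genes carries a log2 fold change drawn from
    ``Normal(effect_mean, effect_sd)`` with random sign.  Statistics come
    from a per-gene two-sample Welch t-test on the log scale — a simple
    stand-in engine for generating calibrated p-values, not a count-model
    DE fit.
    """

    n_genes: int = 2000
    true_de_fraction: float = 0.1
    effect_mean: float = 1.5
    effect_sd: float = 0.5
    n_per_group: int = 3
    dispersion: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.true_de_fraction <= 1:
            raise ValueError("true_de_fraction must lie in [0, 1]")


def simulate_de(config: DESimConfig) -> pd.DataFrame:
    """Simulate a per-gene DE table (gene, log2fc, pvalue, is_true_de, true_log2fc)."""
    from scipy import stats

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_true = int(round(cfg.n_genes * cfg.true_de_fraction))
    true_lfc = np.zeros(cfg.n_genes)
    if n_true:
        idx = rng.choice(cfg.n_genes, n_true, replace=False)
        mags = rng.normal(cfg.effect_mean, cfg.effect_sd, n_true)
        true_lfc[idx] = mags * rng.choice([-1.0, 1.0], n_true)
    sd = np.sqrt(cfg.dispersion)
    a = rng.normal(0.0, sd, (cfg.n_genes, cfg.n_per_group))
    b = rng.normal(true_lfc[:, None], sd, (cfg.n_genes, cfg.n_per_group))
    t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    return pd.DataFrame(
        {"gene": [f"gene{i}" for i in range(cfg.n_genes)],
         "log2fc": b.mean(axis=1) - a.mean(axis=1),
         "pvalue": p,
         "is_true_de": true_lfc != 0,
         "true_log2fc": true_lfc}
    )


# ---------------------------------------------------------------------------
# imaging and sequences


def simulate_nuclei(n_images: int, nuclei_per_image: int,
                    true_retention_ratio: float, noise_cv: float = 0.2,
                    seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-image and per-nucleus fluorescence summary tables.

    Each image gets a baseline signal density; nucleus intensity densities
    are the baseline times ``true_retention_ratio`` times lognormal
    multiplicative noise with mean exactly 1, so the expected retention
    score of every nucleus equals the true ratio.
    """
    if true_retention_ratio <= 0:
        raise ValueError("true_retention_ratio must be positive")
    rng = np.random.default_rng(seed)
    img_rows, nuc_rows = [], []
    for i in range(n_images):
        area = 1e6
        baseline = rng.uniform(5.0, 15.0)
        img_rows.append({"image_id": f"img{i}", "total_intensity": baseline * area,
                         "area": area, "mouse_id": f"m{i % 3}", "group": "sim"})
        if noise_cv > 0:
            s2 = np.log1p(noise_cv**2)
            noise = rng.lognormal(-s2 / 2, np.sqrt(s2), nuclei_per_image)
        else:
            noise = np.ones(nuclei_per_image)
        nuc_area = rng.uniform(50.0, 150.0, nuclei_per_image)
        density = true_retention_ratio * baseline * noise
        for j in range(nuclei_per_image):
            nuc_rows.append({"nucleus_id": f"img{i}_n{j}", "image_id": f"img{i}",
                             "intensity": density[j] * nuc_area[j], "area": nuc_area[j],
                             "aggregate_positive": False, "abnormal_envelope": False})
    images = pd.DataFrame(img_rows)
    nuclei = pd.DataFrame(nuc_rows)
    images.attrs["true_retention_ratio"] = true_retention_ratio
    return images, nuclei


_NON_CAG_CODONS = None


def simulate_sequences(n_genes: int, plant_rate: float, seed: int = 0,
                       length: int = 300, planted_units: int = 4) -> pd.DataFrame:
    """Simulate nucleotide sequences with CAG runs planted at a known rate.

    Background sequence is built from random non-CAG codons and re-drawn if
    a frame-shifted (CAG)>=3 run arises across codon boundaries, so the
    ``planted`` column is an exact ground truth; a fraction ``plant_rate``
    of genes gets a ``(CAG)^planted_units`` run inserted at a random codon
    boundary (its non-CAG flanks cannot extend the run).  Returns a frame
    (gene, sequence, planted).
    """
    if not 0 <= plant_rate <= 1:
        raise ValueError("plant_rate must lie in [0, 1]")
    global _NON_CAG_CODONS
    if _NON_CAG_CODONS is None:
        _NON_CAG_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                           if a + b + c != "CAG"]
    rng = np.random.default_rng(seed)
    n_codons = length // 3
    rows = []
    for i in range(n_genes):
        codons = list(rng.choice(_NON_CAG_CODONS, n_codons))
        while "CAGCAGCAG" in "".join(codons):
            codons = list(rng.choice(_NON_CAG_CODONS, n_codons))
        planted = bool(rng.random() < plant_rate)
        if planted:
            pos = int(rng.integers(0, n_codons + 1))
            codons[pos:pos] = ["CAG"] * planted_units
        rows.append({"gene": f"gene{i}", "sequence": "".join(codons), "planted": planted})
    return pd.DataFrame(rows)
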