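"""Somatic repeat-instability indices from capillary-electrophoresis peak data.

Fragment length analysis (FLA) of a PCR across an expanded CAG tract yields
an electropherogram whose peaks correspond to somatic repeat-length variants.
The instability index summarises the mosaicism of a tissue as the
peak-height-weighted mean repeat-unit change relative to the inherited
allele (measured in tail/ear DNA): peaks above a height threshold are
normalised to unit total height and each contributes its weight times its
signed repeat-unit change.  The expansion index restricts the sum to
positive changes, the contraction index to negative changes, and the overall
instability index is exactly their sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "PeakTable",
    "RepeatCalibration",
    "CalibratedPeaks",
    "InstabilityIndices",
    "call_peaks",
    "assign_repeat_units",
    "compute_indices",
    "summarize_group",
    "read_peak_table",
    "write_indices",
]


@dataclass
class PeakTable:
    """Sized peaks from a capillary trace: fragment size (bp) vs height."""

    sizes_bp: np.ndarray
    heights: np.ndarray
    sample_id: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        self.sizes_bp = np.asarray(self.sizes_bp, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.sizes_bp.shape != self.heights.shape:
            raise ValueError("sizes_bp and heights must have equal length")
        if np.any(self.heights < 0):
            raise ValueError("peak heights must be non-negative")
        if self.sizes_bp.size > 1 and np.any(np.diff(self.sizes_bp) <= 0):
            raise ValueError("fragment sizes must be strictly increasing")

    def __len__(self) -> int:
        return self.sizes_bp.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"size_bp": self.sizes_bp, "height": self.heights,
             "sample_id": self.sample_id, "tissue": self.tissue}
        )


@dataclass
class RepeatCalibration:
    """Maps fragment size to repeat-unit change relative to the inherited allele.

    ``inherited_repeat`` is the germline repeat count (from tail/ear DNA);
    ``inherited_peak_bp`` is the fragment size assigned to that allele;
    one CAG unit adds ``bp_per_repeat`` (3.0 bp) to the amplicon.
    """

    inherited_repeat: int
    inherited_peak_bp: float
    bp_per_repeat: float = 3.0

    def __post_init__(self) -> None:
        if self.inherited_repeat <= 0:
            raise ValueError("inherited_repeat must be positive")
        if self.bp_per_repeat <= 0:
            raise ValueError("bp_per_repeat must be positive")


@dataclass
class CalibratedPeaks:
    """Peaks expressed as integer repeat-unit changes from the inherited allele."""

    deltas: np.ndarray
    heights: np.ndarray
    anchor_missing: bool = False
    sample_id: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=int)
        self.heights = np.asarray(self.heights, dtype=float)

    def __len__(self) -> int:
        return self.deltas.size


@dataclass
class InstabilityIndices:
    """Height-weighted mean repeat-unit change, split by sign.

    Invariant: ``instability_index == expansion_index + contraction_index``
    exactly; expansion is non-negative, contraction non-positive.
    """

    expansion_index: float
    contraction_index: float
    instability_index: float
    threshold_fraction: float
    n_peaks_used: int
    sample_id: str = ""
    tissue: str = ""


def call_peaks(positions_bp, intensities, min_prominence: float = 0.05,
               smooth_sd_bp: float = 0.1) -> PeakTable:
    """Locate peaks in a sampled electropherogram.

    The trace is first lightly smoothed with a Gaussian kernel of
    ``smooth_sd_bp`` (suppressing sampling-resolution noise while leaving
    peaks, which are an order of magnitude wider, essentially intact); local
    maxima with prominence at least ``min_prominence`` times the global
    maximum are then returned, with apex positions refined by quadratic
    interpolation through the three samples around each maximum.

    A flat (or all-zero) signal yields an empty table.  Non-increasing
    positions are rejected.
    """
    from scipy.ndimage import gaussian_filter1d

    pos = np.asarray(positions_bp, dtype=float)
    sig = np.asarray(intensities, dtype=float)
    if pos.size < 3:
        raise ValueError("signal must contain at least 3 samples")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    raw = sig
    if smooth_sd_bp > 0:
        spacing = float(np.median(np.diff(pos)))
        sigma_samples = smooth_sd_bp / spacing
        if sigma_samples >= 0.5:
            sig = gaussian_filter1d(sig, sigma_samples, mode="nearest")
    peak_max = float(sig.max(initial=0.0))
    if peak_max <= 0 or np.allclose(sig, sig[0]):
        return PeakTable(np.empty(0), np.empty(0))

    idx, _ = find_peaks(sig, prominence=min_prominence * peak_max)
    sizes, heights = [], []
    for i in idx:
        x0, x1, x2 = pos[i - 1], pos[i], pos[i + 1]
        y0, y1, y2 = sig[i - 1], sig[i], sig[i + 1]
        # quadratic vertex through the three apex samples (uniform spacing
        # is not assumed)
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
        if a < 0:
            xv = -b / (2 * a)
            sizes.append(xv)
        else:  # degenerate curvature: keep the raw sample
            sizes.append(x1)
        # apex height from a local least-squares quadratic on the unsmoothed
        # trace: avoids the detection filter's attenuation of narrow peaks
        # while averaging point noise over the fit window
        lo, hi = max(i - 4, 0), min(i + 5, len(pos))
        if hi - lo >= 3:
            coef = np.polyfit(pos[lo:hi] - sizes[-1], raw[lo:hi], 2)
            heights.append(float(coef[2]))
        else:
            heights.append(float(raw[i]))
    order = np.argsort(sizes)
    return PeakTable(np.asarray(sizes)[order], np.asarray(heights)[order])


def assign_repeat_units(
    peaks: PeakTable,
    calib: RepeatCalibration,
    anchor_tolerance_bp: float = 1.5,
    reference: str = "inherited",
) -> CalibratedPeaks:
    """Convert fragment sizes to integer repeat-unit changes (deltas).

    Each peak's change is ``round((size - anchor_bp)/bp_per_repeat)``.  With
    ``reference='inherited'`` (default) the anchor is the calibrated
    inherited-allele size; with ``reference='modal'`` the tallest peak is
    re-anchored to delta 0.  Peaks rounding to the same delta have their
    heights summed.  If no peak lies within ``anchor_tolerance_bp`` of the
    anchor, the result is flagged ``anchor_missing``.
    """
    if len(peaks) == 0:
        raise ValueError("peak table is empty")
    if reference not in ("inherited", "modal"):
        raise ValueError("reference must be 'inherited' or 'modal'")
    anchor_bp = calib.inherited_peak_bp
    if reference == "modal":
        anchor_bp = float(peaks.sizes_bp[np.argmax(peaks.heights)])
    deltas = np.rint((peaks.sizes_bp - anchor_bp) / calib.bp_per_repeat).astype(int)
    anchor_missing = not bool(
        np.any(np.abs(peaks.sizes_bp - anchor_bp) <= anchor_tolerance_bp)
    )
    agg: dict[int, float] = {}
    for d, h in zip(deltas, peaks.heights):
        agg[int(d)] = agg.get(int(d), 0.0) + float(h)
    ds = np.array(sorted(agg), dtype=int)
    hs = np.array([agg[d] for d in ds])
    return CalibratedPeaks(ds, hs, anchor_missing=anchor_missing,
                           sample_id=peaks.sample_id, tissue=peaks.tissue)


def compute_indices(peaks: CalibratedPeaks, threshold_fraction: float = 0.10) -> InstabilityIndices:
    """Compute expansion, contraction and overall instability indices.

    Peaks with height below ``threshold_fraction`` of the tallest peak are
    discarded; surviving heights are normalised to sum to one, and each peak
    contributes weight times signed repeat-unit change.  The tallest peak
    always survives, so the result is defined for any non-empty input.
    """
    if len(peaks) == 0:
        raise ValueError("no calibrated peaks")
    if not 0 <= threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in [0, 1)")
    hmax = peaks.heights.max()
    keep = peaks.heights >= threshold_fraction * hmax
    d = peaks.deltas[keep].astype(float)
    w = peaks.heights[keep]
    w = w / w.sum()
    expansion = float(np.sum(w[d > 0] * d[d > 0]))
    contraction = float(np.sum(w[d < 0] * d[d < 0]))
    return InstabilityIndices(
        expansion_index=expansion,
        contraction_index=contraction,
        instability_index=expansion + contraction,
        threshold_fraction=threshold_fraction,
        n_peaks_used=int(keep.sum()),
        sample_id=peaks.sample_id,
        tissue=peaks.tissue,
    )


def summarize_group(indices: list[InstabilityIndices], groups: list[str]) -> pd.DataFrame:
    """Per-group mean and sample standard deviation for each index.

    A single-sample group gets s.d. 0 and is flagged in ``sd_defined``.
    """
    if len(indices) != len(groups):
        raise ValueError("one group label per sample required")
    rows = [
        {"group": g,
         "expansion": ix.expansion_index,
         "contraction": ix.contraction_index,
         "instability": ix.instability_index,
         "sample_id": ix.sample_id}
        for ix, g in zip(indices, groups)
    ]
    df = pd.DataFrame(rows)
    out = []
    for g, sub in df.groupby("group", sort=True):
        rec = {"group": g, "n": len(sub), "sd_defined": len(sub) > 1}
        for kind in ("expansion", "contraction", "instability"):
            rec[f"{kind}_mean"] = sub[kind].mean()
            rec[f"{kind}_sd"] = sub[kind].std(ddof=1) if len(sub) > 1 else 0.0
        out.append(rec)
    return pd.DataFrame(out)


def read_peak_table(path, sample_id: str = "", tissue: str = "") -> PeakTable:
    """Read a two-column CSV (size_bp, height) as exported from sizing software."""
    df = pd.read_csv(path)
    if not {"size_bp", "height"} <= set(df.columns):
        raise ValueError("peak CSV must have columns size_bp and height")
    df = df.sort_values("size_bp")
    return PeakTable(
        df["size_bp"].to_numpy(), df["height"].to_numpy(),
        sample_id=str(df["sample_id"].iloc[0]) if "sample_id" in df and sample_id == "" else sample_id,
        tissue=str(df["tissue"].iloc[0]) if "tissue" in df and tissue == "" else tissue,
    )


def write_indices(indices: list[InstabilityIndices], path) -> None:
    pd.DataFrame(
        [
            {"sample_id": ix.sample_id, "tissue": ix.tissue,
             "expansion": ix.expansion_index, "contraction": ix.contraction_index,
             "instability": ix.instability_index, "n_peaks": ix.n_peaks_used,
             "threshold": ix.threshold_fraction}
            for ix in indices
        ]
    ).to_csv(path, sep="\t", index=False)
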