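"""Image-level metrics from segmentation summary tables.

Works on per-image and per-nucleus tables exported by imaging software;
no segmentation or classification is performed here.  The nuclear
mRNA-retention score of a nucleus is its signal density (intensity/area)
divided by the whole image's baseline density, so a score of 1 means the
nucleus is no brighter than the image at large and scores above 1 indicate
nuclear accumulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "retention_scores",
    "positive_fraction",
    "region_intensity",
    "nuclei_density",
]

_NUC_COLS = {"nucleus_id", "image_id", "intensity", "area"}
_IMG_COLS = {"image_id", "total_intensity", "area"}


def _check(df: pd.DataFrame, cols: set, name: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    if (df["area"] <= 0).any():
        raise ValueError(f"{name} areas must be positive")


def retention_scores(nuclei: pd.DataFrame, images: pd.DataFrame) -> pd.DataFrame:
    """Nuclear retention score per nucleus.

    score = (nucleus intensity / nucleus area) / (image intensity / image
    area).  Every nucleus must reference an image with positive total
    intensity; intensities and areas must share units within an image.
    """
    _check(nuclei, _NUC_COLS, "nuclei")
    _check(images, _IMG_COLS, "images")
    img = images.set_index("image_id")
    unknown = set(nuclei["image_id"]) - set(img.index)
    if unknown:
        raise ValueError(f"nuclei reference unknown images: {sorted(unknown)}")
    if (img["total_intensity"] <= 0).any():
        bad = img.index[img["total_intensity"] <= 0].tolist()
        raise ValueError(f"zero or negative image intensity: {bad}")
    baseline = (img["total_intensity"] / img["area"]).reindex(nuclei["image_id"]).to_numpy()
    out = nuclei.copy()
    out["retention_score"] = (nuclei["intensity"] / nuclei["area"]).to_numpy() / baseline
    return out


def positive_fraction(nuclei: pd.DataFrame, flag: str,
                      images: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    """Percent of flagged nuclei per image, with per-mouse and group summaries.

    ``flag`` names a boolean column of the nuclei table (for example
    ``aggregate_positive`` or ``abnormal_envelope``).  Per-image percent is
    100 * flagged/total; the per-mouse value is the mean over that mouse's
    images; the group summary reports statistics over images (the plotting
    unit) and over mice (the biological replicate) when mouse/group columns
    are available via the images table.
    """
    if flag not in nuclei.columns:
        raise ValueError(f"nuclei table has no column {flag!r}")
    grouped = nuclei.groupby("image_id")[flag]
    per_image = pd.DataFrame({
        "n_nuclei": grouped.size(),
        "n_flagged": grouped.sum(),
    })
    per_image["percent"] = 100.0 * per_image["n_flagged"] / per_image["n_nuclei"]
    per_image = per_image.reset_index()
    out = {"per_image": per_image}
    if images is not None and {"mouse_id", "group"} <= set(images.columns):
        meta = images[["image_id", "mouse_id", "group"]]
        merged = per_image.merge(meta, on="image_id", how="left")
        out["per_mouse"] = (merged.groupby(["group", "mouse_id"])["percent"]
                            .agg(["mean", "count"]).reset_index()
                            .rename(columns={"mean": "percent", "count": "n_images"}))
        out["per_group_images"] = (merged.groupby("group")["percent"]
                                   .agg(["mean", "std", "count"]).reset_index())
        out["per_group_mice"] = (out["per_mouse"].groupby("group")["percent"]
                                 .agg(["mean", "std", "count"]).reset_index())
    return out


def region_intensity(images: pd.DataFrame) -> pd.Series:
    """Area-normalised fluorescent intensity per image/region (a.u.)."""
    _check(images, _IMG_COLS, "images")
    return images.set_index("image_id").eval("total_intensity / area")


def nuclei_density(nuclei: pd.DataFrame, images: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Nuclei counts per image with per-mouse means and group summaries.

    Images with zero nuclei are counted (the images table enumerates them);
    an empty images table is rejected.
    """
    if images.empty:
        raise ValueError("images table is empty")
    counts = nuclei.groupby("image_id").size()
    per_image = images[["image_id"]].copy()
    per_image["n_nuclei"] = counts.reindex(per_image["image_id"]).fillna(0).astype(int).to_numpy()
    out = {"per_image": per_image}
    if {"mouse_id", "group"} <= set(images.columns):
        merged = per_image.merge(images[["image_id", "mouse_id", "group"]], on="image_id")
        out["per_mouse"] = (merged.groupby(["group", "mouse_id"])["n_nuclei"]
                            .agg(["mean", "count"]).reset_index()
                            .rename(columns={"mean": "mean_nuclei", "count": "n_images"}))
        out["per_group_images"] = (merged.groupby("group")["n_nuclei"]
                                   .agg(["mean", "std", "count"]).reset_index())
    return out
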