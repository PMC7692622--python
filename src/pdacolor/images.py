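"""Well-plate image ingestion: ROI intensity extraction and normalization.

Turns brightfield well images (PNG/TIFF, 8- or 16-bit, gray or RGB) into
the tidy intensity tables the calibration models consume.  Pixel values are
rescaled to [0, 1] by bit depth at load; channel means are taken over
rectangular regions of interest (three per well by default, echoing the
assay's three-regions-per-well sampling); and every trial's means are
normalized against that trial's 0 uM control so the downstream
intercept-free calibration sees control intensities of ~1.

Image ingestion is the only place intensities may be floored (to EPS_FLOOR)
before logging; the math core instead raises on non-positive values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "EPS_FLOOR",
    "GRAYSCALE_METHODS",
    "ROISpec",
    "ImageRecord",
    "load_image",
    "extract_roi_means",
    "to_grayscale",
    "normalize_to_control",
    "default_roi_layout",
    "samples_from_images",
]

#: floor applied to channel means before they can reach a logarithm
EPS_FLOOR = 1e-6

#: grayscale conversion weights by method name
GRAYSCALE_METHODS = {
    "luma601": (0.299, 0.587, 0.114),  # ITU-R BT.601 luma
    "mean": (1 / 3, 1 / 3, 1 / 3),
}

CHANNELS = ("r", "g", "b")


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest in 0-based, half-open pixel coordinates."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI must have positive height and width")
        if self.row < 0 or self.col < 0:
            raise ValueError("ROI origin must be non-negative")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row, self.row + self.height),
                slice(self.col, self.col + self.width))

    def check_within(self, shape: tuple[int, int]) -> None:
        if self.row + self.height > shape[0] or self.col + self.width > shape[1]:
            raise ValueError(
                f"ROI {self} exceeds image bounds {shape[0]}x{shape[1]}"
            )


@dataclass
class ImageRecord:
    """A decoded well image plus its manifest metadata.

    ``pixels`` is float in [0, 1], shape (H, W) for grayscale images or
    (H, W, 3) for RGB.
    """

    path: str
    pixels: np.ndarray
    bit_depth: int
    trial: object = None
    condition: str | None = None
    concentration_uM: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


def load_image(path, manifest_row=None) -> ImageRecord:
    """Read a PNG/TIFF well image and rescale pixels to [0, 1] by bit depth.

    ``manifest_row`` may be a mapping with keys ``trial``, ``condition`` and
    ``concentration_uM`` (blank/NaN concentration means unknown).
    """
    raw = iio.imread(path)
    if raw.ndim == 3 and raw.shape[2] == 4:  # drop alpha
        raw = raw[:, :, :3]
    if raw.ndim not in (2, 3) or (raw.ndim == 3 and raw.shape[2] != 3):
        raise ValueError(
            f"unsupported channel layout {raw.shape} for {path}; "
            "need grayscale or 3-channel"
        )
    if raw.dtype == np.uint8:
        depth, pixels = 8, raw.astype(float) / 255.0
    elif raw.dtype == np.uint16:
        depth, pixels = 16, raw.astype(float) / 65535.0
    elif np.issubdtype(raw.dtype, np.floating):
        depth, pixels = 0, raw.astype(float)
        if pixels.min() < 0 or pixels.max() > 1:
            raise ValueError(f"float image {path} not in [0, 1]")
    else:
        raise ValueError(f"unsupported pixel dtype {raw.dtype} for {path}")

    meta = dict(manifest_row) if manifest_row is not None else {}
    conc = meta.get("concentration_uM")
    if conc is not None and (conc == "" or (isinstance(conc, float) and np.isnan(conc))):
        conc = None
    return ImageRecord(
        path=str(path), pixels=pixels, bit_depth=depth,
        trial=meta.get("trial"), condition=meta.get("condition"),
        concentration_uM=None if conc is None else float(conc),
    )


def extract_roi_means(image: ImageRecord, rois: Sequence[ROISpec]) -> pd.DataFrame:
    """Arithmetic per-channel mean over each ROI.

    Returns a DataFrame with one row per ROI (columns r, g, b; for a
    grayscale image all three carry the single channel value) plus a final
    ``well`` row holding the mean of the ROI means.
    """
    if not rois:
        raise ValueError("need at least one ROI")
    for roi in rois:
        roi.check_within(image.shape)
    rows = []
    for k, roi in enumerate(rois):
        patch = image.pixels[roi.slices]
        if image.n_channels == 1:
            m = float(patch.mean())
            rows.append({"roi": k, "r": m, "g": m, "b": m})
        else:
            mr, mg, mb = patch.reshape(-1, 3).mean(axis=0)
            rows.append({"roi": k, "r": float(mr), "g": float(mg), "b": float(mb)})
    df = pd.DataFrame(rows)
    well = df[["r", "g", "b"]].mean()
    df.loc[len(df)] = {"roi": "well", **well.to_dict()}
    return df


def to_grayscale(rgb, method: str = "luma601") -> float:
    """Convert RGB mean intensities to a single grayscale intensity.

    ``luma601`` applies the BT.601 luma weights 0.299/0.587/0.114 (the
    common convention of desktop image-analysis software); ``mean`` is the
    unweighted channel average.  Both weight sets sum to 1, so a gray input
    (R = G = B) maps to the common value under either method.
    """
    try:
        w = GRAYSCALE_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown grayscale method {method!r}; "
            f"choose from {sorted(GRAYSCALE_METHODS)}"
        ) from None
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("grayscale conversion needs r, g, b values")
    out = arr @ np.asarray(w)
    return float(out) if out.ndim == 0 else out


def default_roi_layout(
    shape: tuple[int, int], n_rois: int = 3, coverage: float = 0.10
) -> list[ROISpec]:
    """Equal square ROIs along the image diagonal, each >= ``coverage`` of pixels."""
    h, w = shape
    side = int(np.ceil(np.sqrt(coverage * h * w)))
    side = min(side, h, w)
    if n_rois == 1:
        starts = [((h - side) // 2, (w - side) // 2)]
    else:
        rows = np.linspace(0, h - side, n_rois).round().astype(int)
        cols = np.linspace(0, w - side, n_rois).round().astype(int)
        starts = list(zip(rows, cols))
    return [ROISpec(row=r, col=c, height=side, width=side) for r, c in starts]


def samples_from_images(
    manifest: pd.DataFrame, root: Path | str = ".",
    rois: Sequence[ROISpec] | None = None, n_rois: int = 3,
    grayscale_method: str = "luma601",
) -> pd.DataFrame:
    """Extract the tidy per-ROI intensity table from a manifest of images.

    The manifest needs columns ``image_path``, ``trial``, ``condition``,
    ``concentration_uM`` (blank = unknown).  Emits one row per ROI plus a
    ``well`` row per image, with raw (un-normalized) channel means in [0, 1]
    and the grayscale conversion method recorded.
    """
    root = Path(root)
    frames = []
    for _, row in manifest.iterrows():
        rec = load_image(root / row["image_path"], manifest_row=row)
        layout = rois if rois is not None else default_roi_layout(rec.shape, n_rois)
        means = extract_roi_means(rec, layout)
        means["gray"] = to_grayscale(means[["r", "g", "b"]].to_numpy(),
                                     method=grayscale_method)
        means.insert(0, "trial", rec.trial)
        means.insert(1, "condition", rec.condition)
        means.insert(2, "concentration_uM", rec.concentration_uM)
        means["image_path"] = row["image_path"]
        frames.append(means)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["grayscale_method"] = grayscale_method
    return out


def normalize_to_control(
    samples: pd.DataFrame, control_concentration: float = 0.0,
    channels: Sequence[str] = (*CHANNELS, "gray"), floor: float = EPS_FLOOR,
) -> pd.DataFrame:
    """Divide every channel mean by its trial's control-condition mean.

    Each trial must contain the control condition (``concentration_uM ==
    control_concentration``) with strictly positive means; after the
    division, control rows average to exactly 1 per trial and channel, so
    the operation is idempotent.  Normalized means are floored at ``floor``
    so downstream logarithms stay finite.
    """
    if "trial" not in samples.columns or "concentration_uM" not in samples.columns:
        raise ValueError("samples table needs 'trial' and 'concentration_uM' columns")
    present = [ch for ch in channels if ch in samples.columns]
    if not present:
        raise ValueError("samples table has none of the requested channels")
    out = samples.copy()
    for trial, sub in samples.groupby("trial"):
        is_ctrl = sub["concentration_uM"] == control_concentration
        if not is_ctrl.any():
            raise ValueError(
                f"trial {trial!r} has no control condition at "
                f"{control_concentration} uM"
            )
        ref = sub.loc[is_ctrl, present].mean()
        if (ref <= 0).any():
            bad = ref.index[ref <= 0].tolist()
            raise ValueError(f"trial {trial!r} control mean non-positive for {bad}")
        idx = sub.index
        out.loc[idx, present] = np.maximum(
            sub[present] / ref, floor
        )
    out.attrs["normalization"] = "control"
    return out
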