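"""Synthetic assay data with known ground truth.

Emulates the optical signal of the dopamine-to-polydopamine colorimetric
assay: three replicate trials, six calibration concentrations (0-125 uM),
three regions of interest per well.  Channel means follow the exponential
decay law ``gain_i * alpha_j * exp(-beta_j C)`` — a per-trial multiplicative
gain models plate-to-plate illumination differences, additive Gaussian
noise models measurement scatter — and the defaults are the dopamine-first
reference coefficients so that calibrating on generated data recovers
familiar numbers.

Two output routes share one statistical model: tidy intensity tables (CSV)
for the table-driven pipeline, and rendered 8-bit PNG well images (uniform
background plus pixel noise plus optional dark "colloidal PDA" speckles)
for the full image-extraction pipeline.  A ground-truth manifest records
the noiseless means and trial gains; the estimation path never reads it.

Randomness is reproducible: one root seed, with independent child streams
per (trial, well) so adding wells never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .images import EPS_FLOOR

__all__ = [
    "DOPAMINE_FIRST_CHANNEL_MODELS",
    "CELLS_FIRST_CHANNEL_MODELS",
    "DOPAMINE_FIRST_GRAY",
    "CELLS_FIRST_GRAY",
    "SyntheticConfig",
    "generate_intensity_table",
    "generate_well_images",
]

#: reference (alpha, beta) per channel for the dopamine-first workflow
#: (dopamine added to media before plating the cells)
DOPAMINE_FIRST_CHANNEL_MODELS = {
    "r": (1.0, 0.0068),
    "g": (1.0, 0.009),
    "b": (1.0, 0.0083),
}

#: reference (alpha, beta) per channel for the cells-first workflow
CELLS_FIRST_CHANNEL_MODELS = {
    "r": (0.9899, 0.0084),
    "g": (0.9944, 0.0101),
    "b": (0.9934, 0.0107),
}

#: reference grayscale (alpha, beta) for the two workflows
DOPAMINE_FIRST_GRAY = (1.0, 0.0082)
CELLS_FIRST_GRAY = (0.9911, 0.0096)

#: truncation ceiling for generated normalized intensities
INTENSITY_CEIL = 1.5


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults reproduce the assay's design.

    Concentrations, trial count and ROI count match the calibration
    experiment (3 trials x 6 concentrations x 3 regions per well).
    ``noise_sd`` is additive Gaussian noise on the normalized-intensity
    scale; ``trial_effect_sd`` jitters a per-trial multiplicative gain.
    ``base_levels`` are the raw control brightnesses (fraction of full
    scale) used only when rendering images, so that 8-bit pixels do not
    saturate and control-normalisation recovers the configured models.
    """

    concentrations: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0, 100.0, 125.0)
    n_trials: int = 3
    rois_per_well: int = 3
    channel_models: dict = field(
        default_factory=lambda: dict(DOPAMINE_FIRST_CHANNEL_MODELS)
    )
    gray_model: tuple[float, float] = DOPAMINE_FIRST_GRAY
    noise_sd: float = 0.01
    trial_effect_sd: float = 0.02
    speckle_density: float = 2e-5  # dark particles per pixel per uM
    pixel_noise_sd: float = 0.02  # per-pixel texture when rendering images
    image_height: int = 96
    image_width: int = 96
    base_levels: tuple[float, float, float] = (0.82, 0.80, 0.76)
    seed: int = 0

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c < 0) or np.unique(c).size != c.size:
            raise ValueError("concentrations must be distinct and non-negative")
        if self.noise_sd < 0 or self.trial_effect_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.n_trials < 1 or self.rois_per_well < 1:
            raise ValueError("need at least one trial and one ROI per well")

    def true_means(self, concentration: float) -> dict[str, float]:
        """Noiseless normalized channel means at one concentration."""
        out = {
            ch: a * np.exp(-b * concentration)
            for ch, (a, b) in self.channel_models.items()
        }
        ga, gb = self.gray_model
        out["gray"] = ga * np.exp(-gb * concentration)
        return out


def _trial_gain(config: SyntheticConfig, trial: int) -> float:
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(trial,))
    )
    return float(1.0 + config.trial_effect_sd * rng.standard_normal())


def _well_rng(config: SyntheticConfig, trial: int, well: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(trial, 1 + well))
    )


def generate_intensity_table(
    config: SyntheticConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-ROI intensity samples from the configured decay models.

    Returns ``(samples, ground_truth)``: a tidy table with one row per
    (trial, concentration, ROI) holding noisy normalized channel means
    truncated to (EPS_FLOOR, 1.5], and a ground-truth manifest with the
    noiseless means and trial gains.  Identical config (including seed)
    yields identical output.
    """
    config = config or SyntheticConfig()
    rows, truth = [], []
    for trial in range(config.n_trials):
        gain = _trial_gain(config, trial)
        for well, conc in enumerate(config.concentrations):
            rng = _well_rng(config, trial, well)
            means = config.true_means(conc)
            truth.append({
                "trial": trial, "concentration_uM": conc,
                **{f"true_{ch}": gain * m for ch, m in means.items()},
                "trial_gain": gain, "seed": config.seed,
            })
            for roi in range(config.rois_per_well):
                noise = rng.normal(0.0, config.noise_sd, size=4) \
                    if config.noise_sd > 0 else np.zeros(4)
                vals = {
                    ch: float(np.clip(gain * means[ch] + noise[k],
                                      EPS_FLOOR, INTENSITY_CEIL))
                    for k, ch in enumerate(("r", "g", "b", "gray"))
                }
                rows.append({
                    "trial": trial, "condition": f"{conc:g} uM",
                    "concentration_uM": conc, "roi": roi, **vals,
                })
    samples = pd.DataFrame(rows)
    ground_truth = pd.DataFrame(truth)
    return samples, ground_truth


def _render_well(
    config: SyntheticConfig, rng: np.random.Generator,
    raw_means: Sequence[float], concentration: float,
) -> np.ndarray:
    """One 8-bit RGB well image: flat background, pixel noise, dark speckles."""
    h, w = config.image_height, config.image_width
    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(raw_means)
    if config.pixel_noise_sd > 0:
        img += rng.normal(0.0, config.pixel_noise_sd, size=img.shape)
    n_speckles = int(round(config.speckle_density * h * w * concentration))
    if n_speckles:
        radius = max(2, h // 48)
        ctr_r = rng.integers(radius, h - radius, size=n_speckles)
        ctr_c = rng.integers(radius, w - radius, size=n_speckles)
        yy, xx = np.ogrid[:h, :w]
        for r0, c0 in zip(ctr_r, ctr_c):
            mask = (yy - r0) ** 2 + (xx - c0) ** 2 <= radius**2
            img[mask] *= 0.25  # colloidal PDA particles are nearly opaque
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


def generate_well_images(
    config: SyntheticConfig | None = None, out_dir: Path | str = "synthetic_wells",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render one PNG well image per (trial, concentration) plus manifest.

    Images are written under ``out_dir/images``; the returned manifest
    (also written as ``manifest.csv``) has the columns the extraction
    pipeline consumes, and the ground-truth manifest records the noiseless
    normalized means (speckles excluded — they are cosmetic texture that
    ROI averaging must tolerate).
    """
    config = config or SyntheticConfig()
    h, w = config.image_height, config.image_width
    min_side = int(np.ceil(np.sqrt(0.10 * h * w)))
    if min_side * config.rois_per_well > min(h, w):
        raise ValueError(
            f"image geometry {h}x{w} too small to place {config.rois_per_well} "
            "non-overlapping ROIs of the default layout"
        )
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    base = np.asarray(config.base_levels, dtype=float)
    manifest_rows, truth = [], []
    for trial in range(config.n_trials):
        gain = _trial_gain(config, trial)
        for well, conc in enumerate(config.concentrations):
            rng = _well_rng(config, trial, well)
            means = config.true_means(conc)
            normed = np.array([gain * means[ch] for ch in ("r", "g", "b")])
            if config.noise_sd > 0:
                normed = normed + rng.normal(0.0, config.noise_sd, size=3)
            raw = np.clip(base * normed, 0.0, 1.0)
            name = f"trial{trial}_c{conc:g}.png"
            iio.imwrite(img_dir / name, _render_well(config, rng, raw, conc))
            manifest_rows.append({
                "image_path": f"images/{name}", "trial": trial,
                "condition": f"{conc:g} uM", "concentration_uM": conc,
            })
            truth.append({
                "trial": trial, "concentration_uM": conc,
                **{f"true_{ch}": gain * m for ch, m in means.items()},
                "trial_gain": gain, "seed": config.seed,
            })
    manifest = pd.DataFrame(manifest_rows)
    ground_truth = pd.DataFrame(truth)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest, ground_truth
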