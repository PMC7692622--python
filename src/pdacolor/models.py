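"""Model / Results interface over the calibration mathematics.

Two model families, mirroring the two ways the assay is read out:

``RGBCalibrationModel``
    The pooled multivariate log-linear calibration C = A . ln(I) fitted
    across replicate trials; its Results object estimates concentrations
    for new RGB readings.

``ExponentialDecayModel``
    The per-channel (or grayscale) exponential response
    I(C) = alpha * exp(-beta C); its Results object predicts intensities
    on a concentration grid and inverts grayscale readings back to
    concentration.

Both results objects serialise to the JSON calibration-artifact schema and
print text summaries; fitted decay results can also plot predicted-vs-
observed curves (matplotlib, imported lazily).
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    CHANNELS,
    GrayDecayModel,
    RGBCalibration,
    estimate_concentration,
    fit_channel_decay,
    fit_gray_decay,
    fit_rgb_calibration,
    goodness_of_fit,
    invert_gray,
    log_intensity_matrix,
    predict_channel_intensity,
)

__all__ = [
    "RGBCalibrationModel",
    "RGBCalibrationResults",
    "ExponentialDecayModel",
    "ExponentialDecayResults",
    "load_results",
]


def _trial_tables_from_dataframe(
    data: pd.DataFrame, channels: Sequence[str] = CHANNELS
) -> tuple[np.ndarray, list[np.ndarray], list]:
    """Aggregate a tidy samples table into per-trial condition x channel tables.

    Expects columns ``trial``, ``concentration_uM`` and the channel means;
    replicate rows (e.g. multiple ROIs per well) are averaged.
    """
    required = {"trial", "concentration_uM", *channels}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"samples table is missing columns: {sorted(missing)}")
    known = data.dropna(subset=["concentration_uM"])
    grouped = (
        known.groupby(["trial", "concentration_uM"], sort=True)[list(channels)]
        .mean()
        .reset_index()
    )
    concentrations = np.sort(grouped["concentration_uM"].unique())
    tables, trial_ids = [], []
    for trial, sub in grouped.groupby("trial", sort=True):
        sub = sub.set_index("concentration_uM").reindex(concentrations)
        if sub[list(channels)].isna().any().any():
            raise ValueError(f"trial {trial!r} is missing some concentration conditions")
        tables.append(sub[list(channels)].to_numpy())
        trial_ids.append(trial)
    return concentrations, tables, trial_ids


class RGBCalibrationModel:
    """Pooled intercept-free RGB calibration across replicate trials.

    Parameters
    ----------
    concentrations : array-like
        The n known dopamine concentrations (uM), in table row order.
    trial_tables : sequence of (n, 3) arrays
        One normalized intensity table per trial; rows follow
        ``concentrations``, columns are mean r, g, b.
    trial_ids : optional labels for the trials.
    """

    def __init__(self, concentrations, trial_tables, trial_ids=None):
        self.concentrations = np.asarray(concentrations, dtype=float)
        self.trial_tables = [np.asarray(t, dtype=float) for t in trial_tables]
        self.trial_ids = list(trial_ids) if trial_ids is not None else list(
            range(len(self.trial_tables))
        )
        self.nobs = self.concentrations.size * len(self.trial_tables)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "RGBCalibrationModel":
        """Build from a tidy samples table (trial, concentration_uM, r, g, b)."""
        concentrations, tables, ids = _trial_tables_from_dataframe(data)
        return cls(concentrations, tables, trial_ids=ids)

    def fit(self) -> "RGBCalibrationResults":
        trials = [
            log_intensity_matrix(t, trial_index=i)
            for i, t in enumerate(self.trial_tables)
        ]
        cal = fit_rgb_calibration(self.concentrations, trials)
        return RGBCalibrationResults(self, cal)


class RGBCalibrationResults:
    """Fitted pooled RGB calibration with per-trial diagnostics."""

    kind = "rgb"

    def __init__(self, model: RGBCalibrationModel, calibration: RGBCalibration):
        self.model = model
        self.calibration = calibration
        self.params = pd.Series(
            calibration.coefficients, index=["a_r", "a_g", "a_b"], name="coefficient"
        )
        self.per_trial_r2 = pd.Series(
            calibration.per_trial_r2,
            index=[f"trial {t}" for t in model.trial_ids],
            name="R2",
        )

    def predict(self, intensities) -> np.ndarray:
        """Estimated concentration(s) for RGB triples (single or stacked)."""
        I = np.atleast_2d(np.asarray(intensities, dtype=float))
        return np.array(
            [estimate_concentration(self.calibration, row) for row in I]
        )

    def summary(self) -> str:
        lines = [
            "Pooled RGB calibration (intercept-free log-linear model)",
            f"  trials: {self.calibration.n_trials}   "
            f"conditions per trial: {self.model.concentrations.size}",
            "  coefficients (uM per log-intensity unit):",
        ]
        for name, val in self.params.items():
            lines.append(f"    {name:>4s} = {val:12.4f}")
        lines.append("  per-trial R^2 of estimated vs known concentration:")
        for name, val in self.per_trial_r2.items():
            lines.append(f"    {name}: {val:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "fit": {
                "n_conditions": int(self.model.concentrations.size),
                "n_trials": int(self.calibration.n_trials),
                "per_trial_r2": [float(v) for v in self.calibration.per_trial_r2],
            },
            "normalization": "control",
            "software_version": __version__,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


class ExponentialDecayModel:
    """Exponential intensity-vs-concentration response for one channel.

    ``channel`` is one of r, g, b or "gray"; the response vector holds the
    trial-aggregated normalized intensities at each concentration.
    """

    def __init__(self, concentrations, response, channel: str = "gray"):
        self.concentrations = np.asarray(concentrations, dtype=float)
        self.response = np.asarray(response, dtype=float)
        self.channel = channel
        self.nobs = self.concentrations.size

    def fit(
        self, fix_amplitude: bool = False, refine: bool = False
    ) -> "ExponentialDecayResults":
        if self.channel == "gray":
            decay = fit_gray_decay(
                self.concentrations, self.response,
                fix_amplitude=fix_amplitude, refine=refine,
            )
        else:
            decay = fit_channel_decay(
                self.concentrations, self.response,
                fix_amplitude=fix_amplitude, refine=refine, channel=self.channel,
            )
        return ExponentialDecayResults(self, decay)


class ExponentialDecayResults:
    """Fitted exponential decay with prediction, inversion and plotting."""

    def __init__(self, model: ExponentialDecayModel, decay):
        self.model = model
        self.decay = decay
        self.channel = model.channel
        self.params = pd.Series(
            [decay.alpha, decay.beta], index=["alpha", "beta"], name="coefficient"
        )
        self.rsquared = goodness_of_fit(
            model.response, self.predict(model.concentrations)
        )

    @property
    def kind(self) -> str:
        return "gray_exp" if self.channel == "gray" else "channel_exp"

    def predict(self, concentrations):
        """Predicted normalized intensity at the given concentration(s)."""
        return predict_channel_intensity(self.decay, concentrations)

    def invert(self, intensity: float) -> float:
        """Estimated concentration for an observed normalized intensity."""
        gray = self.decay if isinstance(self.decay, GrayDecayModel) else GrayDecayModel(
            alpha=self.decay.alpha, beta=self.decay.beta
        )
        return invert_gray(gray, intensity)

    def summary(self) -> str:
        return "\n".join([
            f"Exponential decay fit, channel '{self.channel}'",
            f"  I(C) = alpha * exp(-beta C)",
            f"  alpha = {self.decay.alpha:.6g} (normalized intensity at C = 0)",
            f"  beta  = {self.decay.beta:.6g} per uM",
            f"  R^2   = {self.rsquared:.4f} over {self.model.nobs} conditions",
        ])

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "channel": self.channel,
            "coefficients": {"alpha": float(self.decay.alpha),
                             "beta": float(self.decay.beta)},
            "fit": {"n_conditions": int(self.model.nobs),
                    "r2": float(self.rsquared)},
            "normalization": "control",
            "software_version": __version__,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def plot(self, ax=None, grid_step: float = 5.0):
        """Predicted curve over a concentration grid plus observed points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.concentrations
        grid = np.arange(0.0, c.max() + grid_step / 2, grid_step)
        ax.plot(grid, self.predict(grid), "-", label="model")
        ax.plot(c, self.model.response, "o", label="observed")
        ax.set_xlabel("dopamine concentration (uM)")
        ax.set_ylabel("normalized intensity")
        ax.set_title(f"channel '{self.channel}'")
        ax.legend()
        return ax


def load_results(path) -> dict:
    """Load a calibration-artifact JSON.

    Accepts either a single-model artifact written by a Results ``save``
    (kind rgb | channel_exp | gray_exp) or the composite artifact the CLI
    ``calibrate`` command writes (with nested ``rgb`` / ``gray`` /
    ``channels`` entries).
    """
    with open(path) as fh:
        art = json.load(fh)
    single = art.get("kind") in {"rgb", "channel_exp", "gray_exp"}
    composite = any(k in art for k in ("rgb", "gray", "channels"))
    if not (single or composite):
        raise ValueError(f"unrecognised calibration artifact kind: {art.get('kind')!r}")
    return art
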