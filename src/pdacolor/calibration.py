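"""Core calibration mathematics for colorimetric dopamine quantification.

Polydopamine formed by self-oxidation of dopamine darkens culture media in
proportion to the dopamine concentration that started the polymerisation.
This module implements the regression machinery that turns that optical
signal into a concentration estimate:

* a pooled multivariate log-linear calibration mapping RGB intensities to
  concentration, fitted across replicate trials with a Moore-Penrose
  pseudo-inverse construction,
* per-channel and grayscale exponential decay models
  ``I = alpha * exp(-beta * C)`` with forward prediction and closed-form
  inversion,
* coefficient-of-determination diagnostics.

All intensities entering this module are expected to be normalized so that
the 0 uM (control) condition maps to ~1; the calibration model is
intercept-free, so the concentration estimate at control intensities is
identically zero.  Functions here raise on non-positive intensities rather
than clipping — clipping belongs to image-ingestion code, never to the math
core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DegenerateDesignError",
    "IntensityDomainError",
    "NegativeConcentrationWarning",
    "ConcentrationVector",
    "TrialLogIntensityMatrix",
    "RGBCalibration",
    "ChannelDecayModel",
    "GrayDecayModel",
    "PooledChannelResponse",
    "log_intensity_matrix",
    "fit_rgb_calibration",
    "estimate_concentration",
    "pooled_channel_response",
    "fit_channel_decay",
    "predict_channel_intensity",
    "fit_gray_decay",
    "invert_gray",
    "goodness_of_fit",
]

#: singular values below RANK_RTOL * s_max are treated as zero
RANK_RTOL = 1e-10

CHANNELS = ("r", "g", "b")


class IntensityDomainError(ValueError):
    """An intensity was outside the domain of the log-linear model (<= 0)."""


class DegenerateDesignError(ValueError):
    """The calibration design matrix is rank deficient (needs rank 3)."""


class NegativeConcentrationWarning(UserWarning):
    """A concentration estimate came out negative (intensity above control)."""


def _as_concentrations(values: Sequence[float], min_n: int = 3) -> np.ndarray:
    c = np.asarray(values, dtype=float)
    if c.ndim != 1 or c.size < min_n:
        raise ValueError(f"need at least {min_n} concentrations, got shape {c.shape}")
    if not np.all(np.isfinite(c)):
        raise ValueError("concentrations must be finite")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    if np.unique(c).size != c.size:
        raise ValueError("concentrations must be distinct")
    return c


@dataclass(frozen=True)
class ConcentrationVector:
    """Ordered vector of n known distinct dopamine concentrations in uM."""

    values: np.ndarray

    def __init__(self, values: Sequence[float], min_n: int = 3):
        object.__setattr__(self, "values", _as_concentrations(values, min_n=min_n))

    @property
    def n(self) -> int:
        return self.values.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass(frozen=True)
class TrialLogIntensityMatrix:
    """3 x n matrix of natural-log channel intensities for one trial.

    Rows are the r, g, b channels; columns follow the concentration order of
    the associated :class:`ConcentrationVector`.
    """

    entries: np.ndarray
    trial_index: int = 0

    def __post_init__(self):
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2 or e.shape[0] != 3:
            raise ValueError(f"log-intensity matrix must be 3 x n, got {e.shape}")
        if not np.all(np.isfinite(e)):
            raise ValueError("log-intensity entries must be finite")
        object.__setattr__(self, "entries", e)

    @property
    def n(self) -> int:
        return self.entries.shape[1]


@dataclass(frozen=True)
class RGBCalibration:
    """Fitted intercept-free RGB calibration ``Chat = a . ln(I)``.

    Coefficients are in uM per log-intensity unit.  ``per_trial_r2`` holds
    the coefficient of determination of estimated vs known concentrations
    for each trial used in the fit.
    """

    a_r: float
    a_g: float
    a_b: float
    n_trials: int
    per_trial_r2: tuple[float, ...] = ()

    def __post_init__(self):
        coefs = (self.a_r, self.a_g, self.a_b)
        if not all(np.isfinite(coefs)):
            raise ValueError("calibration coefficients must be finite")
        if any(r2 > 1 + 1e-12 for r2 in self.per_trial_r2):
            raise ValueError("R^2 cannot exceed 1")

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a_r, self.a_g, self.a_b])


@dataclass(frozen=True)
class ChannelDecayModel:
    """Exponential decay of one channel's normalized intensity with C.

    ``I_j(C) = alpha_j * exp(-beta_j * C)`` with alpha dimensionless
    (normalized intensity at C = 0) and beta in 1/uM.
    """

    channel: str
    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclass(frozen=True)
class GrayDecayModel:
    """Exponential decay of grayscale intensity: ``I = alpha * exp(-beta C)``."""

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclass(frozen=True)
class PooledChannelResponse:
    """Per-concentration, trial-aggregated normalized intensity of a channel."""

    channel: str
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("response must be one-dimensional")
        if np.any(v <= 0):
            raise ValueError("pooled response values must be positive")
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------------------
# log-intensity matrices


def log_intensity_matrix(table, trial_index: int = 0) -> TrialLogIntensityMatrix:
    """Natural-log matrix of one trial's normalized channel intensities.

    Parameters
    ----------
    table : array-like, shape (n, 3)
        Rows are the n concentration conditions (in calibration order),
        columns the mean r, g, b intensities, all strictly positive.
    trial_index : int
        Identifier of the trial, carried into the result.

    Returns
    -------
    TrialLogIntensityMatrix
        The 3 x n matrix with entry (j, k) = ln(intensity of channel j at
        condition k) — i.e. the table transposed and logged.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[1] != 3:
        raise ValueError(f"intensity table must be n x 3, got shape {t.shape}")
    bad = np.argwhere(~(t > 0))
    if bad.size:
        k, j = bad[0]
        raise IntensityDomainError(
            f"non-positive intensity for channel '{CHANNELS[j]}' at condition {k} "
            f"(value {t[k, j]!r}); log-linear model requires intensities > 0"
        )
    return TrialLogIntensityMatrix(entries=np.log(t).T, trial_index=trial_index)


def _coerce_trials(trials: Iterable) -> list[TrialLogIntensityMatrix]:
    out = []
    for i, t in enumerate(trials):
        if isinstance(t, TrialLogIntensityMatrix):
            out.append(t)
        else:
            out.append(TrialLogIntensityMatrix(entries=np.asarray(t, float), trial_index=i))
    if not out:
        raise ValueError("need at least one trial")
    n = out[0].n
    if any(t.n != n for t in out):
        raise ValueError("all trials must share the same number of conditions")
    return out


# ---------------------------------------------------------------------------
# pooled RGB calibration


def fit_rgb_calibration(C, trials: Iterable) -> RGBCalibration:
    """Fit the pooled RGB calibration across replicate trials.

    Minimises the summed squared error ``sum_i || C - A . Ibar_i ||^2``
    over the row vector of coefficients ``A = (a_r, a_g, a_b)``, where
    ``Ibar_i`` is trial i's 3 x n log-intensity matrix.  The solution is
    computed through the pseudo-inverse construction

        f(I) = (sum_i Ibar_i Ibar_i^T) (sum_i Ibar_i^T)^+ ,
        A    = C f(I)^+ ,

    which under the rank-3 precondition coincides with the pooled
    normal-equations solution ``A = C (sum_i Ibar_i^T)(sum_i Ibar_i Ibar_i^T)^-1``.

    Raises
    ------
    DegenerateDesignError
        If the stacked design has rank < 3 (e.g. a channel constant across
        all conditions in every trial).
    """
    if isinstance(C, ConcentrationVector):
        c = C.values
    else:
        c = _as_concentrations(C)
    trial_list = _coerce_trials(trials)
    if trial_list[0].n != c.size:
        raise ValueError(
            f"trials have {trial_list[0].n} conditions but {c.size} concentrations given"
        )

    stacked = np.hstack([t.entries for t in trial_list])  # 3 x (k*n)
    svals = np.linalg.svd(stacked, compute_uv=False)
    if svals[0] == 0 or np.sum(svals > RANK_RTOL * svals[0]) < 3:
        raise DegenerateDesignError(
            "stacked log-intensity design has rank < 3; the three channels must "
            "vary independently across conditions (singular values: "
            f"{svals.tolist()})"
        )

    M = sum(t.entries @ t.entries.T for t in trial_list)  # 3 x 3
    S = sum(t.entries.T for t in trial_list)  # n x 3
    f_of_I = M @ np.linalg.pinv(S, rcond=RANK_RTOL)  # 3 x n
    A = c[None, :] @ np.linalg.pinv(f_of_I, rcond=RANK_RTOL)  # 1 x 3
    a_r, a_g, a_b = A.ravel()

    r2 = tuple(
        goodness_of_fit(c, (A @ t.entries).ravel()) for t in trial_list
    )
    return RGBCalibration(
        a_r=float(a_r), a_g=float(a_g), a_b=float(a_b),
        n_trials=len(trial_list), per_trial_r2=r2,
    )


def estimate_concentration(cal: RGBCalibration, I_rgb) -> float:
    """Estimated dopamine concentration (uM) for one RGB intensity triple.

    ``Chat = a_r ln(I_r) + a_g ln(I_g) + a_b ln(I_b)``.  The model has no
    intercept, so Chat is exactly zero at control intensities (1, 1, 1).
    Negative estimates (intensities brighter than control) are returned
    unmodified with a :class:`NegativeConcentrationWarning`.
    """
    I = np.asarray(I_rgb, dtype=float)
    if I.shape != (3,):
        raise ValueError(f"expected an (I_r, I_g, I_b) triple, got shape {I.shape}")
    bad = np.argwhere(~(I > 0))
    if bad.size:
        j = int(bad[0][0])
        raise IntensityDomainError(
            f"non-positive intensity for channel '{CHANNELS[j]}' (value {I[j]!r})"
        )
    chat = float(cal.coefficients @ np.log(I))
    if chat < 0:
        warnings.warn(
            f"negative concentration estimate {chat:.4g} uM (intensity above "
            "control); returned unclipped", NegativeConcentrationWarning,
            stacklevel=2,
        )
    return chat


# ---------------------------------------------------------------------------
# pooled per-channel response and exponential decay models


def pooled_channel_response(
    trials: Sequence, channel: str, mode: str = "control-mean",
    control_index: int = 0,
) -> PooledChannelResponse:
    """Aggregate one channel's intensities across trials, per concentration.

    Parameters
    ----------
    trials : sequence of array-like, each shape (n, 3)
        Per-trial normalized intensity tables (rows = conditions in
        calibration order, columns = r, g, b).
    channel : {"r", "g", "b"}
    mode : {"control-mean", "mean", "sum"}
        "sum" is the literal summation over trials; "mean" averages; the
        default "control-mean" averages and then rescales by the control
        condition so C = 0 maps to ~1, matching the normalized-amplitude
        convention of the decay models.
    control_index : int
        Row index of the 0 uM condition, used only by "control-mean".
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    j = CHANNELS.index(channel)
    arrs = [np.asarray(t, dtype=float) for t in trials]
    n = arrs[0].shape[0]
    if any(a.shape != (n, 3) for a in arrs):
        raise ValueError("all trials must be n x 3 with a common n")
    stack = np.stack([a[:, j] for a in arrs])  # k x n
    if mode == "sum":
        vals = stack.sum(axis=0)
    elif mode == "mean":
        vals = stack.mean(axis=0)
    elif mode == "control-mean":
        vals = stack.mean(axis=0)
        ref = vals[control_index]
        if ref <= 0:
            raise ValueError("control-condition response must be positive")
        vals = vals / ref
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return PooledChannelResponse(channel=channel, values=vals)


def _fit_exponential(
    c: np.ndarray, y: np.ndarray, fix_amplitude: bool, refine: bool
) -> tuple[float, float]:
    """Least-squares (alpha, beta) for y = alpha * exp(-beta c).

    Default is the log-linear closed form (exact on noiseless model data);
    ``refine=True`` polishes with nonlinear least squares on the original
    scale, seeded at the log-linear solution.
    """
    if np.any(y <= 0):
        raise IntensityDomainError("response values must be positive")
    if np.ptp(c) == 0:
        raise ValueError("zero concentration spread; cannot identify beta")
    ln_y = np.log(y)
    if fix_amplitude:
        alpha = 1.0
        beta = -float(c @ ln_y) / float(c @ c)
    else:
        slope, intercept = np.polyfit(c, ln_y, 1)
        alpha = float(np.exp(intercept))
        beta = -float(slope)
    if refine:
        from scipy.optimize import curve_fit

        if fix_amplitude:
            popt, _ = curve_fit(lambda x, b: np.exp(-b * x), c, y, p0=[beta])
            beta = float(popt[0])
        else:
            popt, _ = curve_fit(
                lambda x, a, b: a * np.exp(-b * x), c, y, p0=[alpha, beta]
            )
            alpha, beta = float(popt[0]), float(popt[1])
    return alpha, beta


def _check_decay_inputs(C, resp, fix_amplitude: bool) -> tuple[np.ndarray, np.ndarray]:
    c = C.values if isinstance(C, ConcentrationVector) else _as_concentrations(C, min_n=2)
    y = resp.values if isinstance(resp, PooledChannelResponse) else np.asarray(resp, float)
    if y.shape != c.shape:
        raise ValueError(f"response shape {y.shape} does not match {c.shape}")
    min_n = 2 if fix_amplitude else 3
    if c.size < min_n:
        raise ValueError(f"need at least {min_n} conditions for this fit")
    return c, y


def fit_channel_decay(
    C, resp, fix_amplitude: bool = False, refine: bool = False,
    channel: str | None = None,
) -> ChannelDecayModel:
    """Fit ``I_j(C) = alpha_j exp(-beta_j C)`` to one channel's pooled response.

    With ``fix_amplitude`` the amplitude is pinned at 1 (the normalized
    control intensity) and only beta is estimated.
    """
    ch = channel or (resp.channel if isinstance(resp, PooledChannelResponse) else "r")
    c, y = _check_decay_inputs(C, resp, fix_amplitude)
    alpha, beta = _fit_exponential(c, y, fix_amplitude, refine)
    return ChannelDecayModel(channel=ch, alpha=alpha, beta=beta)


def predict_channel_intensity(model, C):
    """Forward model: normalized intensity ``alpha * exp(-beta C)``.

    Strictly decreasing in C whenever beta > 0.  Accepts scalars or arrays.
    """
    c = np.asarray(C, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("concentration must be finite")
    out = model.alpha * np.exp(-model.beta * c)
    return float(out) if np.isscalar(C) or c.ndim == 0 else out


def fit_gray_decay(
    C, gray_resp, fix_amplitude: bool = False, refine: bool = False
) -> GrayDecayModel:
    """Fit the grayscale decay law ``I_gray(C) = alpha exp(-beta C)``."""
    c, y = _check_decay_inputs(C, gray_resp, fix_amplitude)
    alpha, beta = _fit_exponential(c, y, fix_amplitude, refine)
    return GrayDecayModel(alpha=alpha, beta=beta)


def invert_gray(model: GrayDecayModel, I_gray: float) -> float:
    """Closed-form inversion ``Chat = ln(alpha / I_gray) / beta`` in uM.

    Intensities brighter than the amplitude produce a negative estimate,
    which is returned with a :class:`NegativeConcentrationWarning`.
    """
    if model.beta == 0:
        raise ValueError("beta = 0: flat decay model is not invertible")
    I = float(I_gray)
    if I <= 0:
        raise IntensityDomainError(f"grayscale intensity must be positive, got {I!r}")
    chat = float(np.log(model.alpha / I) / model.beta)
    if chat < 0:
        warnings.warn(
            f"negative concentration estimate {chat:.4g} uM (intensity above "
            "the fitted amplitude)", NegativeConcentrationWarning, stacklevel=2,
        )
    return chat


# ---------------------------------------------------------------------------
# goodness of fit


def goodness_of_fit(observed, predicted) -> float:
    """Coefficient of determination R^2 = 1 - SS_res / SS_tot."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1 or o.size < 2:
        raise ValueError("observed and predicted must be equal-length vectors (>= 2)")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: observed values are constant")
    ss_res = float(np.sum((o - p) ** 2))
    return 1.0 - ss_res / ss_tot
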