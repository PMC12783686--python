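"""FRAP recovery analysis of membrane clusters.

Extracts cluster/reference/background ROI traces from time-lapse stacks
(maximum-intensity z-projection per frame), applies double normalisation
(background-subtracted intensities anchored so the pre-bleach mean maps to
1 and the immediate post-bleach value to 0), and fits the
single-exponential recovery model

    Y(t) = Y(0) + (F_mob - Y(0)) * (1 - exp(-t ln2 / tau_half))

to obtain the mobile fraction ``F_mob`` and recovery half-time
``tau_half``.  The recovered plateau can be compared to a distal
reference region of the junction to judge whether a cluster recovers to
the surrounding membrane level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "FrapTrace",
    "FrapFit",
    "extract_frap_trace",
    "normalize_frap",
    "fit_recovery",
    "compare_to_reference",
    "recovery_model",
]


def recovery_model(t: np.ndarray, y0: float, f_mob: float, tau_half: float) -> np.ndarray:
    """Single-exponential FRAP recovery: Y0 + (F_mob - Y0)(1 - 2^(-t/tau_half))."""
    t = np.asarray(t, dtype=float)
    return y0 + (f_mob - y0) * (1.0 - np.exp(-t * np.log(2.0) / tau_half))


@dataclass(frozen=True)
class FrapTrace:
    """Raw ROI intensity traces of one FRAP experiment.

    ``bleach_frame`` is the index of the first frame acquired *after* the
    bleach event; frames before it are pre-bleach.  Times must be strictly
    increasing (default design: uniform 10-s sampling).
    """

    time_s: np.ndarray
    roi: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    bleach_frame: int

    def __post_init__(self) -> None:
        for name in ("time_s", "roi", "reference", "background"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time_s)
        if any(len(getattr(self, k)) != n for k in ("roi", "reference", "background")):
            raise ValueError("all trace columns must share length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (1 <= self.bleach_frame < n):
            raise ValueError("bleach frame must lie within the series, after frame 0")
        if self.bleach_frame < 2:
            warnings.warn("only one pre-bleach frame; pre-bleach mean is a single sample")

    @property
    def n_prebleach(self) -> int:
        return self.bleach_frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, bleach_frame: int | None = None) -> "FrapTrace":
        """Build from a DataFrame with time_s/roi/reference/background columns."""
        if bleach_frame is None:
            bleach_frame = int(frame.attrs.get("bleach_frame", -1))
            if bleach_frame < 0:
                raise ValueError("bleach_frame not given and absent from frame.attrs")
        return cls(
            frame["time_s"].to_numpy(),
            frame["roi"].to_numpy(),
            frame["reference"].to_numpy(),
            frame["background"].to_numpy(),
            bleach_frame,
        )


@dataclass(frozen=True)
class NormalizedFrapTrace:
    """Double-normalised FRAP trace: pre-bleach mean -> 1, first post-bleach -> 0."""

    time_s: np.ndarray
    normalized: np.ndarray
    reference_normalized: np.ndarray
    bleach_frame: int

    @property
    def post_times(self) -> np.ndarray:
        """Times of post-bleach frames, shifted so the first is t = 0."""
        t = self.time_s[self.bleach_frame :]
        return t - t[0]

    @property
    def post_values(self) -> np.ndarray:
        return self.normalized[self.bleach_frame :]


@dataclass(frozen=True)
class FrapFit:
    """Fitted recovery parameters with asymptotic standard errors."""

    y0: float
    f_mob: float
    tau_half_s: float
    y0_se: float
    f_mob_se: float
    tau_half_se: float
    n_traces: int
    mode: str
    tau_at_bound: bool = False

    def curve(self, t: np.ndarray) -> np.ndarray:
        return recovery_model(t, self.y0, self.f_mob, self.tau_half_s)


def extract_frap_trace(
    stack: np.ndarray,
    cluster_roi: tuple[int, int, int, int],
    reference_roi: tuple[int, int, int, int],
    background_roi: tuple[int, int, int, int],
    bleach_frame: int,
    interval_s: float = 10.0,
) -> FrapTrace:
    """Extract ROI mean traces from a time-lapse (T, Z, Y, X) or (T, Y, X) stack.

    Each frame is maximum-intensity projected along z before the ROI means
    are taken.  ROIs are half-open ``(row0, row1, col0, col1)`` rectangles
    in 0-based pixel coordinates, origin top-left.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 3:
        proj = stack
    elif stack.ndim == 4:
        proj = stack.max(axis=1)
    else:
        raise ValueError("stack must be (T, Y, X) or (T, Z, Y, X)")

    def roi_mean(roi):
        r0, r1, c0, c1 = roi
        patch = proj[:, r0:r1, c0:c1]
        if patch.shape[1] == 0 or patch.shape[2] == 0:
            raise ValueError(f"empty ROI {roi}")
        return patch.mean(axis=(1, 2))

    n = proj.shape[0]
    time = interval_s * np.arange(n) - interval_s * bleach_frame
    return FrapTrace(
        time,
        roi_mean(cluster_roi),
        roi_mean(reference_roi),
        roi_mean(background_roi),
        bleach_frame,
    )


def normalize_frap(trace: FrapTrace) -> NormalizedFrapTrace:
    """Double normalisation of a FRAP trace.

    With background-subtracted intensities I'(t), the pre-bleach mean
    I'_pre, and the immediate post-bleach value I'_post (the single first
    frame after the bleach), the normalised trace is

        N(t) = (I'(t) - I'_post) / (I'_pre - I'_post)

    so the pre-bleach plateau maps to 1 and the immediate post-bleach
    frame to 0.  The construction cancels any affine gain/offset of the
    acquisition.  The unbleached reference region is normalised on the
    *cluster's* pre-bleach scale, (I_ref(t) - bg) / I'_pre, so the
    recovered plateau and the junction level are directly comparable on
    one axis (a junction dimmer than the cluster plots below 1).
    """
    bg = float(trace.background.mean())
    b = trace.bleach_frame
    i_pre = float(trace.roi[:b].mean()) - bg
    i_post = float(trace.roi[b]) - bg
    if i_pre <= i_post:
        raise ValueError(
            "pre-bleach mean does not exceed the immediate post-bleach value; "
            "no bleach detected"
        )
    if i_pre <= 0:
        raise ValueError("non-positive pre-bleach cluster intensity")
    norm = (trace.roi - bg - i_post) / (i_pre - i_post)
    ref_norm = (trace.reference - bg) / i_pre
    return NormalizedFrapTrace(trace.time_s.copy(), norm, ref_norm, b)


def fit_recovery(
    traces: NormalizedFrapTrace | list[NormalizedFrapTrace],
    mode: str = "ensemble-mean",
) -> FrapFit:
    """Fit the single-exponential recovery model to normalised traces.

    ``mode='ensemble-mean'`` (default, matching the convention of fitting
    the average of replicate traces) averages the post-bleach traces
    pointwise before a single fit; ``mode='per-trace'`` fits the single
    trace given.  Bounds: Y0 in [-0.2, 0.5], F_mob in [0, 1.5], tau_half
    in (0, 10x total duration].  A half-time pinned at a bound is flagged
    unreliable.
    """
    if isinstance(traces, NormalizedFrapTrace):
        traces = [traces]
    if not traces:
        raise ValueError("need at least one trace")
    if mode not in ("ensemble-mean", "per-trace"):
        raise ValueError("mode must be 'ensemble-mean' or 'per-trace'")
    if mode == "per-trace" and len(traces) != 1:
        raise ValueError("per-trace mode fits exactly one trace; loop externally")

    t = traces[0].post_times
    if any(len(tr.post_times) != len(t) or not np.allclose(tr.post_times, t) for tr in traces[1:]):
        raise ValueError("ensemble traces must share post-bleach sampling")
    if len(t) < 5:
        raise ValueError("need >= 5 post-bleach samples")
    y = np.mean([tr.post_values for tr in traces], axis=0)

    duration = float(t[-1])
    tau_hi = duration * 10.0
    y0_init = float(np.clip(y[0], -0.2, 0.5))
    decile = max(1, len(y) // 10)
    f_mob_init = float(np.clip(y[-decile:].mean(), 0.0, 1.5))
    half = y0_init + 0.5 * (f_mob_init - y0_init)
    above = np.nonzero(y >= half)[0]
    tau_init = float(t[above[0]]) if len(above) and t[above[0]] > 0 else duration / 10.0
    tau_init = float(np.clip(tau_init, 1e-3, tau_hi))

    try:
        popt, pcov = optimize.curve_fit(
            recovery_model,
            t,
            y,
            p0=[y0_init, f_mob_init, tau_init],
            bounds=([-0.2, 0.0, 1e-6], [0.5, 1.5, tau_hi]),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"recovery fit did not converge: {exc}") from exc

    y0, f_mob, tau = popt
    ses = np.sqrt(np.diag(pcov))
    tau_at_bound = bool(np.isclose(tau, tau_hi, rtol=1e-3) or tau < 1e-5)
    if tau_at_bound:
        warnings.warn("tau_half hit a fit bound; estimate unreliable")
    return FrapFit(
        float(y0), float(f_mob), float(tau),
        float(ses[0]), float(ses[1]), float(ses[2]),
        n_traces=len(traces), mode=mode, tau_at_bound=tau_at_bound,
    )


def compare_to_reference(
    fit: FrapFit, reference_normalized: np.ndarray
) -> tuple[float, float]:
    """Ratio of the recovered plateau to the reference junction level.

    Returns ``(ratio, reference_level)`` where ``reference_level`` is the
    time-average of the normalised reference trace.  A ratio near 1 means
    the cluster recovers to the intensity of the surrounding junction.
    """
    ref = np.asarray(reference_normalized, dtype=float)
    level = float(ref.mean())
    if level == 0:
        raise ValueError("zero reference level; ratio undefined")
    return fit.f_mob / level, level
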