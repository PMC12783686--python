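"""Seeded synthetic data with recorded ground truth.

Three generators mirror the three experimental readouts the analysis
modules quantify:

* droplet fields — hard-edged disks of channel-specific interior level on
  a flat exterior, mixed across channels by a bleedthrough matrix, then
  corrupted with additive Gaussian noise (clipped at zero);
* junction line profiles — a positive baseline plus Gaussian clusters of
  250–600 nm FWHM, with a second channel carrying a (jittered) peak at
  each cluster whose co-occurrence flag is set;
* FRAP traces — pre-bleach plateau at 1, bleach drop to Y0, then
  single-exponential recovery Y(t) = Y0 + (F_mob - Y0) * (1 - 2^(-t/tau_half)),
  alongside a constant reference-region trace.

Every generator takes an explicit integer seed and returns its ground
truth, so each downstream estimator can be validated by parameter
recovery.  Identical seeds reproduce bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .dropletquant import MultiChannelField

__all__ = [
    "DropletTruth",
    "ProfileTruth",
    "FrapTruth",
    "ProfileRealization",
    "gen_droplet_field",
    "gen_junction_profile",
    "gen_frap_trace",
    "random_profile_truth",
    "FWHM_PER_SIGMA",
]

# For a Gaussian, full width at half maximum = 2*sqrt(2*ln 2) * sigma.
FWHM_PER_SIGMA: float = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class DropletTruth:
    """Generative parameters of a synthetic droplet field.

    ``centers`` are (row, col) pixel coordinates, ``radii`` pixel radii.
    ``interior_levels`` / ``exterior_levels`` give each channel's intensity
    inside/outside droplets (a.u.).  ``bleedthrough`` is a square matrix of
    source->target spillover fractions with unit diagonal; off-diagonal
    entries must lie in [0, 1).  ``edge_blur_sigma`` optionally softens the
    disk edges (real droplets are diffraction-blurred); the analytic
    two-level ground truth holds only at 0.
    """

    centers: np.ndarray
    radii: np.ndarray
    channel_names: tuple[str, ...]
    interior_levels: np.ndarray
    exterior_levels: np.ndarray
    bleedthrough: np.ndarray | None = None
    noise_sd: float = 0.0
    edge_blur_sigma: float = 0.0
    pixel_size_nm: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        interior = np.atleast_1d(np.asarray(self.interior_levels, dtype=float))
        exterior = np.atleast_1d(np.asarray(self.exterior_levels, dtype=float))
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "interior_levels", interior)
        object.__setattr__(self, "exterior_levels", exterior)

        n_ch = len(self.channel_names)
        if interior.shape != (n_ch,) or exterior.shape != (n_ch,):
            raise ValueError("interior/exterior levels must have one entry per channel")
        if len(radii) and centers.shape != (len(radii), 2):
            raise ValueError("centers must be (n, 2) matching radii")
        if np.any(radii <= 0):
            raise ValueError("radii must be positive")
        if np.any(exterior < 0):
            raise ValueError("exterior levels must be non-negative")
        if np.any(interior < exterior):
            raise ValueError("interior level must be >= exterior level per channel")
        bt = self.bleedthrough
        if bt is not None:
            bt = np.asarray(bt, dtype=float)
            object.__setattr__(self, "bleedthrough", bt)
            if bt.shape != (n_ch, n_ch):
                raise ValueError("bleedthrough matrix must be n_channels square")
            if not np.allclose(np.diag(bt), 1.0):
                raise ValueError("bleedthrough diagonal must be 1")
            off = bt[~np.eye(n_ch, dtype=bool)]
            if np.any(off < 0) or np.any(off >= 1):
                raise ValueError("off-diagonal bleedthrough must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def partition_ratios(self) -> np.ndarray:
        """True interior/exterior ratio per channel (NaN where exterior 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.interior_levels / self.exterior_levels


def gen_droplet_field(
    truth: DropletTruth, dims: tuple[int, int]
) -> tuple[MultiChannelField, DropletTruth]:
    """Render a multi-channel droplet field from its ground truth.

    Each channel starts at the exterior level, is overwritten by the
    interior level inside every droplet disk, mixed across channels by the
    bleedthrough matrix, optionally edge-blurred, and finally corrupted
    with additive Gaussian noise clipped at zero.  Droplets extending
    beyond ``dims`` are rejected.
    """
    rng = np.random.default_rng(truth.seed)
    nrow, ncol = dims
    for (r, c), rad in zip(truth.centers, truth.radii):
        if r - rad < 0 or r + rad > nrow - 1 or c - rad < 0 or c + rad > ncol - 1:
            raise ValueError(
                f"droplet at ({r:.1f}, {c:.1f}) radius {rad:.1f} px "
                f"extends outside the {nrow}x{ncol} field"
            )

    rows, cols = np.mgrid[0:nrow, 0:ncol]
    inside = np.zeros(dims, dtype=bool)
    for (r, c), rad in zip(truth.centers, truth.radii):
        inside |= (rows - r) ** 2 + (cols - c) ** 2 <= rad**2

    clean = np.empty((len(truth.channel_names),) + dims)
    for i, _ in enumerate(truth.channel_names):
        img = np.full(dims, truth.exterior_levels[i])
        img[inside] = truth.interior_levels[i]
        clean[i] = img

    if truth.bleedthrough is not None:
        # mixed_target = sum_source B[source, target] * clean_source
        clean = np.tensordot(truth.bleedthrough.T, clean, axes=1)

    if truth.edge_blur_sigma > 0:
        for i in range(len(clean)):
            clean[i] = gaussian_filter(clean[i], truth.edge_blur_sigma)

    if truth.noise_sd > 0:
        clean = clean + rng.normal(0.0, truth.noise_sd, clean.shape)
        clean = np.clip(clean, 0.0, None)

    channels = {name: clean[i] for i, name in enumerate(truth.channel_names)}
    return MultiChannelField(channels, truth.pixel_size_nm), truth


@dataclass(frozen=True)
class ProfileTruth:
    """Generative parameters of a paired two-channel junction line profile.

    ``cluster_fwhms_nm`` are analytic full widths at half maximum of the
    Gaussian clusters; the rendered sigma is ``fwhm / (2 sqrt(2 ln 2))``
    converted to pixels via ``pixel_size_nm``.  ``co_occurring`` marks the
    clusters that also carry a (jittered) peak in the second channel.
    """

    length_px: int = 100
    pixel_size_nm: float = 100.0
    cluster_centers_px: np.ndarray = dc_field(default_factory=lambda: np.array([]))
    cluster_fwhms_nm: np.ndarray = dc_field(default_factory=lambda: np.array([]))
    cluster_amplitudes: np.ndarray = dc_field(default_factory=lambda: np.array([]))
    baseline: float = 100.0
    co_occurring: np.ndarray = dc_field(default_factory=lambda: np.array([], dtype=bool))
    jitter_sd_px: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cluster_centers_px", "cluster_fwhms_nm", "cluster_amplitudes"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        object.__setattr__(
            self, "co_occurring", np.atleast_1d(np.asarray(self.co_occurring, dtype=bool))
        )
        k = len(self.cluster_centers_px)
        if len(self.cluster_fwhms_nm) != k or len(self.cluster_amplitudes) != k:
            raise ValueError("cluster centers, FWHMs and amplitudes must align")
        if len(self.co_occurring) != k:
            if len(self.co_occurring) == 0:
                object.__setattr__(self, "co_occurring", np.zeros(k, dtype=bool))
            else:
                raise ValueError("co_occurring flags must align with clusters")
        if k and (np.any(self.cluster_centers_px < 0) or np.any(self.cluster_centers_px > self.length_px - 1)):
            raise ValueError("cluster centers must lie within the profile")
        if np.any(self.cluster_fwhms_nm <= 0) or np.any(self.cluster_amplitudes <= 0):
            raise ValueError("cluster FWHMs and amplitudes must be positive")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")

    @property
    def sigmas_px(self) -> np.ndarray:
        return self.cluster_fwhms_nm / FWHM_PER_SIGMA / self.pixel_size_nm


def _gaussian_sum(x: np.ndarray, centers, sigmas, amplitudes) -> np.ndarray:
    y = np.zeros_like(x, dtype=float)
    for c, s, a in zip(centers, sigmas, amplitudes):
        y += a * np.exp(-((x - c) ** 2) / (2.0 * s**2))
    return y


@dataclass(frozen=True)
class ProfileRealization:
    """A rendered two-channel profile plus its generative truth.

    ``channel2_centers_px`` records the jittered positions of the
    channel-2 peaks actually rendered for the co-occurring clusters.
    """

    positions_px: np.ndarray
    channel1: np.ndarray
    channel2: np.ndarray
    channel2_centers_px: np.ndarray
    truth: ProfileTruth


def gen_junction_profile(truth: ProfileTruth) -> ProfileRealization:
    """Render paired raw line profiles from ground truth.

    Channel 1 carries every cluster; channel 2 carries a jittered Gaussian
    only at clusters whose co-occurrence flag is set.  Profiles shorter
    than 40 samples are rejected because baseline normalisation needs the
    20th–40th lowest intensity ranks.
    """
    if truth.length_px < 40:
        raise ValueError(
            "profile length must be >= 40 samples: baseline normalisation "
            "uses the 20th-40th lowest intensity values"
        )
    rng = np.random.default_rng(truth.seed)
    x = np.arange(truth.length_px, dtype=float)
    sigmas = truth.sigmas_px

    ch1 = truth.baseline + _gaussian_sum(
        x, truth.cluster_centers_px, sigmas, truth.cluster_amplitudes
    )

    co = truth.co_occurring
    jitter = rng.normal(0.0, truth.jitter_sd_px, size=co.sum()) if truth.jitter_sd_px > 0 else np.zeros(co.sum())
    ch2_centers = truth.cluster_centers_px[co] + jitter
    ch2 = truth.baseline + _gaussian_sum(
        x, ch2_centers, sigmas[co], truth.cluster_amplitudes[co]
    )

    if truth.noise_sd > 0:
        ch1 = np.clip(ch1 + rng.normal(0.0, truth.noise_sd, ch1.shape), 0.0, None)
        ch2 = np.clip(ch2 + rng.normal(0.0, truth.noise_sd, ch2.shape), 0.0, None)

    return ProfileRealization(x, ch1, ch2, ch2_centers, truth)


def random_profile_truth(
    seed: int,
    n_clusters: int = 5,
    co_occurrence_p: float = 1.0,
    length_px: int = 200,
    pixel_size_nm: float = 100.0,
    fwhm_range_nm: tuple[float, float] = (250.0, 600.0),
    amplitude_range: tuple[float, float] = (100.0, 300.0),
    baseline: float = 100.0,
    jitter_sd_px: float = 1.0,
    noise_sd: float = 0.0,
    min_separation_px: int = 20,
) -> ProfileTruth:
    """Draw a random ProfileTruth with well-separated clusters.

    Cluster FWHMs are uniform over the cortical-cluster size range
    (250–600 nm by default) and each cluster co-occurs in the second
    channel with probability ``co_occurrence_p``.
    """
    rng = np.random.default_rng(seed)
    margin = min_separation_px
    grid = np.arange(margin, length_px - margin, min_separation_px, dtype=float)
    if len(grid) < n_clusters:
        raise ValueError("profile too short for that many separated clusters")
    centers = np.sort(rng.choice(grid, size=n_clusters, replace=False))
    return ProfileTruth(
        length_px=length_px,
        pixel_size_nm=pixel_size_nm,
        cluster_centers_px=centers,
        cluster_fwhms_nm=rng.uniform(*fwhm_range_nm, n_clusters),
        cluster_amplitudes=rng.uniform(*amplitude_range, n_clusters),
        baseline=baseline,
        co_occurring=rng.random(n_clusters) < co_occurrence_p,
        jitter_sd_px=jitter_sd_px,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


@dataclass(frozen=True)
class FrapTruth:
    """Generative parameters of a FRAP recovery trace (normalised units).

    ``y0`` is the normalised intensity at the bleach, ``f_mob`` the mobile
    fraction (recovery plateau), ``tau_half_s`` the half-time of recovery.
    The model is ``Y(t) = Y0 + (F_mob - Y0) * (1 - exp(-t ln2 / tau_half))``
    for t >= 0, with a pre-bleach plateau at 1.  A constant reference-region
    trace at ``reference_level`` accompanies the cluster trace.
    """

    y0: float = 0.0
    f_mob: float = 0.7
    tau_half_s: float = 17.0
    interval_s: float = 10.0
    n_prebleach: int = 5
    duration_s: float = 300.0
    noise_sd: float = 0.0
    reference_level: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_half_s <= 0:
            raise ValueError("tau_half_s must be positive")
        if self.interval_s <= 0:
            raise ValueError("sampling interval must be positive")
        if not (0.0 <= self.y0 <= self.f_mob <= 1.2):
            raise ValueError("require 0 <= Y0 <= F_mob <= 1.2")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")

    def model(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the recovery model at post-bleach times t >= 0 (s)."""
        t = np.asarray(t, dtype=float)
        return self.y0 + (self.f_mob - self.y0) * (
            1.0 - np.exp(-t * np.log(2.0) / self.tau_half_s)
        )


def gen_frap_trace(truth: FrapTruth) -> tuple[pd.DataFrame, FrapTruth]:
    """Simulate one FRAP trace from its generative truth.

    Returns a DataFrame with columns ``time_s`` (pre-bleach frames at
    negative times, the first post-bleach frame at t = 0), ``roi``
    (cluster trace, normalised units), ``reference`` (constant reference
    region) and ``background`` (zeros), plus the truth.  The bleach frame
    index is ``truth.n_prebleach`` (first post-bleach acquisition).
    """
    if truth.duration_s < 3.0 * truth.tau_half_s:
        warnings.warn(
            "trace covers less than 3 half-lives; plateau estimates may be poor"
        )
    rng = np.random.default_rng(truth.seed)
    t_post = np.arange(0.0, truth.duration_s + 0.5 * truth.interval_s, truth.interval_s)
    t_pre = -truth.interval_s * np.arange(truth.n_prebleach, 0, -1)
    time = np.concatenate([t_pre, t_post])

    roi = np.concatenate([np.ones(truth.n_prebleach), truth.model(t_post)])
    reference = np.full(time.shape, truth.reference_level)
    if truth.noise_sd > 0:
        roi = roi + rng.normal(0.0, truth.noise_sd, roi.shape)
        reference = reference + rng.normal(0.0, truth.noise_sd, reference.shape)

    frame = pd.DataFrame(
        {
            "time_s": time,
            "roi": roi,
            "reference": reference,
            "background": np.zeros(time.shape),
        }
    )
    frame.attrs["bleach_frame"] = truth.n_prebleach
    frame.attrs["n_prebleach"] = truth.n_prebleach
    return frame, truth
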