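"""Quantification of in-vitro condensate droplet assays.

Implements the droplet-field metrics used to characterise liquid-liquid
phase separation of purified proteins: segmentation of spherical droplets
by intensity/size/circularity thresholds, the per-droplet partition ratio
``C_in / C_out`` (mean fluorescence inside a droplet over the mean bulk
fluorescence), the condensed fraction ``TC_in / TC_out`` (total
fluorescence inside droplets over the total fluorescence of the field),
partition-ratio based bleedthrough filtering, scaffold-masked
co-condensation, and per-channel normalisation to a reference condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "MultiChannelField",
    "DropletSet",
    "FieldMetrics",
    "segment_droplets",
    "partition_ratio",
    "condensed_fraction",
    "co_condensed_fraction",
    "filter_bleedthrough",
    "normalize_to_reference",
    "union_bulk_mask",
    "DEFAULT_CLASS_THRESHOLDS",
    "CHANNEL_CLASS_ALIASES",
]

# Partition-ratio floors correcting for spectral bleedthrough between
# detection channels: green/red fluorophores share a 1.1 floor, the blue
# channel needs 1.35 because the green fluorophore bleeds into it.
DEFAULT_CLASS_THRESHOLDS: dict[str, float] = {"green": 1.1, "red": 1.1, "blue": 1.35}

CHANNEL_CLASS_ALIASES: dict[str, str] = {
    "megfp": "green",
    "gfp": "green",
    "egfp": "green",
    "green": "green",
    "488": "green",
    "mcherry": "red",
    "mscarlet": "red",
    "msc": "red",
    "red": "red",
    "561": "red",
    "mtagbfp2": "blue",
    "bfp": "blue",
    "blue": "blue",
    "405": "blue",
}


@dataclass(frozen=True)
class MultiChannelField:
    """Aligned 2-D intensity grids, one per fluorophore channel.

    Parameters
    ----------
    channels
        Mapping of channel name to a 2-D float array of intensities (a.u.).
        All channels must share the same shape; intensities must be finite
        and non-negative.
    pixel_size_nm
        Lateral pixel size in nanometres per pixel.
    """

    channels: Mapping[str, np.ndarray]
    pixel_size_nm: float = 120.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("field must contain at least one channel")
        shapes = {np.asarray(img).shape for img in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError("channels must be 2-D arrays")
        for name, img in self.channels.items():
            arr = np.asarray(img, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return np.asarray(self.channels[name], dtype=float)
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; available: {list(self.channels)}"
            ) from None


@dataclass
class DropletSet:
    """Labelled droplet regions of one segmentation run.

    ``label_map`` assigns each pixel a positive droplet label or 0 for bulk.
    ``table`` holds one row per retained droplet with geometry (area in px,
    perimeter in px, circularity) and, per channel, the mean and total
    interior intensity (columns ``mean_<channel>`` / ``total_<channel>``).
    """

    label_map: np.ndarray
    table: pd.DataFrame
    channel: str
    params: dict = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of all droplet pixels."""
        return self.label_map > 0

    def subset(self, keep: np.ndarray) -> "DropletSet":
        """Return a new DropletSet retaining only the rows where ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        kept = self.table.loc[keep].reset_index(drop=True)
        new_map = np.zeros_like(self.label_map)
        for new_label, old_label in enumerate(kept["label"], start=1):
            new_map[self.label_map == old_label] = new_label
        kept = kept.assign(label=np.arange(1, len(kept) + 1))
        return DropletSet(new_map, kept, self.channel, dict(self.params))


@dataclass
class FieldMetrics:
    """Per-channel summary metrics of one droplet field."""

    channel: str
    c_out: float
    partition_ratios: np.ndarray
    mean_partition_ratio: float
    condensed_fraction: float
    droplet_count: int
    co_condensed_fraction: float | None = None
    scaffold_channel: str | None = None


def _circularity(area: float, perimeter: float) -> float:
    """4*pi*area / perimeter**2, clipped at 1.05 for discretisation."""
    if perimeter <= 0:
        return 1.0  # degenerate tiny region; area filters handle these
    return min(4.0 * np.pi * area / perimeter**2, 1.05)


def _resolve_threshold(img: np.ndarray, rule) -> float:
    """Resolve an intensity threshold rule to a number.

    Accepted rules: a float, ``"otsu"`` (per-channel Otsu), or a tuple
    ``("k_sd", k)`` meaning k robust standard deviations above the median
    (a fallback for fields too sparse for a bimodal histogram).
    """
    if isinstance(rule, (int, float)) and not isinstance(rule, bool):
        return float(rule)
    if rule == "otsu":
        if np.ptp(img) == 0:
            return float(np.max(img)) + 1.0  # uniform image: nothing segmented
        return float(threshold_otsu(img))
    if isinstance(rule, tuple) and len(rule) == 2 and rule[0] == "k_sd":
        k = float(rule[1])
        med = float(np.median(img))
        # robust sd from the median absolute deviation
        sd = 1.4826 * float(np.median(np.abs(img - med)))
        if sd == 0:
            sd = float(np.std(img))
        return med + k * sd
    raise ValueError(f"unknown intensity threshold rule: {rule!r}")


def segment_droplets(
    field: MultiChannelField,
    channel: str,
    intensity_thresh_rule="otsu",
    min_area: int = 10,
    max_area: int = 10_000,
    min_circularity: float = 0.8,
) -> DropletSet:
    """Segment droplets in one channel by intensity, size and circularity.

    Connected components above the intensity threshold are retained when
    their area lies in ``[min_area, max_area]`` pixels and their
    circularity ``4*pi*area/perimeter**2`` is at least ``min_circularity``.
    An image with nothing above threshold yields an empty DropletSet.

    Returns a :class:`DropletSet` whose table carries per-droplet geometry
    and the mean/total interior intensity of every channel in the field.
    """
    img = field.channel(channel)
    thresh = _resolve_threshold(img, intensity_thresh_rule)
    if min_area <= 0 or max_area <= 0:
        raise ValueError("area bounds must be positive")

    binary = img > thresh
    labels = measure.label(binary, connectivity=2)
    props = measure.regionprops(labels)

    rows = []
    keep_labels = []
    for p in props:
        perim = measure.perimeter_crofton(labels == p.label, directions=4)
        circ = _circularity(p.area, perim)
        if not (min_area <= p.area <= max_area):
            continue
        if circ < min_circularity:
            continue
        keep_labels.append(p.label)
        rows.append(
            {
                "area_px": float(p.area),
                "perimeter_px": float(perim),
                "circularity": circ,
                "centroid_row": p.centroid[0],
                "centroid_col": p.centroid[1],
            }
        )

    label_map = np.zeros_like(labels)
    for new_label, old in enumerate(keep_labels, start=1):
        label_map[labels == old] = new_label

    table = pd.DataFrame(rows)
    if len(table):
        table.insert(0, "label", np.arange(1, len(table) + 1))
        for name in field.channel_names:
            ch = field.channel(name)
            means, totals = [], []
            for lbl in table["label"]:
                vals = ch[label_map == lbl]
                means.append(float(vals.mean()))
                totals.append(float(vals.sum()))
            table[f"mean_{name}"] = means
            table[f"total_{name}"] = totals
    else:
        cols = ["label", "area_px", "perimeter_px", "circularity",
                "centroid_row", "centroid_col"]
        cols += [f"mean_{n}" for n in field.channel_names]
        cols += [f"total_{n}" for n in field.channel_names]
        table = pd.DataFrame(columns=cols)

    params = {
        "channel": channel,
        "threshold": thresh,
        "min_area": min_area,
        "max_area": max_area,
        "min_circularity": min_circularity,
    }
    return DropletSet(label_map, table, channel, params)


def union_bulk_mask(droplet_sets: Sequence[DropletSet]) -> np.ndarray:
    """Boolean mask of pixels belonging to no droplet in any of the sets.

    The bulk estimate C_out is taken over condensate-free pixels, so when
    several channels were segmented the union of their droplet masks is
    excluded.
    """
    if not droplet_sets:
        raise ValueError("need at least one DropletSet")
    mask = np.zeros_like(droplet_sets[0].label_map, dtype=bool)
    for ds in droplet_sets:
        mask |= ds.mask
    return ~mask


def partition_ratio(
    field: MultiChannelField,
    droplets: DropletSet,
    channel: str,
    bulk_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Per-droplet partition ratios ``C_in / C_out`` and their mean.

    ``C_in`` is the mean intensity of the evaluated channel inside each
    droplet; ``C_out`` is the mean over the bulk — by default every pixel
    outside all droplets of ``droplets``, or a caller-supplied
    ``bulk_mask`` (e.g. :func:`union_bulk_mask` across channels).

    Returns ``(ratios, mean_ratio, c_out)``. A zero bulk mean leaves the
    ratios as NaN (flagged undefined) rather than raising.
    """
    img = field.channel(channel)
    if bulk_mask is None:
        bulk_mask = ~droplets.mask
    bulk = img[bulk_mask]
    c_out = float(bulk.mean()) if bulk.size else 0.0

    means = droplets.table.get(f"mean_{channel}")
    if means is None:
        # droplets segmented on a different field: recompute from the map
        means = [
            float(img[droplets.label_map == lbl].mean())
            for lbl in droplets.table["label"]
        ]
    c_in = np.asarray(means, dtype=float)

    if c_out == 0.0:
        ratios = np.full(len(c_in), np.nan)
    else:
        ratios = c_in / c_out
    finite = ratios[np.isfinite(ratios)]
    mean_ratio = float(finite.mean()) if len(finite) else np.nan
    return ratios, mean_ratio, c_out


def condensed_fraction(
    field: MultiChannelField, droplets: DropletSet, channel: str
) -> float:
    """Total intensity inside droplets over total intensity of the field.

    This is ``TC_in / TC_out`` with ``TC_out`` the whole-field intensity
    sum, i.e. the percentage of fluorescence residing in the condensed
    phase; always in [0, 1].
    """
    img = field.channel(channel)
    total = float(img.sum())
    if total == 0.0:
        warnings.warn(f"channel {channel!r} is all zero; condensed fraction is 0")
        return 0.0
    inside = float(img[droplets.mask].sum())
    return inside / total


def co_condensed_fraction(
    field: MultiChannelField, scaffold_droplets: DropletSet, target_channel: str
) -> float:
    """Condensed fraction of ``target_channel`` over a scaffold's droplet mask.

    Measures how much of a client protein's fluorescence resides inside the
    droplets formed by a scaffold protein (e.g. client fluorescence inside
    beta-catenin droplets over the client's whole-field total).
    """
    if not scaffold_droplets.mask.any():
        warnings.warn("empty scaffold mask; co-condensed fraction is 0")
        return 0.0
    return condensed_fraction(field, scaffold_droplets, target_channel)


def channel_class(name: str) -> str:
    """Map a fluorophore/channel name onto its spectral class.

    Raises ``KeyError`` for unknown names so callers must then provide an
    explicit threshold.
    """
    key = name.lower().replace("-", "").replace("_", "")
    if key in CHANNEL_CLASS_ALIASES:
        return CHANNEL_CLASS_ALIASES[key]
    # fluorophore names may appear as part of a construct name
    # (e.g. "mEGFP-bcat"); generic colour words must match exactly
    generic = {"green", "red", "blue"}
    for alias, cls in CHANNEL_CLASS_ALIASES.items():
        if alias not in generic and alias in key:
            return cls
    raise KeyError(
        f"cannot infer spectral class of channel {name!r}; "
        "pass an explicit bleedthrough threshold for it"
    )


def filter_bleedthrough(
    droplets: DropletSet,
    per_channel_ratios: Mapping[str, np.ndarray],
    channel_class_thresholds: Mapping[str, float] | None = None,
    explicit_thresholds: Mapping[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Per-channel droplet retention masks from partition-ratio floors.

    Droplets whose partition ratio in a channel falls below that channel's
    floor are excluded from that channel's statistics (they are most likely
    bleedthrough, not genuine enrichment). Filtering is per channel: a
    droplet excluded for one channel still contributes to the others and
    the droplet geometry is never deleted, so a scaffold mask stays intact.

    Parameters
    ----------
    per_channel_ratios
        Channel name -> per-droplet partition ratios (aligned to
        ``droplets.table``).
    channel_class_thresholds
        Floor per spectral class; defaults to 1.1 for green/red and 1.35
        for blue.
    explicit_thresholds
        Per-channel overrides taking precedence over class inference.

    Returns channel name -> boolean retention mask.
    """
    class_thresholds = dict(DEFAULT_CLASS_THRESHOLDS)
    if channel_class_thresholds:
        class_thresholds.update(channel_class_thresholds)
    explicit = dict(explicit_thresholds or {})

    retained: dict[str, np.ndarray] = {}
    for name, ratios in per_channel_ratios.items():
        ratios = np.asarray(ratios, dtype=float)
        if len(ratios) != len(droplets):
            raise ValueError(
                f"{len(ratios)} ratios for {len(droplets)} droplets in {name!r}"
            )
        if name in explicit:
            floor = float(explicit[name])
        else:
            cls = channel_class(name)  # KeyError demands explicit threshold
            if cls not in class_thresholds:
                raise KeyError(f"no threshold for channel class {cls!r}")
            floor = float(class_thresholds[cls])
        with np.errstate(invalid="ignore"):
            retained[name] = ratios >= floor
    return retained


def normalize_to_reference(
    condition_table: pd.DataFrame,
    reference_condition: str,
    condition_col: str = "condition",
    channel_col: str = "channel",
    value_col: str = "value",
) -> pd.DataFrame:
    """Divide each value by its channel's reference-condition mean.

    Normalisation is independent per channel, so the reference condition's
    mean maps to 1 in every channel. The input is a tidy long table with
    one measurement per row.
    """
    ref = condition_table[condition_table[condition_col] == reference_condition]
    if ref.empty:
        raise ValueError(f"reference condition {reference_condition!r} not present")
    ref_means = ref.groupby(channel_col)[value_col].mean()
    if (ref_means == 0).any() or ref_means.isna().any():
        bad = ref_means[(ref_means == 0) | ref_means.isna()].index.tolist()
        raise ValueError(f"zero/NaN reference mean for channel(s) {bad}")

    out = condition_table.copy()
    missing = set(out[channel_col]) - set(ref_means.index)
    if missing:
        raise ValueError(f"channels missing from reference condition: {sorted(missing)}")
    out[value_col] = out[value_col] / out[channel_col].map(ref_means)
    return out
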