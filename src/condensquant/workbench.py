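"""Replicate-aware aggregation, contact-score summaries, and pipeline runs.

Imaging experiments here have a nested design: several images (or
contacts) per independent replicate, several replicates per condition.
Summaries therefore follow the superplot convention — per-image points,
per-replicate means, and a condition mean with the standard deviation
taken across replicate means, so pseudo-replication never tightens the
error bars.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "aggregate_replicates",
    "summarize_contact_scores",
    "run_pipeline",
    "write_manifest",
]


@dataclass(frozen=True)
class ReplicateSummary:
    """Three-level summary of a nested measurement table."""

    per_image: pd.DataFrame
    replicate_means: pd.DataFrame
    condition_summary: pd.DataFrame


def aggregate_replicates(
    table: pd.DataFrame,
    condition_col: str = "condition",
    replicate_col: str = "replicate",
    value_col: str = "value",
    metric_col: str | None = None,
) -> ReplicateSummary:
    """Aggregate a tidy long table at image, replicate and condition level.

    The condition mean is the mean of replicate means and its sd is taken
    across replicate means (ddof=1; NaN with a single replicate).  Rows
    with not-applicable (NaN) values are dropped from means.  Output is
    invariant to row order.
    """
    keys = [condition_col] + ([metric_col] if metric_col else [])
    data = table.dropna(subset=[value_col]).copy()
    empty = set(table[condition_col].unique()) - set(data[condition_col].unique())
    if empty:
        warnings.warn(f"conditions with no finite values omitted: {sorted(empty)}")

    rep_means = (
        data.groupby(keys + [replicate_col], sort=True)[value_col]
        .mean()
        .rename("replicate_mean")
        .reset_index()
    )
    cond = (
        rep_means.groupby(keys, sort=True)["replicate_mean"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n_replicates="count")
        .reset_index()
    )
    per_image = data.sort_values(keys + [replicate_col]).reset_index(drop=True)
    return ReplicateSummary(per_image, rep_means, cond)


def summarize_contact_scores(
    scores: pd.DataFrame,
    condition_col: str = "condition",
    replicate_col: str = "replicate",
    clustering_col: str = "clustering",
    linear_col: str = "linear_junction",
    onset_col: str = "onset_min",
    censored_col: str = "censored",
) -> dict[str, pd.DataFrame]:
    """Summarise manually scored de-novo junction-formation experiments.

    Per condition: the fraction of contacts showing clustering, the
    fraction establishing a linear junction, their cross-tabulation, and
    onset delays of cortical enrichment (right-censored contacts — those
    never showing enrichment within the movie — are excluded from onset
    means but still counted in the fractions).
    """
    df = scores.copy()
    for col in (clustering_col, linear_col, censored_col):
        df[col] = df[col].astype(bool)
    if (df.loc[~df[censored_col], onset_col] < 0).any():
        raise ValueError("onset delays must be >= 0 (or censored)")

    rows = []
    for cond, grp in df.groupby(condition_col, sort=True):
        onsets = grp.loc[~grp[censored_col], onset_col]
        rows.append(
            {
                condition_col: cond,
                "n_contacts": len(grp),
                "fraction_clustering": grp[clustering_col].mean(),
                "fraction_linear_junction": grp[linear_col].mean(),
                "n_clustering_and_linear": int((grp[clustering_col] & grp[linear_col]).sum()),
                "n_clustering_only": int((grp[clustering_col] & ~grp[linear_col]).sum()),
                "n_linear_only": int((~grp[clustering_col] & grp[linear_col]).sum()),
                "n_neither": int((~grp[clustering_col] & ~grp[linear_col]).sum()),
                "n_censored": int(grp[censored_col].sum()),
                # all-censored conditions have no onset estimate (not applicable)
                "mean_onset_min": onsets.mean() if len(onsets) else np.nan,
            }
        )
    per_condition = pd.DataFrame(rows)

    onset_reps = (
        df.loc[~df[censored_col]]
        .groupby([condition_col, replicate_col], sort=True)[onset_col]
        .mean()
        .rename("replicate_mean_onset_min")
        .reset_index()
    )
    return {"per_condition": per_condition, "onset_replicate_means": onset_reps}


# ---------------------------------------------------------------------------
# pipeline driver


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir: Path, config: dict, outputs: list[Path]) -> Path:
    """Write a JSON run manifest recording parameters and output hashes."""
    from . import __version__

    manifest = {
        "version": __version__,
        "config": config,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


REQUIRED_KEYS = {
    "droplets": {"input", "out_dir"},
    "junction": {"input", "polylines", "pixel_size_nm", "out_dir"},
    "frap": {"traces", "out_dir"},
}


def validate_config(kind: str, config: dict) -> None:
    if kind not in REQUIRED_KEYS:
        raise ValueError(f"unknown pipeline kind {kind!r}")
    missing = REQUIRED_KEYS[kind] - set(config)
    if missing:
        raise ValueError(
            f"config for {kind!r} pipeline is missing keys: {sorted(missing)}"
        )


def run_pipeline(kind: str, config: dict) -> Path:
    """Dispatch a pipeline run; returns the manifest path.

    Reruns with an identical config (and seeds) are byte-identical: no
    timestamps or unordered collections enter the outputs.
    """
    from . import pipelines

    validate_config(kind, config)
    runner = {
        "droplets": pipelines.run_droplets,
        "junction": pipelines.run_junction,
        "frap": pipelines.run_frap,
    }[kind]
    return runner(config)
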