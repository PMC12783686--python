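"""Concrete pipeline runners behind :func:`condensquant.workbench.run_pipeline`.

Each runner reads its inputs, executes the corresponding analysis module,
writes CSV/JSON outputs into ``out_dir``, and finishes with a manifest
recording the configuration and SHA-256 of every output so a rerun can be
verified byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import dropletquant as dq
from . import frapkinetics as fk
from . import junctionclusters as jc
from .io import (
    CSV_FLOAT_FORMAT,
    read_field_tiff,
    read_frap_csv,
    read_polylines,
)
from .workbench import write_manifest

__all__ = ["run_droplets", "run_junction", "run_frap"]


def run_droplets(config: dict) -> Path:
    """Segment droplets and compute per-droplet and per-field metrics."""
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    field = read_field_tiff(
        config["input"],
        channel_names=config.get("channels"),
        pixel_size_nm=config.get("pixel_size_nm"),
    )
    seg_cfg = config.get("segmentation", {})
    kwargs = dict(
        intensity_thresh_rule=seg_cfg.get("threshold", "otsu"),
        min_area=seg_cfg.get("min_area", 10),
        max_area=seg_cfg.get("max_area", 10_000),
        min_circularity=seg_cfg.get("min_circularity", 0.8),
    )

    droplet_sets = {
        name: dq.segment_droplets(field, name, **kwargs)
        for name in field.channel_names
    }
    bulk = dq.union_bulk_mask(list(droplet_sets.values()))

    explicit = config.get("bleedthrough_thresholds") or {}
    scaffold = config.get("scaffold_channel")

    droplet_rows, metric_rows = [], []
    for name, droplets in droplet_sets.items():
        ratios, mean_ratio, c_out = dq.partition_ratio(field, droplets, name, bulk)
        retained = dq.filter_bleedthrough(
            droplets, {name: ratios}, explicit_thresholds=explicit
        )[name] if len(droplets) else np.array([], dtype=bool)

        kept = droplets.subset(retained) if len(droplets) else droplets
        cf = dq.condensed_fraction(field, kept, name)
        co = (
            dq.co_condensed_fraction(field, droplet_sets[scaffold], name)
            if scaffold
            else np.nan
        )
        metric_rows.append(
            {
                "channel": name,
                "c_out": c_out,
                "mean_partition_ratio": mean_ratio,
                "condensed_fraction": cf,
                "co_condensed_fraction": co,
                "droplet_count": int(retained.sum()),
            }
        )
        for i, (_, row) in enumerate(droplets.table.iterrows()):
            droplet_rows.append(
                {
                    "channel": name,
                    "label": int(row["label"]),
                    "area_px": row["area_px"],
                    "circularity": row["circularity"],
                    "partition_ratio": ratios[i],
                    "retained": bool(retained[i]),
                }
            )

    droplet_csv = out_dir / "droplets.csv"
    metrics_csv = out_dir / "field_metrics.csv"
    pd.DataFrame(droplet_rows).to_csv(droplet_csv, index=False, float_format=CSV_FLOAT_FORMAT)
    pd.DataFrame(metric_rows).to_csv(metrics_csv, index=False, float_format=CSV_FLOAT_FORMAT)
    return write_manifest(out_dir, config, [droplet_csv, metrics_csv])


def run_junction(config: dict) -> Path:
    """Profile junctions: peak density, overlap, correlation, FWHM sizes."""
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    field = read_field_tiff(
        config["input"], channel_names=config.get("channels"),
        pixel_size_nm=config.get("pixel_size_nm"),
    )
    polylines = read_polylines(config["polylines"])
    width = int(config.get("width_px", 4))
    min_amp = float(config.get("min_amplitude_fraction", 0.5))
    window = int(config.get("overlap_window_px", 3))
    fit_window = int(config.get("fit_window_px", 10))
    px = float(config["pixel_size_nm"])

    names = list(field.channel_names)
    ref_ch = config.get("reference_channel", names[0])
    partner_ch = config.get("partner_channel", names[1] if len(names) > 1 else None)

    contact_rows, cluster_rows = [], []
    for contact, poly in polylines.items():
        prof_ref = jc.extract_line_profile(field.channel(ref_ch), poly, width, px)
        nref = jc.normalize_profile(prof_ref)
        peaks_ref = jc.detect_peaks(nref, min_amp)

        row = {
            "contact": contact,
            "length_um": nref.length_um,
            "n_peaks": len(peaks_ref),
            "peaks_per_um": jc.peak_density(peaks_ref, nref.length_um),
        }
        if partner_ch is not None:
            prof_par = jc.extract_line_profile(field.channel(partner_ch), poly, width, px)
            npar = jc.normalize_profile(prof_par)
            peaks_par = jc.detect_peaks(npar, min_amp)
            ov = jc.overlap_fraction(peaks_ref, peaks_par, window)
            r2 = jc.profile_correlation(nref, npar)
            row["overlap_fraction"] = np.nan if ov is None else ov
            row["r_squared"] = np.nan if r2 is None else r2
        contact_rows.append(row)

        for idx in peaks_ref.indices:
            shape = jc.cluster_fwhm(nref, int(idx), fit_window)
            if shape.converged:
                cluster_rows.append(
                    {
                        "contact": contact,
                        "peak_index": int(idx),
                        "position_um": idx * px / 1000.0,
                        "sigma_nm": shape.sigma_nm,
                        "fwhm_nm": shape.fwhm_nm,
                        "r_squared": shape.r_squared,
                    }
                )

    contacts_csv = out_dir / "contacts.csv"
    clusters_csv = out_dir / "clusters.csv"
    pd.DataFrame(contact_rows).to_csv(contacts_csv, index=False, float_format=CSV_FLOAT_FORMAT)
    pd.DataFrame(cluster_rows).to_csv(clusters_csv, index=False, float_format=CSV_FLOAT_FORMAT)
    return write_manifest(out_dir, config, [contacts_csv, clusters_csv])


def run_frap(config: dict) -> Path:
    """Normalise FRAP traces, fit the recovery model, compare to reference."""
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = config["traces"]
    if isinstance(paths, (str, Path)):
        paths = [paths]
    mode = config.get("mode", "ensemble-mean")
    bleach = config.get("bleach_frame")

    normalized = []
    for p in paths:
        frame = read_frap_csv(p)
        trace = fk.FrapTrace.from_frame(frame, bleach)
        normalized.append(fk.normalize_frap(trace))

    fit = fk.fit_recovery(normalized if mode == "ensemble-mean" else normalized[0], mode)
    ref_mean = np.mean([n.reference_normalized for n in normalized], axis=0)
    ratio, ref_level = fk.compare_to_reference(fit, ref_mean)

    fit_json = out_dir / "fit.json"
    fit_json.write_text(
        json.dumps(
            {
                "y0": fit.y0,
                "f_mob": fit.f_mob,
                "tau_half_s": fit.tau_half_s,
                "y0_se": fit.y0_se,
                "f_mob_se": fit.f_mob_se,
                "tau_half_se": fit.tau_half_se,
                "n_traces": fit.n_traces,
                "mode": fit.mode,
                "plateau_over_reference": ratio,
                "reference_level": ref_level,
            },
            indent=2,
            sort_keys=True,
        )
    )

    t_post = normalized[0].post_times
    curve_csv = out_dir / "fitted_curve.csv"
    pd.DataFrame({"time_s": t_post, "fitted": fit.curve(t_post)}).to_csv(
        curve_csv, index=False, float_format=CSV_FLOAT_FORMAT
    )
    norm_csv = out_dir / "normalized_traces.csv"
    norm_frame = pd.DataFrame({"time_s": normalized[0].time_s})
    for i, n in enumerate(normalized):
        norm_frame[f"trace_{i}"] = n.normalized
    norm_frame["reference_mean"] = ref_mean
    norm_frame.to_csv(norm_csv, index=False, float_format=CSV_FLOAT_FORMAT)
    return write_manifest(out_dir, config, [fit_json, curve_csv, norm_csv])
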