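"""File I/O: phantom containers, flow-curve and cohort CSV, JSON reports.

Phantom series are written either as an NPZ container or as a pair of
NIfTI volumes (magnitude, phase), each with a JSON sidecar carrying the
acquisition parameters and ground truth.  Tables are UTF-8 CSV; reports
are schema-versioned JSON embedding the resolved config hash and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .config import SCHEMA_VERSION, PipelineConfig
from .flow import FlowCurve
from .synthetic import (
    AcquisitionParams,
    PhantomSeries,
    PhantomTruth,
    VesselSpec,
    WaveformSpec,
)

__all__ = [
    "save_phantom",
    "load_phantom",
    "save_flow_curve",
    "load_flow_curve",
    "save_cohort",
    "load_cohort",
    "write_report",
]


def _truth_to_dict(truth: PhantomTruth) -> dict:
    return {
        "waveform": dataclasses.asdict(truth.waveform),
        "flow": truth.flow_curve.flow.tolist(),
        "times": truth.flow_curve.times.tolist(),
        "site_label": truth.flow_curve.site_label,
        "hfr": truth.hfr,
        "dfr_velocity": truth.dfr_velocity,
        "peak_velocity": truth.peak_velocity,
        "aliased": truth.aliased,
    }


def save_phantom(series: PhantomSeries, path: str | Path, format: str = "npz") -> Path:
    """Write a phantom series plus JSON sidecar; returns the sidecar path.

    ``format='npz'`` writes one ``.npz`` container; ``format='nifti'``
    writes ``<stem>_mag.nii`` and ``<stem>_phase.nii``.  The sidecar
    ``<stem>.json`` carries acquisition parameters, vessel geometry and
    ground truth (truth masks live in the NPZ container only).
    """
    path = Path(path)
    stem = path.with_suffix("")
    if format == "npz":
        np.savez(
            stem.with_suffix(".npz"),
            magnitude=series.magnitude,
            phase=series.phase,
            lumen_fraction=series.truth.lumen_fraction,
            static_mask=series.truth.static_mask,
            air_mask=series.truth.air_mask,
        )
    elif format == "nifti":
        affine = np.diag([series.params.pixel_spacing, series.params.pixel_spacing, 1.0, 1.0])
        # stored as (ny, nx, 1, n_phases) volumes
        mag = np.transpose(series.magnitude, (1, 2, 0))[:, :, None, :]
        phs = np.transpose(series.phase, (1, 2, 0))[:, :, None, :]
        nib.save(nib.Nifti1Image(mag, affine), str(stem) + "_mag.nii")
        nib.save(nib.Nifti1Image(phs, affine), str(stem) + "_phase.nii")
    else:
        raise ValueError(f"unknown phantom format {format!r}")

    sidecar = stem.with_suffix(".json")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "format": format,
        "params": dataclasses.asdict(series.params),
        "vessel": dataclasses.asdict(series.vessel),
        "truth": _truth_to_dict(series.truth),
    }
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return sidecar


def load_phantom(sidecar: str | Path) -> PhantomSeries:
    """Load a phantom series from its JSON sidecar (NPZ or NIfTI payload)."""
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    params = AcquisitionParams(
        **{k: tuple(v) if k == "offset_coeffs" else v for k, v in meta["params"].items()}
    )
    vessel_d = meta["vessel"]
    vessel = VesselSpec(
        center=tuple(vessel_d["center"]),
        radius=vessel_d["radius"],
        angulation=vessel_d["angulation"],
        profile=vessel_d["profile"],
    )
    stem = sidecar.with_suffix("")
    if meta["format"] == "npz":
        with np.load(stem.with_suffix(".npz")) as data:
            magnitude = data["magnitude"]
            phase = data["phase"]
            lumen_fraction = data["lumen_fraction"]
            static_mask = data["static_mask"].astype(bool)
            air_mask = data["air_mask"].astype(bool)
    else:
        magnitude = np.transpose(
            np.asarray(nib.load(str(stem) + "_mag.nii").dataobj)[:, :, 0, :], (2, 0, 1)
        )
        phase = np.transpose(
            np.asarray(nib.load(str(stem) + "_phase.nii").dataobj)[:, :, 0, :], (2, 0, 1)
        )
        lumen_fraction = np.zeros(magnitude.shape[1:])
        static_mask = np.zeros(magnitude.shape[1:], dtype=bool)
        air_mask = np.zeros(magnitude.shape[1:], dtype=bool)

    t = meta["truth"]
    curve = FlowCurve(
        flow=np.array(t["flow"]), times=np.array(t["times"]), site_label=t["site_label"]
    )
    truth = PhantomTruth(
        waveform=WaveformSpec(**t["waveform"]),
        flow_curve=curve,
        lumen_fraction=lumen_fraction,
        lumen_mask=lumen_fraction > 0,
        core_mask=lumen_fraction >= 0.5,
        static_mask=static_mask,
        air_mask=air_mask,
        hfr=t["hfr"],
        dfr_velocity=t["dfr_velocity"],
        peak_velocity=t["peak_velocity"],
        aliased=t["aliased"],
    )
    return PhantomSeries(
        magnitude=magnitude, phase=phase, params=params, vessel=vessel, truth=truth
    )


def save_flow_curve(curve: FlowCurve, path: str | Path) -> None:
    """Write a flow curve as CSV with columns phase_index,time_ms,flow_ml_s."""
    pd.DataFrame(
        {
            "phase_index": np.arange(curve.n_phases),
            "time_ms": curve.times,
            "flow_ml_s": curve.flow,
        }
    ).to_csv(path, index=False)


def load_flow_curve(path: str | Path, site_label: str = "ascending") -> FlowCurve:
    df = pd.read_csv(path)
    return FlowCurve(
        flow=df["flow_ml_s"].to_numpy(),
        times=df["time_ms"].to_numpy(),
        site_label=site_label,
    )


def save_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if table.empty:
        raise ValueError(f"cohort table {path} is empty")
    for col in ("x_aao", "y_da"):
        if col not in table.columns:
            raise ValueError(f"cohort table missing required column {col!r}")
        if table[col].isna().any():
            raise ValueError(f"cohort table has missing values in {col!r}")
    return table


def write_report(payload: dict, config: PipelineConfig, path: str | Path) -> None:
    """Write a schema-versioned JSON report embedding config hash and seed.

    Serialization is canonical (sorted keys, fixed separators) so identical
    config + seeds reproduce byte-identical files.
    """
    doc = {
        "schema_version": SCHEMA_VERSION,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        **payload,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, allow_nan=True) + "\n")
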