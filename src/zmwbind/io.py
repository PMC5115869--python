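"""Plain-text persistence: per-molecule trace TSVs, cohort manifests,
idealization and QC tables, dwell tables and fit reports.

All persisted durations are seconds and concentrations molar; loaders
reject unit-less column names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from zmwbind.process import IdealizedTrace
from zmwbind.simulate import TraceSet

TRACE_COLUMNS = ["frame", "I_DD", "I_AD", "I_AA", "I_DA"]
MANIFEST_COLUMNS = ["molecule_id", "concentration_M", "seed", "file"]


def write_cohort(traces: list[TraceSet], out_dir, float_fmt: str = "%.6g") -> Path:
    """Write one TSV per molecule plus a cohort manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in traces:
        fname = f"{ts.molecule_id}.tsv"
        ts.to_frame().to_csv(out_dir / fname, sep="\t", index=False,
                             float_format=float_fmt)
        rows.append({"molecule_id": ts.molecule_id,
                     "concentration_M": ts.concentration,
                     "seed": ts.seed if ts.seed is not None else -1,
                     "file": fname})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort(manifest_path, frame_period: float = 0.1) -> list[TraceSet]:
    """Read a cohort written by :func:`write_cohort` (same schema accepted
    for real per-ZMW extractions)."""
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(man.columns)
    if missing:
        raise ValueError(f"manifest missing unit-qualified columns: {sorted(missing)}")
    out = []
    for _, row in man.iterrows():
        df = pd.read_csv(manifest_path.parent / row["file"], sep="\t")
        if not set(TRACE_COLUMNS) <= set(df.columns):
            raise ValueError(f"trace file {row['file']} missing channels")
        truth = df["truth_state"].to_numpy(dtype=np.int8) if "truth_state" in df else None
        bleach = None
        if "truth_bleached" in df and df["truth_bleached"].any():
            bleach = int(df.index[df["truth_bleached"] == 1][0])
        out.append(
            TraceSet(
                molecule_id=str(row["molecule_id"]),
                concentration=float(row["concentration_M"]),
                frame_period=frame_period,
                I_DD=df["I_DD"].to_numpy(float),
                I_AD=df["I_AD"].to_numpy(float),
                I_AA=df["I_AA"].to_numpy(float),
                I_DA=df["I_DA"].to_numpy(float),
                truth_state=truth,
                truth_bleach_frame=bleach,
                seed=int(row["seed"]) if row["seed"] >= 0 else None,
            )
        )
    return out


def write_idealizations(ideals: list[IdealizedTrace], out_dir) -> Path:
    """Per-molecule idealization TSVs plus a QC table; returns QC path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qc = []
    for it in ideals:
        qc.append({"molecule_id": it.molecule_id,
                   "concentration_M": it.concentration,
                   "n_bleach_steps": it.n_bleach_steps,
                   "amplitude": it.amplitude,
                   "snr": it.snr,
                   "accepted": int(it.accepted),
                   "reason": it.reason or "ok"})
        if it.accepted and it.states is not None:
            cols = {"frame": np.arange(len(it.states))}
            if it.corrected is not None and len(it.corrected) == len(it.states):
                cols["corrected_I"] = it.corrected
            cols["state"] = it.states
            pd.DataFrame(cols).to_csv(
                out_dir / f"{it.molecule_id}.ideal.tsv", sep="\t", index=False,
                float_format="%.6g")
    qc_path = out_dir / "qc.tsv"
    pd.DataFrame(qc).to_csv(qc_path, sep="\t", index=False)
    return qc_path


def read_idealizations(qc_path, frame_period: float = 0.1) -> list[IdealizedTrace]:
    qc_path = Path(qc_path)
    qc = pd.read_csv(qc_path, sep="\t")
    out = []
    for _, row in qc.iterrows():
        states = None
        f = qc_path.parent / f"{row['molecule_id']}.ideal.tsv"
        if row["accepted"] and f.exists():
            states = pd.read_csv(f, sep="\t")["state"].to_numpy(np.int8)
        out.append(IdealizedTrace(
            molecule_id=str(row["molecule_id"]), states=states,
            amplitude=float(row["amplitude"]), snr=float(row["snr"]),
            bleach_frame=None, n_bleach_steps=int(row["n_bleach_steps"]),
            accepted=bool(row["accepted"]),
            reason="" if row["reason"] == "ok" else str(row["reason"]),
            concentration=float(row["concentration_M"]),
            frame_period=frame_period,
        ))
    return out


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
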