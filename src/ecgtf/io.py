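"""On-disk formats: CSV signals with JSON sidecars, TF and SAECG JSON/CSV.

Signals travel as two-column CSV ``time_s,voltage_mV`` (sampling frequency
inferred from the time grid) or one-column CSV ``voltage_mV`` plus a JSON
sidecar carrying ``fs``.  Transfer functions are JSON objects with ``num``
and ``den`` coefficient lists in descending powers of z.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .preprocess import SAECG, SampledSignal
from .sysid import DiscreteTransferFunction
from .synthetic import SyntheticTrial

__all__ = [
    "load_signal",
    "save_signal",
    "load_tf",
    "save_tf",
    "save_saecg",
    "load_saecg",
    "write_trial",
]

_TIME_TOL_S = 1e-6


def load_signal(path: str | Path) -> SampledSignal:
    """Read a recording from CSV, inferring fs from the time column.

    Two-column files must have a uniform time grid (within 1 microsecond);
    one-column files need a sidecar ``<stem>.json`` with an ``fs`` entry.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path)
    if frame.shape[1] == 2:
        t = frame.iloc[:, 0].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0 or np.any(np.abs(dt - dt[0]) > _TIME_TOL_S) or dt[0] <= 0:
            raise FormatError(f"{path}: time column is not a uniform grid")
        fs = 1.0 / dt[0]
        samples = frame.iloc[:, 1].to_numpy(dtype=float)
    elif frame.shape[1] == 1:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FormatError(
                f"{path}: one-column signal needs a sidecar {sidecar.name} with fs"
            )
        meta = json.loads(sidecar.read_text())
        if "fs" not in meta:
            raise FormatError(f"{sidecar}: missing 'fs'")
        fs = float(meta["fs"])
        samples = frame.iloc[:, 0].to_numpy(dtype=float)
    else:
        raise FormatError(f"{path}: expected 1 or 2 columns, got {frame.shape[1]}")
    return SampledSignal(samples=samples, fs=fs)


def save_signal(signal: SampledSignal, path: str | Path, sidecar: dict | None = None):
    """Write a two-column CSV (time_s, voltage_mV); optional JSON sidecar."""
    path = Path(path)
    t = np.arange(len(signal)) / signal.fs
    pd.DataFrame({"time_s": t, "voltage_mV": signal.samples}).to_csv(
        path, index=False, float_format="%.9g"
    )
    if sidecar is not None:
        meta = {"fs": signal.fs, **sidecar}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def save_tf(tf: DiscreteTransferFunction, path: str | Path, fs: float | None = None):
    d = tf.to_dict()
    if fs is not None:
        d["fs"] = fs
    Path(path).write_text(json.dumps(d, indent=1))


def load_tf(path: str | Path) -> DiscreteTransferFunction:
    return DiscreteTransferFunction.from_dict(json.loads(Path(path).read_text()))


def save_saecg(saecg: SAECG, path: str | Path):
    """CSV (sample_index, voltage_mV) plus JSON sidecar with the metadata."""
    path = Path(path)
    pd.DataFrame(
        {"sample_index": np.arange(len(saecg)), "voltage_mV": saecg.samples}
    ).to_csv(path, index=False, float_format="%.9g")
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "r_offset": saecg.r_offset,
                "fs": saecg.fs,
                "n_used": saecg.n_used,
                "n_rejected": saecg.n_rejected,
            },
            indent=1,
        )
    )


def load_saecg(path: str | Path) -> SAECG:
    path = Path(path)
    frame = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return SAECG(
        samples=frame["voltage_mV"].to_numpy(dtype=float),
        r_offset=int(meta["r_offset"]),
        fs=float(meta["fs"]),
        n_used=int(meta["n_used"]),
        n_rejected=int(meta["n_rejected"]),
    )


def write_trial(trial: SyntheticTrial, out_dir: str | Path) -> Path:
    """Write a synthetic trial as per-recording CSVs plus a manifest.

    Layout: ``<subject>_<period>.csv`` with JSON sidecars, a
    ``ground_truth.json`` (true R indices, per-subject pair TF coefficients)
    and a ``manifest.json`` listing the subject file triplets.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"fs": trial.config.fs, "subjects": []}
    truth: dict = {"seed": trial.config.seed, "subjects": {}}
    for sid in trial.subject_ids:
        entry = {"subject_id": sid}
        truth_entry: dict = {"r_indices": {}, "artifact_beats": {}, "pair_tfs": {}}
        for period in ("before", "during", "after"):
            rec = trial.recordings[(sid, period)]
            name = f"{sid}_{period}.csv"
            save_signal(
                SampledSignal(samples=rec.samples, fs=rec.fs),
                out_dir / name,
                sidecar={"subject_id": sid, "period": period, "seed": trial.config.seed},
            )
            entry[f"path_{period}"] = name
            truth_entry["r_indices"][period] = rec.true_r_indices.tolist()
            truth_entry["artifact_beats"][period] = list(rec.artifact_beat_indices)
        for (s, pair), tf in trial.subject_tfs.items():
            if s == sid:
                truth_entry["pair_tfs"][pair] = tf.to_dict()
        manifest["subjects"].append(entry)
        truth["subjects"][sid] = truth_entry
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return out_dir / "manifest.json"
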