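"""Readers and writers for the pipeline's on-disk formats.

- EEG recordings: delimited text (rows = samples, header = electrode labels),
  or EDF via mne when available;
- tracing-trial logs: CSV with columns ``trial,section,direction,t,x,y``;
- connectivity index tables, session summaries, leaderboards: CSV;
- fitted models: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import STANDARD_32_LABELS, AcquisitionSpec, validate_recording_length
from .pls import ModelEvaluation, PLSRModel
from .tracing import TrackPattern, TrialRecord


# ---------------------------------------------------------------------------
# EEG recordings
# ---------------------------------------------------------------------------

def write_recording_csv(path: str | Path, recording: np.ndarray, spec: AcquisitionSpec) -> None:
    """Write a (channels x samples) recording as CSV (rows = samples)."""
    df = pd.DataFrame(np.asarray(recording).T, columns=list(spec.labels))
    df.to_csv(path, index=False)


def read_recording(
    path: str | Path,
    fs_hz: float = 250.0,
    expected_labels: tuple[str, ...] = STANDARD_32_LABELS,
    fmt: str | None = None,
) -> tuple[np.ndarray, AcquisitionSpec]:
    """Read an EEG recording (CSV/TSV matrix with a label header, or EDF).

    Channels are reordered to ``expected_labels``; missing or unknown labels
    raise with the offending names. Recordings shorter than 5 minutes trigger
    a warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("reading EDF requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        labels = tuple(ch.upper() for ch in raw.ch_names)
        data = raw.get_data()
        fs_hz = float(raw.info["sfreq"])
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        labels = tuple(str(c).upper() for c in df.columns)
        data = df.to_numpy(dtype=float).T
    expected = tuple(lab.upper() for lab in expected_labels)
    missing = [lab for lab in expected if lab not in labels]
    unknown = [lab for lab in labels if lab not in expected]
    if missing or unknown:
        parts = []
        if missing:
            parts.append(f"missing labels: {', '.join(missing)}")
        if unknown:
            parts.append(f"unknown labels: {', '.join(unknown)}")
        raise ValueError(f"channel labels do not match the montage ({'; '.join(parts)})")
    order = [labels.index(lab) for lab in expected]
    data = data[order]
    validate_recording_length(data.shape[1], fs_hz)
    return data, AcquisitionSpec(labels=expected, fs_hz=fs_hz)


# ---------------------------------------------------------------------------
# Tracing-trial logs
# ---------------------------------------------------------------------------

def write_trial_log(path: str | Path, trials: list[TrialRecord]) -> None:
    """Write trials as CSV with columns ``trial,section,direction,t,x,y``."""
    frames = []
    for i, tr in enumerate(trials, start=1):
        frames.append(
            pd.DataFrame(
                {
                    "trial": i,
                    "section": tr.section_id,
                    "direction": tr.direction,
                    "t": tr.trace[:, 2],
                    "x": tr.trace[:, 0],
                    "y": tr.trace[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trial_log(path: str | Path, track: TrackPattern) -> list[TrialRecord]:
    """Read a trial log; the track supplies each trial's section polyline."""
    df = pd.read_csv(path)
    required = {"trial", "section", "direction", "t", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trial log must have columns {sorted(required)}")
    trials = []
    for _, grp in df.groupby("trial", sort=True):
        section = int(grp["section"].iloc[0])
        direction = str(grp["direction"].iloc[0])
        trace = grp[["x", "y", "t"]].to_numpy(dtype=float)
        trials.append(
            TrialRecord(section, direction, trace, track.section_polyline(section, direction))
        )
    return trials


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def write_session_summaries(path: str | Path, rows: list[dict]) -> None:
    """CSV with columns ``session,metric,option,value``."""
    pd.DataFrame(rows, columns=["session", "metric", "option", "value"]).to_csv(path, index=False)


def write_model_json(
    path: str | Path,
    model: PLSRModel,
    evaluation: ModelEvaluation,
    meta: dict | None = None,
) -> None:
    payload = {
        "channels": list(model.feature_labels),
        "coefficients": model.coefficients.tolist(),
        "intercept": model.intercept,
        "n_latent": model.n_latent,
        "x_mean": model.x_mean.tolist(),
        "x_scale": model.x_scale.tolist(),
        "y_mean": model.y_mean,
        "evaluation": {
            "r2_insample": evaluation.r2_insample,
            "rmse": evaluation.rmse,
            "rmse_pct": evaluation.rmse_pct,
            "power": evaluation.power,
            "slope_through_origin": evaluation.slope_through_origin,
            "n_channels": evaluation.n_channels,
            "loo_predictions": evaluation.loo_predictions.tolist(),
        },
    }
    if meta:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
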