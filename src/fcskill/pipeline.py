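"""End-to-end individualized analysis: score -> connect -> search -> evaluate.

One participant's longitudinal data (per-session pre/post resting EEG plus a
tracing-trial log) is turned into the best-performing brain-behavior model:
trial logs are scored into session behavior summaries, recordings into
peak-detected connectivity indices, and a model search over candidate
(metric, center frequency, EEG condition, behavior option) combinations runs
PLSC screening, bootstrap-consensus channel selection, power-constrained
pruning and leave-one-out evaluation.

Connectivity tables are cached on disk keyed by (recording file hash, metric
set, centers, window), so repeated searches over the same recordings are
incremental.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .connectivity import METRICS, AnalysisWindow, BandScheme, connectivity_pipeline
from .pls import Candidate, DesignMatrix, SearchResult, model_search
from .tracing import build_track, score_trial, summarize_session

logger = logging.getLogger("fcskill")

BEHAVIOR_METRICS = ("pos_only", "pos_time")
BEHAVIOR_OPTIONS = ("single", "dual")


@dataclass
class RunConfig:
    """Configuration of one participant run (parsed strictly from YAML)."""

    sessions: list[dict]  # each: {pre_eeg, post_eeg, trials}
    out_dir: str
    track_extent_x_px: float = 1000.0
    track_extent_y_px: float = 700.0
    fs_hz: float = 250.0
    metrics: tuple[str, ...] = METRICS
    centers_hz: tuple[float, ...] | None = None
    behavior_metrics: tuple[str, ...] = BEHAVIOR_METRICS
    behavior_options: tuple[str, ...] = BEHAVIOR_OPTIONS
    window: AnalysisWindow = field(default_factory=AnalysisWindow)
    scheme: BandScheme = field(default_factory=BandScheme)
    n_perm: int = 2000
    n_boot: int = 1000
    n_reps: int = 50
    consensus_frac: float = 0.8
    bsr_threshold: float = 2.0
    target_power: float = 0.8
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.window, dict):
            self.window = AnalysisWindow(**self.window)
        for key in ("metrics", "centers_hz", "behavior_metrics", "behavior_options"):
            val = getattr(self, key)
            if val is not None and not isinstance(val, tuple):
                setattr(self, key, tuple(val))

    _KNOWN = {
        "sessions", "out_dir", "track_extent_x_px", "track_extent_y_px", "fs_hz",
        "metrics", "centers_hz", "behavior_metrics", "behavior_options", "window",
        "scheme", "n_perm", "n_boot", "n_reps", "consensus_frac", "bsr_threshold",
        "target_power", "alpha", "seed",
    }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "window" in raw:
            raw["window"] = AnalysisWindow(**raw["window"])
        for key in ("metrics", "centers_hz", "behavior_metrics", "behavior_options"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.describe(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def describe(self) -> dict:
        d = {k: getattr(self, k) for k in sorted(self._KNOWN) if k not in ("window", "scheme")}
        d["window"] = {
            "epoch_s": self.window.epoch_s,
            "offset_s": self.window.offset_s,
            "window_epochs": self.window.window_epochs,
        }
        d["scheme_centers"] = list(self.scheme.centers_hz)
        d["metrics"] = list(self.metrics)
        d["centers_hz"] = list(self.centers_hz) if self.centers_hz else None
        d["behavior_metrics"] = list(self.behavior_metrics)
        d["behavior_options"] = list(self.behavior_options)
        return d


def _file_sha1(path: Path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _cached_connectivity(
    path: Path, cache_dir: Path, config: RunConfig
) -> pd.DataFrame:
    centers = config.centers_hz or config.scheme.centers_hz
    key_src = json.dumps(
        [
            _file_sha1(path),
            sorted(config.metrics),
            list(centers),
            config.window.offset_s,
            config.window.window_epochs,
            config.window.epoch_s,
            config.scheme.n_cycles,
        ]
    )
    key = hashlib.sha1(key_src.encode()).hexdigest()[:16]
    cache_file = cache_dir / f"conn_{key}.csv"
    if cache_file.exists():
        return pd.read_csv(cache_file)
    data, spec = fio.read_recording(path, fs_hz=config.fs_hz)
    table = connectivity_pipeline(
        data, spec, metrics=tuple(config.metrics), scheme=config.scheme,
        window=config.window, centers_hz=tuple(centers),
    )
    cache_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(cache_file, index=False)
    return table


def _load_sessions(config: RunConfig) -> list[dict]:
    """Validate session inputs, dropping incomplete sessions with a warning."""
    usable = []
    for i, sess in enumerate(config.sessions, start=1):
        paths = {k: Path(sess[k]) for k in ("pre_eeg", "post_eeg", "trials")}
        missing = [k for k, p in paths.items() if not p.exists()]
        if missing:
            warnings.warn(f"dropping session {i}: missing {missing}", stacklevel=2)
            continue
        usable.append({"session": i, **paths})
    if len(usable) < 4:
        raise ValueError(
            f"only {len(usable)} usable sessions; at least 4 are required"
        )
    return usable


def run_participant(config: RunConfig) -> SearchResult:
    """Run the full individualized analysis for one participant.

    Writes to ``config.out_dir``: ``leaderboard.csv``, ``model.json``,
    ``behavior.csv``, ``estimated_vs_actual.csv`` and ``run_manifest.json``
    (all parameters plus the config hash). Returns the search result.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache_dir = out / "cache"
    sessions = _load_sessions(config)
    track = build_track(config.track_extent_x_px, config.track_extent_y_px)

    # --- behavior ---------------------------------------------------------
    behavior_rows = []
    summaries: dict[int, dict[str, object]] = {}
    for sess in sessions:
        trials = fio.read_trial_log(sess["trials"], track)
        scores = [score_trial(t, track.pixel_area_cm2) for t in trials]
        per_metric = {}
        for bm in config.behavior_metrics:
            try:
                perf = summarize_session(scores, metric=bm, option="dual")
            except ValueError:  # too few trials for the dual-median option
                perf = summarize_session(scores, metric=bm, option="single")
            per_metric[bm] = perf
            behavior_rows += [
                {"session": sess["session"], "metric": bm, "option": "single",
                 "value": perf.single_median},
                {"session": sess["session"], "metric": bm, "option": "dual_pre",
                 "value": perf.dual_median_pre},
                {"session": sess["session"], "metric": bm, "option": "dual_post",
                 "value": perf.dual_median_post},
            ]
        summaries[sess["session"]] = per_metric
    fio.write_session_summaries(out / "behavior.csv", behavior_rows)

    # --- connectivity -----------------------------------------------------
    tables: dict[tuple[int, str], pd.DataFrame] = {}
    for sess in sessions:
        for cond in ("pre", "post"):
            logger.info("connectivity: session %s, %s-training EEG", sess["session"], cond)
            tables[(sess["session"], cond)] = _cached_connectivity(
                sess[f"{cond}_eeg"], cache_dir, config
            )

    # --- candidates -------------------------------------------------------
    centers = config.centers_hz or config.scheme.centers_hz
    session_ids = [s["session"] for s in sessions]
    candidates = []
    for metric in config.metrics:
        for center in centers:
            for cond in ("pre", "post"):
                sub = {}
                for sid in session_ids:
                    t = tables[(sid, cond)]
                    sub[sid] = t[(t["metric"] == metric) & (t["center_hz"] == center)]
                pairs = sub[session_ids[0]]["pair"].tolist()
                X = np.vstack([sub[sid]["value"].to_numpy() for sid in session_ids])
                for bm in config.behavior_metrics:
                    for option in config.behavior_options:
                        if option == "single":
                            y = [summaries[sid][bm].single_median for sid in session_ids]
                        else:  # dual: pre EEG vs first-30 median, post vs last-30
                            attr = "dual_median_pre" if cond == "pre" else "dual_median_post"
                            y = [getattr(summaries[sid][bm], attr) for sid in session_ids]
                            if any(v is None for v in y):
                                continue  # dual medians unavailable (short logs)
                        candidates.append(
                            Candidate(
                                metric, center, cond, f"{option}:{bm}",
                                DesignMatrix(X, np.array(y), tuple(pairs), tuple(session_ids)),
                            )
                        )

    # --- search -----------------------------------------------------------
    result = model_search(
        candidates,
        alpha=config.alpha,
        n_reps=config.n_reps,
        frac=config.consensus_frac,
        bsr_threshold=config.bsr_threshold,
        n_perm=config.n_perm,
        n_boot=config.n_boot,
        target_power=config.target_power,
        seed=config.seed,
    )
    result.leaderboard.to_csv(out / "leaderboard.csv", index=False)
    manifest = {"config": config.describe(), "config_hash": config.config_hash(),
                "n_sessions_used": len(sessions), "n_candidates": len(candidates)}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    if result.best is not None:
        meta = {
            "metric": result.best.metric,
            "center_hz": result.best.center_hz,
            "eeg_condition": result.best.eeg_condition,
            "behavior_option": result.best.behavior_option,
            "config_hash": config.config_hash(),
        }
        fio.write_model_json(out / "model.json", result.best_model, result.best_evaluation, meta)
        pd.DataFrame(
            {
                "session": session_ids,
                "actual": result.best.design.y,
                "estimated": result.best_evaluation.loo_predictions,
            }
        ).to_csv(out / "estimated_vs_actual.csv", index=False)
    return result
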