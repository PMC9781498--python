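"""Synthetic study generator with planted connectivity-behavior structure.

Emulates the measured quantities of a longitudinal tracing-training study:

- 32-channel resting-state EEG (250 Hz, 5 min) as independent pink-noise
  background per electrode, with a narrowband stochastic oscillator planted
  on chosen electrode pairs at chosen center frequencies. The first electrode
  carries the oscillator; the second carries a coherent mixture of the same
  oscillator (delayed by a fixed nonzero phase lag, default pi/4, weight
  kappa) and an independent oscillator of the same bandwidth (weight
  sqrt(1 - kappa^2)), so phase-lag-based synchrony (PLI/wPLI) rises
  monotonically with the per-session coupling strength kappa in [0, 1] and is
  indistinguishable from an unplanted pair at kappa = 0;
- per-session behavior linear in the coupling, b = beta0 + beta1 * kappa + eps;
- tracing trials as the track polyline plus smooth correlated noise whose SD
  follows a per-session skill trajectory, with a terminal dwell at the
  destination vertex;
- a ``make_study`` writer that lays a full participant dataset (pre/post EEG
  plus trial logs per session) on disk in the formats the pipeline reads,
  together with a ground-truth card.

``simulate_indices`` generates the same planted linear structure directly at
the connectivity-index level (sessions x 496 features), which is the natural
scale for exercising the PLS stage in isolation.

Defaults are chosen once as a realistic regime: coupling declining from 0.85
to 0.15 over sessions (spanning the informative range of the peak-detected
index), oscillator amplitude twice the background RMS, oscillator bandwidth
half the center frequency (comparable to the analyzing wavelet's), behavior
noise giving a brain-behavior R^2 in the high-0.9s, index noise giving a
planted-column SNR around 5. The behavior scale (median tracing error around
8-10 cm^2 varying by roughly +/-10% across sessions) reproduces the regime in
which longitudinal skill change is modest relative to absolute error, which
is what makes relative estimation errors of a few percent meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .connectivity import STANDARD_32_LABELS, AcquisitionSpec
from .pls import DesignMatrix
from .tracing import TrackPattern, TrialRecord, build_track

N_SECTIONS = 8


def _default_coupling(n: int) -> tuple[float, ...]:
    return tuple(np.linspace(0.85, 0.15, n))


@dataclass(frozen=True)
class SyntheticDesign:
    """Ground-truth configuration of a synthetic participant."""

    n_sessions: int = 7
    #: planted coupling: each entry is ("EL1-EL2", center_hz) for a single
    #: electrode pair, or "EL1-EL2-...-ELm" for a synchronized network clique
    #: (all C(m, 2) pairs coupled, electrode lags staggered by 0.4 rad)
    planted: tuple[tuple[str, float], ...] = (("C3-C4", 21.0),)
    coupling: tuple[float, ...] | None = None  # per-session kappa in [0, 1]
    planted_condition: str = "pre"  # which EEG condition carries the structure
    behavior_beta: tuple[float, float] = (8.0, 3.5)  # b = beta0 + beta1 * kappa + eps, cm^2
    behavior_noise_sd: float = 0.12
    osc_amplitude: float = 2.0  # relative to unit-RMS pink background
    osc_rel_bandwidth: float = 0.5  # oscillator bandwidth as a fraction of its center
    phase_lag_rad: float = np.pi / 4
    common_source_amplitude: float = 0.0  # zero-lag volume-conduction confound
    fs_hz: float = 250.0
    duration_s: float = 300.0
    trace_speed_px_s: float = 400.0
    labels: tuple[str, ...] = STANDARD_32_LABELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling is None:
            object.__setattr__(self, "coupling", _default_coupling(self.n_sessions))
        if len(self.coupling) != self.n_sessions:
            raise ValueError("coupling must have one value per session")
        if not all(0.0 <= k <= 1.0 for k in self.coupling):
            raise ValueError("coupling strengths must lie in [0, 1]")
        if self.behavior_noise_sd < 0:
            raise ValueError("behavior noise SD must be nonnegative")
        for group, _ in self.planted:
            for el in group.split("-"):
                if el not in self.labels:
                    raise ValueError(f"planted electrode {el!r} not in the montage")

    def planted_pairs(self) -> list[tuple[str, float]]:
        """All coupled electrode pairs implied by the planted entries, with
        pair labels in montage (upper-triangle) order."""
        import itertools

        order = {lab: i for i, lab in enumerate(self.labels)}
        out = []
        for group, center in self.planted:
            els = group.split("-")
            for a, b in itertools.combinations(els, 2):
                a, b = sorted((a, b), key=order.get)
                out.append((f"{a}-{b}", center))
        return out

    def session_rng(self, session: int, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, session, stream])

    def behavior(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Planted behavior series b_s = beta0 + beta1 * kappa_s + eps."""
        rng = rng or np.random.default_rng([self.seed, 10_001])
        b0, b1 = self.behavior_beta
        eps = rng.normal(0.0, self.behavior_noise_sd, self.n_sessions)
        return b0 + b1 * np.asarray(self.coupling) + eps


# ---------------------------------------------------------------------------
# EEG simulation
# ---------------------------------------------------------------------------

def pink_noise(n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-power noise by spectral shaping of white noise."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n=n_samples)
    return x / x.std()


def narrowband_envelope(
    n_samples: int, bandwidth_hz: float, fs_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-power complex Gaussian envelope band-limited to ``bandwidth_hz``.

    Multiplied by a carrier ``exp(2j pi f t)`` this yields a narrowband
    stochastic oscillator centered at f with total spectral width
    ``bandwidth_hz``.
    """
    env = rng.standard_normal(n_samples) + 1j * rng.standard_normal(n_samples)
    spec = np.fft.fft(env)
    f = np.fft.fftfreq(n_samples, 1.0 / fs_hz)
    spec[np.abs(f) > bandwidth_hz / 2.0] = 0
    env = np.fft.ifft(spec)
    return env / np.sqrt(np.mean(np.abs(env) ** 2))


def simulate_recording(
    design: SyntheticDesign,
    session: int,
    condition: str = "pre",
    coupling: float | None = None,
) -> np.ndarray:
    """One resting-state recording (n_electrodes x samples) for a session.

    The planted condition uses the session's coupling strength; the other
    condition uses a seed-fixed permutation of the coupling series, so it
    carries connectivity of comparable magnitude but no systematic relation to
    the behavior. ``coupling`` overrides both.
    """
    if condition not in ("pre", "post"):
        raise ValueError("condition must be 'pre' or 'post'")
    if not 0 <= session < design.n_sessions:
        raise ValueError(f"session must be in 0..{design.n_sessions - 1}")
    stream = 0 if condition == "pre" else 1
    rng = design.session_rng(session, stream)
    n = int(design.duration_s * design.fs_hz)
    n_ch = len(design.labels)
    data = np.empty((n_ch, n))
    for ch in range(n_ch):
        data[ch] = pink_noise(n, rng)

    if coupling is None:
        if condition == design.planted_condition:
            kappa = design.coupling[session]
        else:
            perm = np.random.default_rng([design.seed, 77]).permutation(design.n_sessions)
            kappa = design.coupling[perm[session]]
    else:
        kappa = coupling

    t = np.arange(n) / design.fs_hz
    idx = {lab: i for i, lab in enumerate(design.labels)}
    for group, center_hz in design.planted:
        electrodes = group.split("-")
        bw = design.osc_rel_bandwidth * center_hz
        carrier = np.exp(2j * np.pi * center_hz * t)
        shared = narrowband_envelope(n, bw, design.fs_hz, rng)
        amp = design.osc_amplitude
        # each electrode mixes the lag-delayed shared oscillator (weight
        # kappa) with its own independent oscillator of the same bandwidth
        # (weight sqrt(1 - kappa^2), keeping the total oscillator power
        # fixed); lags are staggered so every pair has a nonzero phase lag
        if len(electrodes) == 2:
            # pair: first electrode carries the oscillator cleanly so the
            # pair's effective coupling scales as kappa (not kappa^2)
            lags = (0.0, design.phase_lag_rad)
            weights = (1.0, kappa)
        else:
            lags = tuple(0.4 * i for i in range(len(electrodes)))
            weights = tuple(kappa for _ in electrodes)
        for el, lag, w_shared in zip(electrodes, lags, weights):
            indep = narrowband_envelope(n, bw, design.fs_hz, rng)
            mix = w_shared * shared * np.exp(-1j * lag)
            mix = mix + np.sqrt(max(0.0, 1.0 - w_shared**2)) * indep
            data[idx[el]] += amp * np.sqrt(2.0) * np.real(mix * carrier)
        if design.common_source_amplitude > 0:
            common = design.common_source_amplitude * pink_noise(n, rng)
            for el in electrodes:
                data[idx[el]] += common
    return data


# ---------------------------------------------------------------------------
# Tracing-trial simulation
# ---------------------------------------------------------------------------

def _smooth_noise(n: int, sd_px: float, rng: np.random.Generator, corr_samples: int = 8) -> np.ndarray:
    if sd_px == 0:
        return np.zeros(n)
    raw = rng.standard_normal(n + 4 * corr_samples)
    kern = np.exp(-0.5 * (np.arange(-2 * corr_samples, 2 * corr_samples + 1) / corr_samples) ** 2)
    kern /= kern.sum()
    sm = np.convolve(raw, kern, mode="same")[:n]
    return sm / sm.std() * sd_px


def trace_noise_sd_for(behavior_cm2: float, track: TrackPattern) -> float:
    """Approximate trace-noise SD (px) yielding a given median position error.

    The area between a polyline of length L and its noisy copy with pointwise
    offset SD sigma is roughly E|offset| * L = sigma * sqrt(2/pi) * L px^2.
    """
    section_len = track.arc_length() / N_SECTIONS
    area_px2 = behavior_cm2 / track.pixel_area_cm2
    return float(area_px2 / (np.sqrt(2.0 / np.pi) * section_len))


def simulate_session_trials(
    design: SyntheticDesign,
    session: int,
    track: TrackPattern,
    n_trials: int = 90,
    trace_noise_sd_px: float | None = None,
    sample_hz: float = 100.0,
) -> list[TrialRecord]:
    """Simulate one session's tracing trials against a track pattern.

    Each trial picks a random section and direction; the trace is the section
    polyline plus smooth correlated noise (SD set by the session's skill
    level, tapered to zero at both endpoints so trials start on the start
    vertex and settle at the destination), followed by a dwell at the
    destination. Timestamps come from a constant-speed model with a lognormal
    per-trial speed factor.
    """
    rng = design.session_rng(session, 2)
    if trace_noise_sd_px is None:
        b = design.behavior()[session]
        trace_noise_sd_px = trace_noise_sd_for(max(b, 0.0), track)
    trials = []
    for _ in range(n_trials):
        section = int(rng.integers(1, N_SECTIONS + 1))
        direction = "forward" if rng.random() < 0.5 else "reverse"
        poly = track.section_polyline(section, direction)
        n_pts = len(poly)
        taper = np.minimum(1.0, np.minimum(np.arange(n_pts), np.arange(n_pts)[::-1]) / (0.1 * n_pts))
        noise = np.column_stack(
            [
                _smooth_noise(n_pts, trace_noise_sd_px, rng) * taper,
                _smooth_noise(n_pts, trace_noise_sd_px, rng) * taper,
            ]
        )
        xy = poly + noise
        seg_len = float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())
        speed = design.trace_speed_px_s * rng.lognormal(0.0, 0.1)
        duration = seg_len / speed
        t = np.linspace(0.0, duration, n_pts)
        # terminal dwell: slightly longer than required, within the rest radius
        n_dwell = int(1.3 / (1.0 / sample_hz))
        t_dwell = t[-1] + (np.arange(1, n_dwell + 1)) / sample_hz
        xy_dwell = poly[-1] + rng.normal(0.0, 0.4, (n_dwell, 2))
        trace = np.vstack(
            [
                np.column_stack([xy, t]),
                np.column_stack([xy_dwell, t_dwell]),
            ]
        )
        trials.append(TrialRecord(section, direction, trace, poly))
    return trials


# ---------------------------------------------------------------------------
# Index-level generator (the PLS stage's natural input scale)
# ---------------------------------------------------------------------------

def simulate_indices(
    design: SyntheticDesign,
    n_features: int = 496,
    n_planted: int | None = None,
    index_noise_sd: float = 0.015,
    index_gain: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[DesignMatrix, dict]:
    """Planted-structure connectivity indices without the EEG stage.

    Planted columns follow ``0.3 + index_gain * kappa + noise`` (the linear
    rise of a peak-detected synchrony index with coupling); the remaining
    columns are behavior-independent noise around a typical resting level.
    Returns the design matrix and a ground-truth dict with the planted column
    indices and the behavior series.
    """
    rng = rng or np.random.default_rng([design.seed, 20_002])
    n = design.n_sessions
    kappa = np.asarray(design.coupling)
    if n_planted is None:
        n_planted = max(1, len(design.planted))
    planted_idx = rng.choice(n_features, size=n_planted, replace=False)
    X = 0.3 + rng.normal(0.0, 0.05, (n, n_features))
    for j in planted_idx:
        X[:, j] = 0.3 + index_gain * kappa + rng.normal(0.0, index_noise_sd, n)
    X = np.clip(X, 0.0, 1.0)
    y = design.behavior(rng)
    labels = tuple(f"f{j:03d}" for j in range(n_features))
    truth = {"planted_idx": sorted(int(j) for j in planted_idx), "behavior": y.tolist(),
             "coupling": list(design.coupling)}
    return DesignMatrix(X, y, labels), truth


# ---------------------------------------------------------------------------
# Full study on disk
# ---------------------------------------------------------------------------

def make_study(
    design: SyntheticDesign,
    out_dir: str | Path,
    track: TrackPattern | None = None,
    n_trials: int = 90,
) -> dict:
    """Write a full synthetic participant dataset.

    Layout: ``<out_dir>/session_<k>/{pre_eeg.csv, post_eeg.csv, trials.csv}``
    plus ``<out_dir>/ground_truth.json``. Fixed design seed => bit-identical
    dataset. Returns the ground-truth dict.
    """
    from .io import write_recording_csv, write_trial_log

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    track = track or build_track(1000, 700)
    spec = AcquisitionSpec(labels=design.labels, fs_hz=design.fs_hz)
    behavior = design.behavior()
    truth = {
        "n_sessions": design.n_sessions,
        "planted": [[pair, c] for pair, c in design.planted],
        "planted_condition": design.planted_condition,
        "coupling": list(design.coupling),
        "behavior_beta": list(design.behavior_beta),
        "behavior": behavior.tolist(),
        "seed": design.seed,
    }
    for s in range(design.n_sessions):
        sdir = out / f"session_{s + 1:02d}"
        sdir.mkdir(exist_ok=True)
        for cond in ("pre", "post"):
            rec = simulate_recording(design, s, cond)
            write_recording_csv(sdir / f"{cond}_eeg.csv", rec, spec)
        trials = simulate_session_trials(design, s, track, n_trials=n_trials)
        write_trial_log(sdir / "trials.csv", trials)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return truth
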