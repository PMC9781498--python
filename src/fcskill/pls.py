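"""Partial least squares brain-behavior modeling.

Given a sessions x features matrix of connectivity indices (one column per
electrode pair at a fixed center frequency and metric) and a per-session
behavioral series (a tracing-performance summary), this module provides:

- PLS correlation (PLSC) with a permutation test on the singular value and
  bootstrap ratios per feature; with a single behavioral variable the salience
  vector is proportional to the correlation between behavior and each feature
  and the singular value equals that correlation vector's Euclidean norm;
- bootstrap-consensus channel selection: PLSC is repeated with independent
  bootstrap streams and only features whose |bootstrap ratio| clears a
  threshold in more than a fixed fraction of repetitions are kept;
- PLS regression (PLS1 with rank-one deflation), leave-one-out evaluation
  (RMSE as a percentage of mean behavior, zero-intercept estimated-vs-actual
  slope), post-hoc power of the regression via the noncentral F distribution,
  and power-constrained backward pruning of channels;
- a model search over candidate (metric, center, EEG condition, behavior
  option) combinations returning the best model and a full leaderboard.

Features are z-scored and behavior mean-centered internally, so coefficient
magnitudes are comparable across channels (required for the pruning rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DesignMatrix:
    """Sessions x features design with per-session behavior.

    ``feature_labels`` carry each column's identity (e.g. ``"T7-CP6"`` at a
    given center frequency).
    """

    X: np.ndarray
    y: np.ndarray
    feature_labels: tuple[str, ...]
    session_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=float).ravel()
        if X.shape[0] != len(y):
            raise ValueError("X and y disagree on the number of sessions")
        if X.shape[1] != len(self.feature_labels):
            raise ValueError("feature_labels length must match X columns")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("design matrix contains missing values")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if not self.session_ids:
            object.__setattr__(self, "session_ids", tuple(range(len(y))))

    @property
    def n_sessions(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, feature_idx: np.ndarray) -> "DesignMatrix":
        idx = np.asarray(feature_idx)
        return DesignMatrix(
            self.X[:, idx],
            self.y,
            tuple(np.asarray(self.feature_labels)[idx]),
            self.session_ids,
        )


# ---------------------------------------------------------------------------
# PLS correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PLSCResult:
    saliences: np.ndarray  # unit norm over valid features
    singular_value: float
    p_perm: float
    bootstrap_ratios: np.ndarray  # NaN for dropped (zero-variance) features
    feature_labels: tuple[str, ...]
    n_perm: int
    n_boot: int
    dropped: tuple[int, ...] = ()


def _zscore_cols(X: np.ndarray, ddof: int = 1) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    return (X - mu) / sd


def _corr_with_y(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of X with y."""
    n = len(y)
    Xz = _zscore_cols(X)
    yz = (y - y.mean()) / y.std(ddof=1)
    return Xz.T @ yz / (n - 1)


def plsc(
    design: DesignMatrix,
    n_perm: int = 2000,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PLSCResult:
    """PLS correlation of behavior with connectivity features.

    The z-scored brain-behavior cross-correlation is decomposed by SVD; with a
    single behavioral variable this reduces to salience = corr / ||corr|| and
    singular value = ||corr||. Significance is assessed by permuting the
    behavior labels (the observed value is included in both numerator and
    denominator of the p-value); robustness by bootstrap resampling of
    sessions, with bootstrap ratio = observed correlation / bootstrap SE.
    Zero-variance columns are dropped with a warning (their salience is 0 and
    bootstrap ratio NaN in the returned arrays).
    """
    rng = np.random.default_rng(seed)
    X, y = design.X, design.y
    n, p = X.shape
    if n < 4:
        raise ValueError("PLSC needs at least 4 sessions")
    if y.std() == 0:
        raise ValueError("behavior has zero variance")
    sd = X.std(axis=0, ddof=1)
    dropped = tuple(int(i) for i in np.nonzero(sd == 0)[0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature column(s)", stacklevel=2)
    valid = sd > 0
    Xv = X[:, valid]

    r_obs = _corr_with_y(Xv, y)
    sv_obs = float(np.linalg.norm(r_obs))

    # vectorized permutations of the behavior labels
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = y[perm_idx]  # (n_perm, n)
    Ypz = (Yp - Yp.mean(axis=1, keepdims=True)) / Yp.std(axis=1, ddof=1, keepdims=True)
    Xz = _zscore_cols(Xv)
    Rp = Ypz @ Xz / (n - 1)  # (n_perm, p_valid)
    sv_perm = np.linalg.norm(Rp, axis=1)
    p_perm = (1.0 + np.sum(sv_perm >= sv_obs)) / (n_perm + 1.0)

    # bootstrap over sessions
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    Xb = Xv[boot_idx]  # (n_boot, n, p)
    Yb = y[boot_idx]  # (n_boot, n)
    Xb_mu = Xb.mean(axis=1, keepdims=True)
    Xb_sd = Xb.std(axis=1, ddof=1, keepdims=True)
    Yb_mu = Yb.mean(axis=1, keepdims=True)
    Yb_sd = Yb.std(axis=1, ddof=1, keepdims=True)
    ok_y = (Yb_sd[:, 0] > 0).ravel()
    ok_x = Xb_sd[:, 0, :] > 0  # (n_boot, p)
    Xbz = np.divide(Xb - Xb_mu, Xb_sd, out=np.zeros_like(Xb), where=Xb_sd > 0)
    Ybz = np.divide(Yb - Yb_mu, Yb_sd, out=np.zeros_like(Yb), where=Yb_sd > 0)
    Rb = np.einsum("bn,bnp->bp", Ybz, Xbz) / (n - 1)
    usable = ok_y[:, None] & ok_x
    # SE per feature over usable resamples
    cnt = usable.sum(axis=0)
    mean_b = np.where(cnt > 1, np.sum(np.where(usable, Rb, 0.0), axis=0) / np.maximum(cnt, 1), 0.0)
    var_b = np.sum(np.where(usable, (Rb - mean_b) ** 2, 0.0), axis=0) / np.maximum(cnt - 1, 1)
    se = np.sqrt(var_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr_valid = np.where(se > 0, r_obs / se, np.sign(r_obs) * np.inf)

    saliences = np.zeros(p)
    bsr = np.full(p, np.nan)
    saliences[valid] = r_obs / sv_obs if sv_obs > 0 else 0.0
    bsr[valid] = bsr_valid
    return PLSCResult(
        saliences, sv_obs, float(p_perm), bsr, design.feature_labels, n_perm, n_boot, dropped
    )


def consensus_channels(
    design: DesignMatrix,
    n_reps: int = 50,
    frac: float = 0.8,
    bsr_threshold: float = 2.0,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    n_perm: int = 200,
) -> tuple[np.ndarray, PLSCResult]:
    """Bootstrap-consensus feature selection.

    PLSC is repeated ``n_reps`` times with independent bootstrap streams; a
    feature is selected if its |bootstrap ratio| >= ``bsr_threshold`` in MORE
    than ``frac`` of the repetitions (so ``frac=0`` keeps every feature that
    ever clears the threshold). Returns (selected feature indices, the first
    repetition's PLSCResult). An empty consensus is returned as an empty index
    array; callers should treat it as "no robust channels".
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros(design.n_features)
    first: PLSCResult | None = None
    for _ in range(n_reps):
        res = plsc(design, n_perm=n_perm, n_boot=n_boot, seed=rng)
        if first is None:
            first = res
        counts += (np.abs(np.nan_to_num(res.bootstrap_ratios, nan=0.0)) >= bsr_threshold)
    selected = np.nonzero(counts / n_reps > frac)[0]
    if len(selected) == 0:
        warnings.warn("empty consensus: no feature cleared the bootstrap-ratio threshold", stacklevel=2)
    return selected, first  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# PLS regression (PLS1 with deflation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PLSRModel:
    """PLS1 regression model with coefficients mapped back to feature space."""

    coefficients: np.ndarray  # original (unstandardized) feature space
    intercept: float
    n_latent: int
    feature_labels: tuple[str, ...]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    r2: float
    mean_only: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coefficients + self.intercept

    @property
    def coefficients_std(self) -> np.ndarray:
        """Coefficients on z-scored features (scale-free magnitudes)."""
        return self.coefficients * self.x_scale


def plsr_fit(
    design: DesignMatrix,
    n_latent: int | None = None,
    *,
    scale: bool = True,
) -> PLSRModel:
    """Fit PLS1 by iterative rank-one deflation.

    Per component: the weight vector is the (normalized) covariance between
    the current deflated features and behavior — for a single behavioral
    variable the covariance-matrix SVD reduces to exactly this vector; scores,
    loadings and a rank-one deflation of X and y follow. The loop stops at
    ``n_latent`` components (default ``min(n_features, n_sessions - 2)``) or
    when X is fully deflated. Coefficients are mapped back to the original
    feature space. A constant behavior series yields a mean-only model.
    """
    X, y = design.X, design.y
    n, p = X.shape
    if n_latent is None:
        n_latent = max(1, min(p, n - 2))
    if n_latent > min(n - 1, p):
        warnings.warn(
            f"n_latent={n_latent} exceeds min(n-1, p)={min(n - 1, p)}; truncating", stacklevel=2
        )
        n_latent = min(n - 1, p)
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(p)
    if np.any(x_scale == 0):
        raise ValueError("zero-variance feature column; drop it before fitting")
    y_mean = float(y.mean())
    Xc = (X - x_mean) / x_scale
    yc = y - y_mean

    if np.allclose(yc, 0):
        return PLSRModel(
            np.zeros(p), y_mean, 0, design.feature_labels, x_mean, x_scale, y_mean, 1.0, True
        )

    W, P, Q = [], [], []
    Xd, yd = Xc.copy(), yc.copy()
    for _ in range(n_latent):
        w = Xd.T @ yd
        norm_w = np.linalg.norm(w)
        if norm_w < 1e-12 * max(1.0, np.abs(yd).max()):
            break  # fully deflated
        w /= norm_w
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-24:
            break
        p_load = Xd.T @ t / tt
        q = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p_load)
        yd = yd - t * q
        W.append(w)
        P.append(p_load)
        Q.append(q)
    if not Q:  # X carries no covariance with y at all
        return PLSRModel(
            np.zeros(p), y_mean, 0, design.feature_labels, x_mean, x_scale, y_mean, 0.0, True
        )
    Wm, Pm, Qv = np.array(W).T, np.array(P).T, np.array(Q)
    beta_std = Wm @ np.linalg.solve(Pm.T @ Wm, Qv)
    coef = beta_std / x_scale
    intercept = y_mean - float(x_mean @ coef)
    pred = X @ coef + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum(yc**2))
    r2 = 1.0 - ss_res / ss_tot
    return PLSRModel(
        coef, intercept, len(Q), design.feature_labels, x_mean, x_scale, y_mean, r2
    )


# ---------------------------------------------------------------------------
# Evaluation: LOO, power, pruning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelEvaluation:
    loo_predictions: np.ndarray
    rmse: float
    rmse_pct: float  # 100 * rmse / mean(y)
    r2_insample: float
    power: float | None
    slope_through_origin: float
    n_channels: int
    feature_labels: tuple[str, ...] = ()


def regression_power(r2: float, n: int, k: int, alpha: float = 0.05) -> float:
    """Post-hoc power of the overall F-test of a k-predictor regression.

    Cohen's effect size f^2 = R^2 / (1 - R^2); the test statistic under the
    alternative is noncentral F with df (k, n - k - 1) and noncentrality
    lambda = f^2 * n.
    """
    if n <= k + 1:
        raise ValueError(f"power undefined: need n > k + 1 (n={n}, k={k})")
    if not 0 < r2 < 1:
        if r2 <= 0:
            return alpha  # null limit
        return 1.0  # perfect fit limit
    f2 = r2 / (1.0 - r2)
    lam = f2 * n
    df1, df2 = k, n - k - 1
    fcrit = stats.f.ppf(1.0 - alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def loo_evaluate(
    design: DesignMatrix,
    n_latent: int | None = None,
    *,
    alpha: float = 0.05,
    scale: bool = True,
) -> ModelEvaluation:
    """Leave-one-session-out evaluation of the PLS1 model.

    For each session the model is refit on the remaining sessions and used to
    predict the held-out behavior. RMSE over held-out predictions is reported
    both raw and as a percentage of the mean behavior; the estimated-vs-actual
    relation is summarized by the least-squares slope through the origin.
    Power uses the full-sample in-sample R^2 (None when n <= k + 1).
    """
    X, y = design.X, design.y
    n, k = X.shape
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 sessions")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sub = DesignMatrix(X[mask], y[mask], design.feature_labels)
        try:
            model = plsr_fit(sub, n_latent, scale=scale)
        except ValueError:
            # e.g. a column constant within the training fold: mean fallback
            preds[i] = y[mask].mean()
            continue
        preds[i] = model.predict(X[i : i + 1])[0]
    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    mean_y = float(np.mean(y))
    rmse_pct = 100.0 * rmse / mean_y if mean_y != 0 else float("inf")
    denom = float(y @ y)
    slope = float(preds @ y) / denom if denom > 0 else float("nan")
    full = plsr_fit(design, n_latent, scale=scale)
    power = regression_power(full.r2, n, k, alpha) if n > k + 1 else None
    return ModelEvaluation(
        preds, rmse, rmse_pct, full.r2, power, slope, k, design.feature_labels
    )


def prune_channels(
    design: DesignMatrix,
    target_power: float = 0.8,
    alpha: float = 0.05,
    n_latent: int | None = None,
) -> tuple[PLSRModel, ModelEvaluation, bool]:
    """Power-constrained backward pruning of channels.

    Fit, compute post-hoc power from the in-sample R^2; while the power is
    below ``target_power`` (or undefined because n <= k + 1) and more than one
    channel remains, drop the channel with the smallest absolute standardized
    coefficient (ties broken by column order) and refit. Returns the final
    model, its leave-one-out evaluation, and a flag that is True when the
    target power could not be reached even with a single channel.
    """
    if design.n_features == 0:
        raise ValueError("cannot prune an empty channel set")
    current = design
    while True:
        model = plsr_fit(current, n_latent)
        n, k = current.n_sessions, current.n_features
        power = regression_power(model.r2, n, k, alpha) if n > k + 1 else None
        if power is not None and power >= target_power:
            unreached = False
            break
        if k == 1:
            unreached = True
            warnings.warn("target power not reached with a single channel", stacklevel=2)
            break
        drop = int(np.argmin(np.abs(model.coefficients_std)))
        keep = np.array([j for j in range(k) if j != drop])
        current = current.subset(keep)
    evaluation = loo_evaluate(current, n_latent, alpha=alpha)
    return model, evaluation, unreached


# ---------------------------------------------------------------------------
# Model search over the candidate grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    """One cell of the model-search grid."""

    metric: str
    center_hz: float
    eeg_condition: str  # 'pre' | 'post'
    behavior_option: str  # e.g. 'single:pos_only'
    design: DesignMatrix


@dataclass(frozen=True)
class SearchResult:
    best: Candidate | None
    best_model: PLSRModel | None
    best_evaluation: ModelEvaluation | None
    leaderboard: pd.DataFrame
    best_features: tuple[str, ...] = ()


def model_search(
    candidates: list[Candidate],
    *,
    alpha: float = 0.05,
    n_reps: int = 50,
    frac: float = 0.8,
    bsr_threshold: float = 2.0,
    n_perm: int = 2000,
    n_boot: int = 1000,
    target_power: float = 0.8,
    seed: int | np.random.Generator | None = None,
) -> SearchResult:
    """Screen, select, prune and cross-validate every candidate combination.

    Per candidate: PLSC permutation screening at ``alpha``; bootstrap-consensus
    channel selection; power-constrained pruning; leave-one-out evaluation.
    The winner minimizes LOO RMSE%, with ties broken by fewer channels, then
    lower permutation p, then grid order. The leaderboard has one row per
    candidate regardless of screening outcome.
    """
    rng = np.random.default_rng(seed)
    rows = []
    results: list[tuple[int, Candidate, PLSRModel, ModelEvaluation]] = []
    for i, cand in enumerate(candidates):
        row = {
            "metric": cand.metric,
            "center_hz": cand.center_hz,
            "eeg_condition": cand.eeg_condition,
            "behavior_option": cand.behavior_option,
            "p_perm": np.nan,
            "k": 0,
            "R2": np.nan,
            "power": np.nan,
            "rmse_pct": np.nan,
            "status": "",
        }
        try:
            screen = plsc(cand.design, n_perm=n_perm, n_boot=n_boot, seed=rng)
        except ValueError as exc:
            row["status"] = f"error: {exc}"
            rows.append(row)
            continue
        row["p_perm"] = screen.p_perm
        if screen.p_perm >= alpha:
            row["status"] = "screened_out"
            rows.append(row)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected, _ = consensus_channels(
                cand.design, n_reps=n_reps, frac=frac,
                bsr_threshold=bsr_threshold, n_boot=n_boot, seed=rng,
            )
        if len(selected) == 0:
            row["status"] = "empty_consensus"
            rows.append(row)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, evaluation, unreached = prune_channels(
                cand.design.subset(selected), target_power=target_power, alpha=alpha
            )
        row.update(
            k=evaluation.n_channels,
            R2=evaluation.r2_insample,
            power=evaluation.power if evaluation.power is not None else np.nan,
            rmse_pct=evaluation.rmse_pct,
            status="underpowered" if unreached else "ok",
        )
        rows.append(row)
        results.append((i, cand, model, evaluation))
    leaderboard = pd.DataFrame(rows)
    if not results:
        return SearchResult(None, None, None, leaderboard)
    order = sorted(
        results,
        key=lambda r: (
            r[3].rmse_pct,
            r[3].n_channels,
            leaderboard.loc[r[0], "p_perm"],
            r[0],
        ),
    )
    _, best, best_model, best_eval = order[0]
    return SearchResult(best, best_model, best_eval, leaderboard, best_eval.feature_labels)
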