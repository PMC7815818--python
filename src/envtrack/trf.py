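"""Forward TRF estimation: lagged ridge regression, cross-validated tracking,
and permutation chance levels.

The temporal response function maps time-lagged multiband envelope-edge
features (-100 to 450 ms by default) onto each EEG channel via ridge
regression; cross-validated Pearson correlation between predicted and
observed EEG, averaged over tracks then channels, is the cortical tracking
metric. Chance levels are the 97.5th percentile of the same metric under
derangement re-pairings of stimulus and EEG tracks.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .envelope import MultibandEnvelope
from .preprocess import EEGEpochs

__all__ = [
    "LagWindow",
    "TRFModel",
    "TrackingResult",
    "DEFAULT_LAMBDA_GRID",
    "build_lagged_design",
    "prepare_designs",
    "DesignGram",
    "fit_ridge",
    "predict_eeg",
    "crossval_tracking",
    "permutation_chance_level",
    "fit_subject_trf",
    "stimulus_locked_response",
]

DEFAULT_LAMBDA_GRID = 10.0 ** np.arange(0, 7)  # 10^0 .. 10^6 in decade steps


@dataclass(frozen=True)
class LagWindow:
    """Inclusive lag window; lag samples are round(t * fs / 1000)."""

    t_min_ms: float = -100.0
    t_max_ms: float = 450.0
    fs: float = 128.0

    def __post_init__(self) -> None:
        if self.t_min_ms >= self.t_max_ms:
            raise ValueError("t_min_ms must be < t_max_ms")

    @property
    def lags(self) -> np.ndarray:
        lo = int(np.round(self.t_min_ms * self.fs / 1000.0))
        hi = int(np.round(self.t_max_ms * self.fs / 1000.0))
        return np.arange(lo, hi + 1)

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.fs

    @property
    def n_lags(self) -> int:
        return len(self.lags)


@dataclass
class TRFModel:
    """Lag x band x channel beta weights plus per-channel intercept."""

    weights: np.ndarray  # (n_lags, n_bands, n_channels)
    intercept: np.ndarray  # (n_channels,)
    lam: float
    lag_axis_ms: np.ndarray
    band_centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.intercept = np.atleast_1d(np.asarray(self.intercept, dtype=float))
        if self.weights.ndim != 3:
            raise ValueError("weights must be lag x band x channel")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weights")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")

    @property
    def n_lags(self) -> int:
        return self.weights.shape[0]

    @property
    def n_bands(self) -> int:
        return self.weights.shape[1]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[2]

    def flat_weights(self) -> np.ndarray:
        """(n_lags*n_bands, n_channels), lag-major band-minor (design column order)."""
        return self.weights.reshape(self.n_lags * self.n_bands, self.n_channels)


@dataclass
class TrackingResult:
    """Per-track/per-channel prediction accuracies and their summary."""

    r_per_track_channel: np.ndarray  # (n_tracks, n_channels)
    r_mean: float
    lambda_selected: float
    band: str = "full"
    chance_level: float = np.nan
    lambda_grid: np.ndarray | None = None
    grid_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.r_per_track_channel, dtype=float)
        if np.any(np.abs(r[np.isfinite(r)]) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        self.r_per_track_channel = r


def build_lagged_design(env: MultibandEnvelope | np.ndarray, window: LagWindow) -> np.ndarray:
    """Sample x (1 + n_lags*n_bands) design matrix with a leading intercept column.

    Row t holds env(band, t - tau) for every lag tau (negative lags look into
    the future); out-of-range samples are zero-padded. Columns after the
    intercept are ordered lag-major, band-minor: column 1 + i_lag*n_bands + i_band.
    """
    if isinstance(env, MultibandEnvelope):
        if env.fs != window.fs:
            raise ValueError(f"envelope rate {env.fs} != lag-window rate {window.fs}")
        feats = env.features
    else:
        feats = np.atleast_2d(np.asarray(env, dtype=float))
    nb, n = feats.shape
    lags = window.lags
    X = np.zeros((n, 1 + nb * len(lags)))
    X[:, 0] = 1.0
    F = feats.T
    for li, tau in enumerate(lags):
        cols = slice(1 + li * nb, 1 + (li + 1) * nb)
        if tau >= 0:
            X[tau:, cols] = F[: n - tau]
        else:
            X[: n + tau, cols] = F[-tau:]
    return X


def prepare_designs(envs: list[MultibandEnvelope], window: LagWindow) -> list[np.ndarray]:
    """Precompute per-track design matrices (reusable across subjects/lambdas)."""
    return [build_lagged_design(e, window) for e in envs]


def _ridge_solve(XtX: np.ndarray, Xty: np.ndarray, lam: float) -> np.ndarray:
    """Solve (XtX + lam*m*P) w = Xty with the intercept (column 0) unpenalized.

    m = trace(XtX)/ncols makes lambda comparable across track lengths.
    """
    ncols = XtX.shape[0]
    A = XtX.copy()
    if lam > 0:
        m = np.trace(XtX) / ncols
        A[np.arange(1, ncols), np.arange(1, ncols)] += lam * m
    try:
        c = cho_factor(A)
    except LinAlgError as err:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; use lambda > 0 for a unique solution"
        ) from err
    return cho_solve(c, Xty)


def fit_ridge(
    design: np.ndarray,
    eeg: np.ndarray,
    lam: float,
    *,
    window: LagWindow | None = None,
    n_bands: int | None = None,
    band_centers: np.ndarray | None = None,
) -> TRFModel:
    """Ridge regression of ``eeg`` (sample x channel) on a lagged design matrix."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim == 1:
        eeg = eeg[:, None]
    if design.shape[0] != eeg.shape[0]:
        raise ValueError("design and eeg row counts differ")
    W = _ridge_solve(design.T @ design, design.T @ eeg, lam)
    intercept, coefs = W[0], W[1:]
    p = coefs.shape[0]
    if window is not None:
        nl = window.n_lags
        nb = n_bands if n_bands is not None else p // nl
        lag_ms = window.lags_ms
    else:
        nl, nb = p, 1
        lag_ms = np.arange(p, dtype=float)
    if nl * nb != p:
        raise ValueError(f"{p} coefficients do not factor into {nl} lags x {nb} bands")
    return TRFModel(
        weights=coefs.reshape(nl, nb, eeg.shape[1]),
        intercept=intercept,
        lam=lam,
        lag_axis_ms=lag_ms,
        band_centers=band_centers,
    )


def predict_eeg(model: TRFModel, env: MultibandEnvelope | np.ndarray, window: LagWindow | None = None) -> np.ndarray:
    """Predicted EEG (sample x channel) = lagged design @ weights + intercept."""
    if window is None:
        if isinstance(env, MultibandEnvelope):
            window = LagWindow(model.lag_axis_ms[0], model.lag_axis_ms[-1], env.fs)
        else:
            raise ValueError("window required for raw feature arrays")
    nb = env.n_bands if isinstance(env, MultibandEnvelope) else np.atleast_2d(env).shape[0]
    if nb != model.n_bands:
        raise ValueError(f"feature band count {nb} != model band count {model.n_bands}")
    X = build_lagged_design(env, window)
    if X.shape[1] - 1 != model.n_lags * model.n_bands:
        raise ValueError("lag/band dimension mismatch between model and design")
    return X[:, 1:] @ model.flat_weights() + model.intercept


def stimulus_locked_response(epochs: EEGEpochs, n_samples: int) -> list[np.ndarray]:
    """Post-onset (sample x channel) response per track, truncated to ``n_samples``."""
    i0 = epochs.onset_sample
    stop = min(i0 + n_samples, epochs.n_samples)
    return [epochs.data[:, i0:stop, k].T for k in range(epochs.n_tracks)]


class DesignGram:
    """Per-track Gram matrices of a fixed design set, cacheable across subjects.

    Holds XtX, column sums, and lazily computed Cholesky factors of the
    ridge-regularized normal equations per lambda — the expensive parts that
    depend only on the stimuli, not on any subject's EEG.
    """

    def __init__(self, X_list: list[np.ndarray]):
        self.X_list = X_list
        self.n = len(X_list)
        self.XtX = [X.T @ X for X in X_list]
        self.colsum = [X.sum(axis=0) for X in X_list]
        self.nsamp = [X.shape[0] for X in X_list]
        self.ncols = X_list[0].shape[1]
        self._factors: dict[float, list] = {}

    def factors(self, lam: float) -> list:
        if lam not in self._factors:
            chols = []
            for G in self.XtX:
                A = G.copy()
                if lam > 0:
                    m = np.trace(G) / self.ncols
                    A[np.arange(1, self.ncols), np.arange(1, self.ncols)] += lam * m
                try:
                    chols.append(cho_factor(A))
                except LinAlgError as err:
                    raise np.linalg.LinAlgError(
                        "rank-deficient design; use lambda > 0"
                    ) from err
            self._factors[lam] = chols
        return self._factors[lam]


class _CVEngine:
    """Cross-validated correlations from cached cross-products.

    Per-track TRFs are fit once per (stimulus, response) pairing requested;
    Pearson correlations for any fold model are evaluated from Gram matrices
    without materializing predictions.
    """

    def __init__(self, gram: DesignGram, Y_list, lam, pairs="diag", xty=None):
        self.g = gram
        self.n = gram.n
        if self.n != len(Y_list):
            raise ValueError("stimulus/response track counts differ")
        self.ysum = [Y.sum(axis=0) for Y in Y_list]
        self.yss = [(Y * Y).sum(axis=0) for Y in Y_list]
        if xty is not None:
            self.Xty = xty
        elif pairs == "diag":
            self.Xty = {(i, i): gram.X_list[i].T @ Y_list[i] for i in range(self.n)}
        else:
            self.Xty = {
                (i, j): gram.X_list[i].T @ Y_list[j]
                for i in range(self.n)
                for j in range(self.n)
            }
        chols = gram.factors(lam)
        self.W = {k: cho_solve(chols[k[0]], v) for k, v in self.Xty.items()}

    def fold_r(self, k: int, pairing: np.ndarray) -> np.ndarray:
        """Per-channel Pearson r for held-out track k under a track pairing."""
        train = [i for i in range(self.n) if i != k]
        Wm = np.mean([self.W[(i, pairing[i])] for i in train], axis=0)
        j = pairing[k]
        N = self.g.nsamp[k]
        xty = self.Xty[(k, j)]  # (ncols, nch)
        dot = (Wm * xty).sum(axis=0)  # pred . y  (intercept row included)
        sum_pred = self.g.colsum[k] @ Wm
        ss_pred = np.einsum("ic,ij,jc->c", Wm, self.g.XtX[k], Wm)
        cov = dot - sum_pred * self.ysum[j] / N
        var_p = ss_pred - sum_pred**2 / N
        var_y = self.yss[j] - self.ysum[j] ** 2 / N
        denom = np.sqrt(np.maximum(var_p, 0) * np.maximum(var_y, 0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, cov / denom, 0.0)
        return np.clip(r, -1.0, 1.0)

    def cv_matrix(self, pairing: np.ndarray | None = None) -> np.ndarray:
        if pairing is None:
            pairing = np.arange(self.n)
        return np.stack([self.fold_r(k, pairing) for k in range(self.n)])


def _as_xy(envs, epochs, window, designs, gram=None):
    """Resolve (DesignGram, Y_list) from envelopes/designs/cached gram + epochs."""
    if gram is None:
        X_list = designs if designs is not None else prepare_designs(envs, window)
    else:
        X_list = gram.X_list
    if isinstance(epochs, EEGEpochs):
        Y_list = stimulus_locked_response(epochs, max(X.shape[0] for X in X_list))
    else:
        Y_list = [np.asarray(Y, dtype=float) for Y in epochs]
    if gram is None:
        X_list = [X[: Y.shape[0]] for X, Y in zip(X_list, Y_list)]
        gram = DesignGram(X_list)
    if any(Y.shape[0] != n for Y, n in zip(Y_list, gram.nsamp)):
        Y_list = [Y[:n] for Y, n in zip(Y_list, gram.nsamp)]
        if any(Y.shape[0] != n for Y, n in zip(Y_list, gram.nsamp)):
            raise ValueError("response tracks shorter than the cached designs")
    return gram, Y_list


def crossval_tracking(
    envs: list[MultibandEnvelope] | None,
    epochs: EEGEpochs,
    window: LagWindow,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    *,
    designs: list[np.ndarray] | None = None,
    gram: DesignGram | None = None,
) -> TrackingResult:
    """Leave-one-track-out cross-validated tracking with ridge-parameter selection.

    For each lambda and each held-out track, per-track TRFs fit on the
    remaining tracks are averaged into the fold model (mTRF convention) and
    the held-out track's per-channel Pearson r recorded. The lambda
    maximizing the grand-mean r is selected.
    """
    g, Y_list = _as_xy(envs, epochs, window, designs, gram)
    if g.n < 3:
        raise ValueError("cross-validation requires at least 3 tracks")
    grid = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
    xty = {(i, i): g.X_list[i].T @ Y_list[i] for i in range(g.n)}
    best = None
    scores = np.empty(len(grid))
    for gi, lam in enumerate(grid):
        eng = _CVEngine(g, Y_list, lam, xty=xty)
        R = eng.cv_matrix()
        gm = float(R.mean())
        scores[gi] = gm
        if best is None or gm > best[0]:
            best = (gm, lam, R)
    gm, lam, R = best
    band = epochs.band if isinstance(epochs, EEGEpochs) else "full"
    return TrackingResult(
        r_per_track_channel=R,
        r_mean=gm,
        lambda_selected=float(lam),
        band=band,
        lambda_grid=grid,
        grid_scores=scores,
    )


def _sample_derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    idx = np.arange(n)
    while True:
        p = rng.permutation(n)
        if not np.any(p == idx):
            return p


def permutation_chance_level(
    envs: list[MultibandEnvelope] | None,
    epochs: EEGEpochs,
    window: LagWindow,
    lam: float,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    *,
    designs: list[np.ndarray] | None = None,
    gram: DesignGram | None = None,
    return_distribution: bool = False,
):
    """97.5th percentile of grand-mean tracking under mismatched track pairings.

    Each permutation re-pairs stimulus tracks with non-matching EEG tracks via
    a uniformly sampled derangement, recomputes the cross-validated grand-mean
    r at the given lambda, and the 97.5th percentile of the resulting
    distribution is the chance level.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable 97.5th percentile")
    g, Y_list = _as_xy(envs, epochs, window, designs, gram)
    n = g.n
    if n < 3:
        raise ValueError("permutation chance level requires at least 3 tracks")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eng = _CVEngine(g, Y_list, lam, pairs="all")
    vals = np.empty(n_perm)
    for p in range(n_perm):
        pairing = _sample_derangement(rng, n)
        vals[p] = eng.cv_matrix(pairing).mean()
    level = float(np.percentile(vals, 97.5))
    if return_distribution:
        return level, vals
    return level


def fit_subject_trf(
    envs: list[MultibandEnvelope] | None,
    epochs: EEGEpochs,
    window: LagWindow,
    lam: float,
    *,
    designs: list[np.ndarray] | None = None,
    gram: DesignGram | None = None,
) -> TRFModel:
    """Subject-level TRF: average of per-track ridge fits at a fixed lambda."""
    g, Y_list = _as_xy(envs, epochs, window, designs, gram)
    chols = g.factors(lam)
    Ws = [
        cho_solve(chols[i], g.X_list[i].T @ Y_list[i]) for i in range(g.n)
    ]
    Wm = np.mean(Ws, axis=0)
    nb = (g.ncols - 1) // window.n_lags
    centers = envs[0].band_centers if envs else None
    return TRFModel(
        weights=Wm[1:].reshape(window.n_lags, nb, -1),
        intercept=Wm[0],
        lam=lam,
        lag_axis_ms=window.lags_ms,
        band_centers=centers,
    )
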