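"""Backward (decoding) models: kernel ridge convolution, static ridge,
and per-phoneme logistic regression.

The convolution model reconstructs each time-varying feature channel
``s_f(t)`` from a lagged window of the evoked response,

    s_f(t) = sum_x sum_{tau=tau1..tau2} g_f(tau, x) r(t + tau, x),

where ``tau`` runs over positive stimulus-to-response delays (neural
activity follows, never precedes, the stimulus sample it encodes) and
one independent spatiotemporal filter ``g_f`` is fit per channel.  The
ridge solution exists in two algebraically identical forms: the primal
normal equations ``(R'R + lam I)^-1 R'S`` and the dual (kernel/Gram)
form ``R'(RR' + lam I)^-1 S``.  The dual form is the cheap one when the
number of training samples is far below the lag x sensor dimensionality,
which is the typical evoked-MEG regime; the solver is chosen by shape
unless forced.

The ridge penalty ``lam`` is selected on a grid by leave-one-out error
within the training data, where the left-out unit is one *stimulus*
(all of its time frames), since frames within a stimulus are strongly
dependent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "DEFAULT_PENALTY_GRID",
    "LaggedDesign",
    "ConvolutionModel",
    "RidgeModel",
    "LogisticPhonemeModel",
    "lag_matrix",
    "build_lagged_design",
    "ridge_primal",
    "ridge_dual",
    "ridge_fit",
    "loo_lambda_select",
    "fit_convolution",
    "predict_time_varying",
    "fit_ridge_static",
    "predict_static",
    "fit_logistic_phonemes",
    "predict_phonemes",
]

#: default penalty grid: 10^-3 .. 10^6
DEFAULT_PENALTY_GRID = tuple(10.0**k for k in range(-3, 7))


def _lag_samples(lags_ms: np.ndarray, rate: float) -> np.ndarray:
    lags_ms = np.asarray(lags_ms, dtype=float)
    if lags_ms.size == 0:
        raise ValueError("empty lag set")
    if np.any(lags_ms < 0):
        raise ValueError("lags must be non-negative delays (response follows stimulus)")
    return np.round(lags_ms * rate / 1000.0).astype(int)


def lag_window_ms(tau1_ms: float, tau2_ms: float, rate: float = 100.0) -> np.ndarray:
    """All lag samples from ``tau1`` to ``tau2`` ms inclusive, in ms."""
    if tau1_ms > tau2_ms:
        raise ValueError("tau1 must not exceed tau2")
    step = 1000.0 / rate
    n = int(round((tau2_ms - tau1_ms) / step)) + 1
    return tau1_ms + step * np.arange(n)


def lag_matrix(
    response: np.ndarray,
    lags_ms,
    rate: float,
    n_frames: int,
    onset: int = 0,
) -> np.ndarray:
    """Lagged design block for one stimulus.

    Row ``t`` concatenates ``r(t + tau, x)`` over lags (outer) and
    sensors (inner): columns are ordered lag-major.  Lags are positive
    *delays* from a stimulus time point to the response samples that
    encode it — the response follows the stimulus, so reconstructing
    ``s(t)`` uses the response from ``t + tau1`` to ``t + tau2``.
    Samples falling outside the recording are zero-filled (responses
    are baseline-corrected toward zero).

    Parameters
    ----------
    response : ndarray, (n_sensors, n_times)
        Evoked response; index ``onset`` is stimulus onset (t = 0).
    lags_ms : array-like
        Non-negative delays in ms.
    rate : float
        Sampling rate in Hz (10 ms resolution at 100 Hz).
    n_frames : int
        Number of feature frames (rows) to produce.
    """
    response = np.asarray(response, dtype=float)
    n_sensors, n_times = response.shape
    taus = _lag_samples(lags_ms, rate)
    t = np.arange(n_frames)
    idx = onset + t[:, None] + taus[None, :]  # (n_frames, n_lags)
    valid = (idx >= 0) & (idx < n_times)
    safe = np.clip(idx, 0, n_times - 1)
    block = response[:, safe]  # (n_sensors, n_frames, n_lags)
    block = np.where(valid[None], block, 0.0)
    # -> (n_frames, n_lags, n_sensors) -> flat lag-major
    return block.transpose(1, 2, 0).reshape(n_frames, -1)


@dataclass
class LaggedDesign:
    """Stacked lagged response matrix R with its row bookkeeping."""

    matrix: np.ndarray  # (sum of frame counts, n_lags * n_sensors)
    lags_ms: np.ndarray
    rate: float
    n_sensors: int
    row_stimulus: np.ndarray  # stimulus index per row

    @property
    def n_lags(self) -> int:
        return len(self.lags_ms)

    def rows_of(self, stimulus: int) -> np.ndarray:
        return np.flatnonzero(self.row_stimulus == stimulus)


def build_lagged_design(
    responses,
    lags_ms,
    rate: float,
    target_lengths,
    onset: int = 0,
) -> LaggedDesign:
    """Stack per-stimulus lagged blocks into one design matrix.

    ``responses`` is an (n_stimuli, n_sensors, n_times) array or a list
    of (n_sensors, n_times) arrays; ``target_lengths[n]`` gives the
    number of feature frames of stimulus ``n``.
    """
    lags_ms = np.asarray(lags_ms, dtype=float)
    if lags_ms.size > 1 and np.any(np.diff(lags_ms) < 0):
        raise ValueError("lags must be ordered")
    blocks, owner = [], []
    for n, resp in enumerate(responses):
        blk = lag_matrix(resp, lags_ms, rate, int(target_lengths[n]), onset)
        blocks.append(blk)
        owner.append(np.full(blk.shape[0], n))
    R = np.concatenate(blocks, axis=0)
    n_sensors = np.asarray(responses[0]).shape[0]
    return LaggedDesign(R, lags_ms, rate, n_sensors, np.concatenate(owner))


# ---------------------------------------------------------------------------
# ridge solvers


def ridge_primal(R: np.ndarray, S: np.ndarray, lam: float) -> np.ndarray:
    """MAP estimate via the normal equations (R'R + lam I)^-1 R'S."""
    D = R.shape[1]
    A = R.T @ R + lam * np.eye(D)
    return scipy.linalg.solve(A, R.T @ S, assume_a="pos")


def ridge_dual(R: np.ndarray, S: np.ndarray, lam: float) -> np.ndarray:
    """MAP estimate via the Gram (kernel) form R'(RR' + lam I)^-1 S."""
    n = R.shape[0]
    K = R @ R.T + lam * np.eye(n)
    return R.T @ scipy.linalg.solve(K, S, assume_a="pos")


def ridge_fit(R: np.ndarray, S: np.ndarray, lam: float, solver: str = "auto") -> np.ndarray:
    """Ridge weights, choosing the cheaper of the two identical forms."""
    if solver == "auto":
        solver = "primal" if R.shape[1] <= R.shape[0] else "dual"
    if solver == "primal":
        return ridge_primal(R, S, lam)
    if solver == "dual":
        return ridge_dual(R, S, lam)
    raise ValueError(f"unknown solver {solver!r}")


def _stimulus_slices(row_stimulus: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(row_stimulus == n) for n in np.unique(row_stimulus)]


def loo_lambda_select(
    R: np.ndarray,
    S: np.ndarray,
    row_stimulus: np.ndarray,
    grid=DEFAULT_PENALTY_GRID,
    solver: str = "auto",
) -> tuple[float, np.ndarray]:
    """Pick the ridge penalty by leave-one-stimulus-out error.

    For every grid value, each stimulus in turn is held out, the model
    is refit on the remaining rows (by down-dating the normal equations
    or by dropping kernel rows, whichever is cheaper), and the squared
    prediction error on the held-out rows is accumulated.

    Returns the best penalty and the per-grid-point error vector.
    Grid points whose system is numerically singular are skipped with a
    warning.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3 or np.any(np.diff(grid) <= 0) or np.any(grid <= 0):
        raise ValueError("penalty grid must be >= 3 strictly increasing positive values")
    S = np.atleast_2d(S.T).T  # (rows, k)
    slices = _stimulus_slices(row_stimulus)
    n_rows, D = R.shape
    use_primal = solver == "primal" or (solver == "auto" and D <= n_rows)
    errors = np.full(grid.size, np.inf)
    if use_primal:
        A = R.T @ R
        b = R.T @ S
        blocks = [(R[ix], S[ix]) for ix in slices]
        A_blocks = [Rn.T @ Rn for Rn, _ in blocks]
        b_blocks = [Rn.T @ Sn for Rn, Sn in blocks]
        eye = np.eye(D)
        for gi, lam in enumerate(grid):
            err = 0.0
            try:
                for (Rn, Sn), An, bn in zip(blocks, A_blocks, b_blocks):
                    w = scipy.linalg.solve(A - An + lam * eye, b - bn, assume_a="pos")
                    err += float(((Rn @ w - Sn) ** 2).sum())
            except scipy.linalg.LinAlgError:
                warnings.warn(f"singular system at lambda={lam:g}; skipped", RuntimeWarning)
                continue
            errors[gi] = err
    else:
        K = R @ R.T
        for gi, lam in enumerate(grid):
            err = 0.0
            try:
                for ix in slices:
                    keep = np.setdiff1d(np.arange(n_rows), ix, assume_unique=True)
                    alpha = scipy.linalg.solve(
                        K[np.ix_(keep, keep)] + lam * np.eye(keep.size),
                        S[keep],
                        assume_a="pos",
                    )
                    pred = K[np.ix_(ix, keep)] @ alpha
                    err += float(((pred - S[ix]) ** 2).sum())
            except scipy.linalg.LinAlgError:
                warnings.warn(f"singular system at lambda={lam:g}; skipped", RuntimeWarning)
                continue
            errors[gi] = err
    if not np.any(np.isfinite(errors)):
        raise RuntimeError("all penalty grid points failed")
    return float(grid[int(np.argmin(errors))]), errors


# ---------------------------------------------------------------------------
# model containers and fit/predict


@dataclass
class ConvolutionModel:
    """Per-channel lagged ridge filters G_f with their penalties."""

    weights: np.ndarray  # (n_lags * n_sensors, n_channels)
    lambdas: np.ndarray  # (n_channels,)
    lags_ms: np.ndarray
    rate: float
    n_sensors: int


@dataclass
class RidgeModel:
    """Static (time-integrated) ridge decoder over a 0-1000 ms window."""

    weights: np.ndarray  # (n_sensors * n_times, n_features)
    lambdas: np.ndarray
    n_sensors: int
    n_times: int


def fit_convolution(
    design: LaggedDesign,
    S: np.ndarray,
    grid=DEFAULT_PENALTY_GRID,
    solver: str = "auto",
    lambdas: np.ndarray | None = None,
) -> ConvolutionModel:
    """Fit the convolution decoder, one filter per feature channel.

    ``S`` is (n_rows, n_channels), rows aligned with ``design.matrix``.
    Each channel gets its own penalty by leave-one-stimulus-out unless
    ``lambdas`` pins them.
    """
    S = np.atleast_2d(S.T).T
    if S.shape[0] != design.matrix.shape[0]:
        raise ValueError("feature rows do not match design rows")
    n_ch = S.shape[1]
    if lambdas is None:
        lambdas = np.empty(n_ch)
        for f in range(n_ch):
            lambdas[f], _ = loo_lambda_select(
                design.matrix, S[:, [f]], design.row_stimulus, grid, solver
            )
    else:
        lambdas = np.broadcast_to(np.asarray(lambdas, float), (n_ch,)).copy()
    W = np.empty((design.matrix.shape[1], n_ch))
    for lam in np.unique(lambdas):
        cols = np.flatnonzero(lambdas == lam)
        W[:, cols] = ridge_fit(design.matrix, S[:, cols], lam, solver)
    return ConvolutionModel(W, lambdas, design.lags_ms, design.rate, design.n_sensors)


def predict_time_varying(
    model: ConvolutionModel,
    response: np.ndarray,
    n_frames: int,
    onset: int = 0,
) -> np.ndarray:
    """Reconstruct feature channels from one test response.

    Returns (n_frames, n_channels).
    """
    response = np.asarray(response, dtype=float)
    if response.shape[0] != model.n_sensors:
        raise ValueError("sensor layout mismatch")
    R = lag_matrix(response, model.lags_ms, model.rate, n_frames, onset)
    return R @ model.weights


def fit_ridge_static(
    X: np.ndarray,
    S: np.ndarray,
    grid=DEFAULT_PENALTY_GRID,
    n_sensors: int | None = None,
    n_times: int | None = None,
    lambdas: np.ndarray | None = None,
) -> RidgeModel:
    """Ridge decoder for non time-varying features.

    ``X`` is one flattened (sensor x time) response row per stimulus —
    typically the 0-1000 ms window — and ``S`` one feature value per
    stimulus per feature.  Solved in the dual form (stimuli are far
    fewer than response samples); the penalty is ordinary leave-one-out
    over stimuli.
    """
    X = np.asarray(X, dtype=float)
    S = np.atleast_2d(np.asarray(S, dtype=float).T).T
    if X.shape[0] != S.shape[0]:
        raise ValueError("one feature row per stimulus required")
    rows = np.arange(X.shape[0])
    n_ch = S.shape[1]
    if lambdas is None:
        lambdas = np.empty(n_ch)
        for f in range(n_ch):
            lambdas[f], _ = loo_lambda_select(X, S[:, [f]], rows, grid, solver="dual")
    else:
        lambdas = np.broadcast_to(np.asarray(lambdas, float), (n_ch,)).copy()
    W = np.empty((X.shape[1], n_ch))
    for lam in np.unique(lambdas):
        cols = np.flatnonzero(lambdas == lam)
        W[:, cols] = ridge_dual(X, S[:, cols], lam)
    return RidgeModel(
        W,
        lambdas,
        n_sensors or X.shape[1],
        n_times or 1,
    )


def predict_static(model: RidgeModel, X: np.ndarray) -> np.ndarray:
    return np.asarray(X, dtype=float) @ model.weights


# ---------------------------------------------------------------------------
# logistic phoneme decoding


@dataclass
class LogisticPhonemeModel:
    """One binary ridge-regularized logistic model per phoneme row."""

    coefs: dict = field(default_factory=dict)  # label -> (w, b)
    labels: list = field(default_factory=list)
    skipped: list = field(default_factory=list)
    lags_ms: np.ndarray | None = None
    rate: float = 100.0
    n_sensors: int | None = None


def fit_logistic_phonemes(
    design: LaggedDesign,
    Y: np.ndarray,
    labels: list,
    alpha: float = 1e-3,
    max_epochs: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> LogisticPhonemeModel:
    """Train a binary logistic model per phoneme with SGD + L2 penalty.

    ``Y`` is (n_phonemes, n_rows) in {-1, +1}, columns aligned with the
    design rows.  Phonemes whose training labels are single-class are
    skipped with a warning.  Averaged SGD iterates with a fixed maximum
    of ``max_epochs`` epochs and loss tolerance ``tol``.
    """
    from sklearn.linear_model import SGDClassifier

    Y = np.asarray(Y)
    if Y.shape[1] != design.matrix.shape[0]:
        raise ValueError("phoneme frames do not match design rows")
    model = LogisticPhonemeModel(
        labels=list(labels),
        lags_ms=design.lags_ms,
        rate=design.rate,
        n_sensors=design.n_sensors,
    )
    for i, lab in enumerate(labels):
        y = Y[i]
        if np.unique(y).size < 2:
            warnings.warn(f"phoneme {lab!r} has single-class labels; skipped", RuntimeWarning)
            model.skipped.append(lab)
            continue
        clf = SGDClassifier(
            loss="log_loss",
            penalty="l2",
            alpha=alpha,
            max_iter=max_epochs,
            tol=tol,
            average=True,
            random_state=seed + i,
        )
        clf.fit(design.matrix, y)
        model.coefs[lab] = (clf.coef_[0].copy(), float(clf.intercept_[0]))
    return model


def predict_phonemes(
    model: LogisticPhonemeModel,
    response: np.ndarray,
    n_frames: int,
    onset: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict per-frame phoneme activity (+1 iff p > 0.5, strictly).

    Returns (activity, probabilities), each (n_phonemes, n_frames);
    skipped phonemes get probability 0.5 and activity -1.
    """
    response = np.asarray(response, dtype=float)
    if model.n_sensors is not None and response.shape[0] != model.n_sensors:
        raise ValueError("sensor layout mismatch")
    X = lag_matrix(response, model.lags_ms, model.rate, n_frames, onset)
    probs = np.full((len(model.labels), n_frames), 0.5)
    for i, lab in enumerate(model.labels):
        if lab not in model.coefs:
            continue
        w, b = model.coefs[lab]
        z = X @ w + b
        probs[i] = 1.0 / (1.0 + np.exp(-z))
    activity = np.where(probs > 0.5, 1.0, -1.0)
    return activity, probs
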