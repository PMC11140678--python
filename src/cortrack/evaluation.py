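"""Leave-two-out pairwise evaluation of stimulus reconstruction.

Every unordered pair of stimuli is held out once (C(n, 2) splits; 946
for 44 stimuli); the decoder is trained on the remainder and both
held-out stimuli are reconstructed.  A pair counts as correct when the
correctly-matched similarity sum beats the swapped matching,

    sim(s1, p1) + sim(s2, p2) > sim(s1, p2) + sim(s2, p1),

where ``sim`` is Pearson correlation over the flattened feature cells
and the two test items are first truncated to the shorter item's
length.  Exact ties score 0.5.  Accuracy is the percentage of correct
pairs.

The heavy lifting lives in :class:`PairwiseEngine`, which precomputes
one lagged design block per response and down-dates the normal
equations per split instead of refitting from raw data; the result is
algebraically identical to an explicit refit (a property covered by the
test suite).  Following the original analysis, features and responses
are standardized across *all* stimuli before cross-validation; a strict
mode that restricts standardization to the training fold is available
for leakage sensitivity checks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .containers import EvokedSet
from .decoders import DEFAULT_PENALTY_GRID, lag_matrix
from .features import standardize_responses, standardize_time_varying

__all__ = [
    "PairwiseOutcome",
    "DecodingAccuracy",
    "PairwiseEngine",
    "enumerate_splits",
    "equalize_pair_lengths",
    "classify_pair",
    "run_cv",
    "loo_reconstruction",
    "estimate_snr",
]


def enumerate_splits(n_stimuli: int) -> list[tuple[int, int]]:
    """All leave-two-out splits: every unordered stimulus pair."""
    if n_stimuli < 3:
        raise ValueError("need at least 3 stimuli")
    return list(itertools.combinations(range(n_stimuli), 2))


def equalize_pair_lengths(f1: np.ndarray, f2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Truncate two time-varying features to the shorter length (from onset)."""
    f1 = np.atleast_2d(f1)
    f2 = np.atleast_2d(f2)
    if f1.shape[-1] == 0 or f2.shape[-1] == 0:
        raise ValueError("zero-length feature")
    L = min(f1.shape[-1], f2.shape[-1])
    return f1[..., :L], f2[..., :L]


def _pearson_flat(a: np.ndarray, b: np.ndarray, warn: bool = True) -> float:
    """Pearson correlation over flattened cells; 0 if either side is constant."""
    a = np.ravel(a).astype(float)
    b = np.ravel(b).astype(float)
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        if warn:
            warnings.warn("zero-variance vector in similarity; set to 0", RuntimeWarning)
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


@dataclass
class PairwiseOutcome:
    """One leave-two-out pairwise decision and its similarity terms."""

    pair: tuple
    correct: float  # 1 correct, 0 incorrect, 0.5 tie/failed fold
    sims: tuple = (0.0, 0.0, 0.0, 0.0)  # (s1p1, s2p2, s1p2, s2p1)


@dataclass
class DecodingAccuracy:
    """Pairwise decoding accuracy for one participant/model/lag window."""

    accuracy: float  # percent correct over all pairs
    n_pairs: int
    outcomes: list = field(default_factory=list)
    lags_ms: np.ndarray | None = None
    participant_id: str = ""
    model_id: str = ""
    reconstructions: dict | None = None
    lambdas: np.ndarray | None = None  # penalty per channel, when shared


def classify_pair(
    s1: np.ndarray, s2: np.ndarray, p1: np.ndarray, p2: np.ndarray, pair=(0, 1)
) -> PairwiseOutcome:
    """Score one held-out pair by the summed-correlation criterion."""
    sims = (
        _pearson_flat(s1, p1),
        _pearson_flat(s2, p2),
        _pearson_flat(s1, p2),
        _pearson_flat(s2, p1),
    )
    matched = sims[0] + sims[1]
    swapped = sims[2] + sims[3]
    if matched > swapped:
        correct = 1.0
    elif matched < swapped:
        correct = 0.0
    else:
        correct = 0.5
    return PairwiseOutcome(pair, correct, sims)


def _as_channel_arrays(features) -> list[np.ndarray]:
    return [np.atleast_2d(np.asarray(f, dtype=float)) for f in features]


class PairwiseEngine:
    """Shared state for repeated leave-two-out evaluations.

    Builds the standardized features, standardized responses, and one
    full-length lagged design block per response once, so that label
    permutations, lag-window subsets, and leave-one/two-out folds reuse
    them.  Folds are solved by down-dating the pooled normal equations
    ``(R'R, R'S)`` with the held-out stimulus blocks, which is exact.
    """

    def __init__(
        self,
        evoked: EvokedSet,
        features,
        lags_ms,
        grid=DEFAULT_PENALTY_GRID,
        lambda_mode: str = "per-split",
        standardize: bool = True,
    ):
        if lambda_mode not in ("per-split", "once"):
            raise ValueError("lambda_mode must be 'per-split' or 'once'")
        feats = _as_channel_arrays(features)
        if len(feats) != evoked.n_stimuli:
            raise ValueError("feature count does not match evoked stimuli")
        data = evoked.data
        if standardize:
            feats, _ = standardize_time_varying(feats)
            feats = _as_channel_arrays(feats)
            data, _ = standardize_responses(data)
        self.feats = feats
        self.lengths = np.array([f.shape[1] for f in feats])
        self.lags_ms = np.asarray(lags_ms, dtype=float)
        self.grid = grid
        self.lambda_mode = lambda_mode
        self.n_channels = feats[0].shape[0]
        max_t = int(self.lengths.max())
        self.blocks_full = [
            lag_matrix(data[m], self.lags_ms, evoked.rate, max_t, evoked.onset)
            for m in range(evoked.n_stimuli)
        ]
        self.n_stimuli = evoked.n_stimuli
        self.D = self.blocks_full[0].shape[1]

    def _paired_blocks(self, permutation=None) -> list[np.ndarray]:
        """Design block per stimulus under an optional label permutation.

        ``permutation[n]`` is the index of the response assigned to the
        features of stimulus ``n``; rows are cut to that stimulus's
        feature length.
        """
        if permutation is None:
            permutation = np.arange(self.n_stimuli)
        return [
            self.blocks_full[int(permutation[n])][: self.lengths[n]]
            for n in range(self.n_stimuli)
        ]

    def _normal_equations(self, blocks):
        A_n = np.stack([B.T @ B for B in blocks])
        b_n = np.stack([B.T @ self.feats[n].T for n, B in enumerate(blocks)])
        return A_n, b_n

    def _select_lambda_once(self, A_n, b_n, blocks) -> np.ndarray:
        """Penalty per channel by leave-one-stimulus-out on the full set."""
        A, b = A_n.sum(axis=0), b_n.sum(axis=0)
        eye = np.eye(self.D)
        lambdas = np.empty(self.n_channels)
        for f in range(self.n_channels):
            errors = np.full(len(self.grid), np.inf)
            for gi, lam in enumerate(self.grid):
                err = 0.0
                try:
                    for n, B in enumerate(blocks):
                        w = scipy.linalg.solve(
                            A - A_n[n] + lam * eye,
                            b[:, f] - b_n[n, :, f],
                            assume_a="pos",
                        )
                        err += float(((B @ w - self.feats[n][f]) ** 2).sum())
                except scipy.linalg.LinAlgError:
                    continue
                errors[gi] = err
            lambdas[f] = self.grid[int(np.argmin(errors))]
        return lambdas

    def _select_lambda_split(self, A_n, b_n, blocks, train) -> np.ndarray:
        """Per-channel penalty by LOO within one training fold."""
        A = A_n[train].sum(axis=0)
        b = b_n[train].sum(axis=0)
        eye = np.eye(self.D)
        lambdas = np.empty(self.n_channels)
        for f in range(self.n_channels):
            errors = np.full(len(self.grid), np.inf)
            for gi, lam in enumerate(self.grid):
                err = 0.0
                try:
                    for n in train:
                        w = scipy.linalg.solve(
                            A - A_n[n] + lam * eye,
                            b[:, f] - b_n[n, :, f],
                            assume_a="pos",
                        )
                        err += float(((blocks[n] @ w - self.feats[n][f]) ** 2).sum())
                except scipy.linalg.LinAlgError:
                    continue
                errors[gi] = err
            lambdas[f] = self.grid[int(np.argmin(errors))]
        return lambdas

    def accuracy(
        self,
        permutation=None,
        lambdas=None,
        return_reconstructions: bool = False,
        participant_id: str = "",
        model_id: str = "",
    ) -> DecodingAccuracy:
        """Full leave-two-out pairwise evaluation."""
        blocks = self._paired_blocks(permutation)
        A_n, b_n = self._normal_equations(blocks)
        A, b = A_n.sum(axis=0), b_n.sum(axis=0)
        splits = enumerate_splits(self.n_stimuli)
        if lambdas is not None:
            lambdas = np.broadcast_to(np.asarray(lambdas, float), (self.n_channels,))
        elif self.lambda_mode == "once":
            lambdas = self._select_lambda_once(A_n, b_n, blocks)

        outcomes: list[PairwiseOutcome] = []
        recon: dict | None = {} if return_reconstructions else None
        eye = np.eye(self.D)
        all_idx = np.arange(self.n_stimuli)
        if lambdas is not None:
            # batched solve per unique penalty
            W_all = self._batched_split_weights(A_n, b_n, A, b, splits, lambdas)
            for k, (i, j) in enumerate(splits):
                outcomes.append(self._score_pair(blocks, (i, j), W_all[k], recon))
        else:
            for i, j in splits:
                train = np.setdiff1d(all_idx, [i, j], assume_unique=True)
                try:
                    lam_split = self._select_lambda_split(A_n, b_n, blocks, train)
                    A_tr = A - A_n[i] - A_n[j]
                    b_tr = b - b_n[i] - b_n[j]
                    W = np.empty((self.D, self.n_channels))
                    for lam in np.unique(lam_split):
                        cols = np.flatnonzero(lam_split == lam)
                        W[:, cols] = scipy.linalg.solve(
                            A_tr + lam * eye, b_tr[:, cols], assume_a="pos"
                        )
                except scipy.linalg.LinAlgError:
                    warnings.warn(f"fold {(i, j)} failed; scored as tie", RuntimeWarning)
                    outcomes.append(PairwiseOutcome((i, j), 0.5))
                    continue
                outcomes.append(self._score_pair(blocks, (i, j), W, recon))
        acc = 100.0 * float(np.mean([o.correct for o in outcomes]))
        return DecodingAccuracy(
            acc,
            len(splits),
            outcomes,
            self.lags_ms,
            participant_id,
            model_id,
            recon,
            np.asarray(lambdas, float) if lambdas is not None else None,
        )

    def _batched_split_weights(self, A_n, b_n, A, b, splits, lambdas):
        """Solve all split systems in memory-bounded batches."""
        ii = np.array([s[0] for s in splits])
        jj = np.array([s[1] for s in splits])
        n_splits = len(splits)
        W_all = np.empty((n_splits, self.D, self.n_channels))
        chunk = max(1, int(2e8 / (self.D * self.D * 8)))
        eye = np.eye(self.D)
        for start in range(0, n_splits, chunk):
            sl = slice(start, min(start + chunk, n_splits))
            A_tr = A[None] - A_n[ii[sl]] - A_n[jj[sl]]
            b_tr = b[None] - b_n[ii[sl]] - b_n[jj[sl]]
            for lam in np.unique(lambdas):
                cols = np.flatnonzero(lambdas == lam)
                try:
                    W_all[sl][..., cols] = np.linalg.solve(
                        A_tr + lam * eye, b_tr[..., cols]
                    )
                except np.linalg.LinAlgError:
                    # fall back to per-split solves; failures become ties
                    for k in range(sl.start, sl.stop):
                        try:
                            W_all[k][:, cols] = scipy.linalg.solve(
                                A - A_n[ii[k]] - A_n[jj[k]] + lam * eye,
                                (b - b_n[ii[k]] - b_n[jj[k]])[:, cols],
                                assume_a="pos",
                            )
                        except scipy.linalg.LinAlgError:
                            W_all[k][:, cols] = np.nan
        return W_all

    def _score_pair(self, blocks, pair, W, recon) -> PairwiseOutcome:
        i, j = pair
        if not np.all(np.isfinite(W)):
            warnings.warn(f"fold {pair} failed; scored as tie", RuntimeWarning)
            return PairwiseOutcome(pair, 0.5)
        L = int(min(self.lengths[i], self.lengths[j]))
        p1 = (blocks[i][:L] @ W).T  # (n_channels, L)
        p2 = (blocks[j][:L] @ W).T
        s1, s2 = self.feats[i][:, :L], self.feats[j][:, :L]
        if recon is not None:
            recon[pair] = (p1, p2)
        return classify_pair(s1, s2, p1, p2, pair)

    def loo_correlations(self, permutation=None, lambdas=None) -> np.ndarray:
        """Leave-one-out reconstruction correlation per stimulus."""
        blocks = self._paired_blocks(permutation)
        A_n, b_n = self._normal_equations(blocks)
        A, b = A_n.sum(axis=0), b_n.sum(axis=0)
        if lambdas is not None:
            lambdas = np.broadcast_to(np.asarray(lambdas, float), (self.n_channels,))
        else:
            lambdas = self._select_lambda_once(A_n, b_n, blocks)
        eye = np.eye(self.D)
        r = np.empty(self.n_stimuli)
        for n in range(self.n_stimuli):
            W = np.empty((self.D, self.n_channels))
            for lam in np.unique(lambdas):
                cols = np.flatnonzero(lambdas == lam)
                W[:, cols] = scipy.linalg.solve(
                    A - A_n[n] + lam * eye, (b - b_n[n])[:, cols], assume_a="pos"
                )
            pred = (blocks[n] @ W).T
            r[n] = _pearson_flat(self.feats[n], pred)
        return r

    def lag_subset(self, lag_indices) -> "PairwiseEngine":
        """Cheap engine over a subset of the lag axis (shared blocks)."""
        lag_indices = np.asarray(lag_indices, dtype=int)
        n_sensors = self.D // len(self.lags_ms)
        cols = (lag_indices[:, None] * n_sensors + np.arange(n_sensors)[None]).ravel()
        sub = object.__new__(PairwiseEngine)
        sub.feats = self.feats
        sub.lengths = self.lengths
        sub.lags_ms = self.lags_ms[lag_indices]
        sub.grid = self.grid
        sub.lambda_mode = self.lambda_mode
        sub.n_channels = self.n_channels
        sub.blocks_full = [B[:, cols] for B in self.blocks_full]
        sub.n_stimuli = self.n_stimuli
        sub.D = cols.size
        return sub


def run_cv(
    evoked: EvokedSet,
    features,
    lags_ms,
    grid=DEFAULT_PENALTY_GRID,
    lambda_mode: str = "per-split",
    lambdas=None,
    permutation=None,
    standardize=True,
    return_reconstructions: bool = False,
    participant_id: str = "",
    model_id: str = "convolution",
) -> DecodingAccuracy:
    """Leave-two-out pairwise decoding accuracy for one participant.

    ``features`` is one (n_channels, n_frames) array per stimulus (a
    1-D array is treated as a single channel, e.g. the envelope).
    ``lambda_mode='per-split'`` reselects the ridge penalty within every
    training fold; ``'once'`` selects it once on the full set, which is
    much faster and nearly always picks the same grid point.
    ``standardize`` is True (across all stimuli, replicating the
    original analysis), False (raw inputs), or ``"train-only"`` — a
    strict mode that recomputes standardization statistics on each
    training fold only, for leakage sensitivity checks (slower).
    """
    if standardize == "train-only":
        return _run_cv_strict(
            evoked, features, lags_ms, grid, lambdas, participant_id, model_id
        )
    eng = PairwiseEngine(evoked, features, lags_ms, grid, lambda_mode, standardize)
    return eng.accuracy(
        permutation, lambdas, return_reconstructions, participant_id, model_id
    )


def _run_cv_strict(
    evoked: EvokedSet,
    features,
    lags_ms,
    grid=DEFAULT_PENALTY_GRID,
    lambdas=None,
    participant_id: str = "",
    model_id: str = "convolution",
) -> DecodingAccuracy:
    """Leave-two-out evaluation with training-fold-only standardization.

    Refits standardization and the design from scratch per split, so it
    is exact but slow; intended for small leakage sensitivity checks.
    """
    from .decoders import loo_lambda_select, ridge_fit

    feats_raw = _as_channel_arrays(features)
    n = evoked.n_stimuli
    lengths = [f.shape[1] for f in feats_raw]
    lags_ms = np.asarray(lags_ms, dtype=float)
    outcomes = []
    for i, j in enumerate_splits(n):
        train = [k for k in range(n) if k not in (i, j)]
        _, fstate = standardize_time_varying([feats_raw[k] for k in train])
        feats = [fstate.apply(f) for f in feats_raw]
        _, rstate = standardize_responses(evoked.data[train])
        data = rstate.apply(evoked.data)
        blocks = [
            lag_matrix(data[k], lags_ms, evoked.rate, lengths[k], evoked.onset)
            for k in range(n)
        ]
        R = np.concatenate([blocks[k] for k in train])
        S = np.concatenate([feats[k].T for k in train])
        owner = np.concatenate([np.full(lengths[k], k) for k in train])
        if lambdas is None:
            lam, _ = loo_lambda_select(R, S, owner, grid)
        else:
            lam = float(np.asarray(lambdas).ravel()[0])
        W = ridge_fit(R, S, lam)
        L = min(lengths[i], lengths[j])
        p1 = (blocks[i][:L] @ W).T
        p2 = (blocks[j][:L] @ W).T
        outcomes.append(
            classify_pair(feats[i][:, :L], feats[j][:, :L], p1, p2, (i, j))
        )
    acc = 100.0 * float(np.mean([o.correct for o in outcomes]))
    return DecodingAccuracy(
        acc, len(outcomes), outcomes, lags_ms, participant_id, model_id
    )


def loo_reconstruction(
    evoked: EvokedSet,
    features,
    lags_ms,
    grid=DEFAULT_PENALTY_GRID,
    lambdas=None,
    standardize: bool = True,
) -> np.ndarray:
    """Leave-one-out Pearson correlation per stimulus."""
    eng = PairwiseEngine(evoked, features, lags_ms, grid, "once", standardize)
    return eng.loo_correlations(lambdas=lambdas)


def estimate_snr(evoked: EvokedSet, stimulus_window: int | None = None) -> float:
    """Evoked-response SNR from baseline-normalized signal intensity.

    Each sensor's response to each stimulus is z-scored with its own
    baseline mean and sd; the SNR is the RMS of the z-scored signal
    during stimulus presentation divided by the baseline variance of the
    z-scored signal (unity by construction), averaged over sensors and
    stimuli.  Pure noise therefore yields SNR near 1.
    """
    if evoked.onset < 2:
        raise ValueError("no baseline window before stimulus onset")
    base = evoked.data[:, :, : evoked.onset]
    end = evoked.n_times if stimulus_window is None else evoked.onset + stimulus_window
    post = evoked.data[:, :, evoked.onset : end]
    mu = base.mean(axis=2, keepdims=True)
    sd = base.std(axis=2, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero baseline variance")
    z_post = (post - mu) / sd
    z_base = (base - mu) / sd
    base_var = z_base.var(axis=2)  # = 1 per (stimulus, sensor)
    rms = np.sqrt((z_post**2).mean(axis=2))
    return float((rms / base_var).mean())
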