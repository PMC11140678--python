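"""Significance and group statistics for lag-resolved decoding.

Three layers: per-participant label-permutation nulls for the pairwise
decoding accuracy (chance is ~50%; the empirical 95th percentile of the
null acts as the significance threshold), independent-samples t tests
with Benjamini-Hochberg FDR across models, and a cluster-based
permutation test over the 20 non-overlapping 20-ms lag windows
(20-40 ... 400-420 ms) that compares the largest contiguous
supra-threshold cluster's t-statistic mass against a group-relabeling
null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import EvokedSet
from .decoders import DEFAULT_PENALTY_GRID
from .evaluation import PairwiseEngine

__all__ = [
    "PermutationNull",
    "LagSweepCurve",
    "GroupComparison",
    "ClusterTestResult",
    "permute_labels",
    "permutation_test",
    "lag_sweep",
    "default_lag_windows",
    "group_compare",
    "cluster_permutation",
]


@dataclass
class PermutationNull:
    """Observed accuracy against its label-permutation null.

    ``threshold`` is the interpolated 95th percentile of the null;
    ``significance_level`` is the operational alpha = 0.05 level: the
    smallest accuracy value above which the exceedance p-value
    (count of null accuracies strictly greater, over n) drops below
    alpha.  On a fine accuracy grid the two coincide; on coarse grids
    (few pairwise tests) the significance level respects the grid.
    """

    observed: float
    null: np.ndarray
    p_value: float
    threshold: float  # 95th percentile of the null
    significance_level: float  # alpha = 0.05 exceedance level
    n_permutations: int
    add_one: bool = False


def significance_level(null: np.ndarray, alpha: float = 0.05) -> float:
    """Smallest accuracy whose exceedance probability under the null is
    below ``alpha``: performance above this level has p < alpha."""
    for v in np.unique(null):
        if np.mean(null > v) < alpha:
            return float(v)
    return float(np.max(null))


@dataclass
class LagSweepCurve:
    """Decoding accuracy per non-overlapping 20 ms lag window."""

    windows_ms: np.ndarray  # (n_windows, 2) [start, stop)
    accuracy: np.ndarray
    participant_id: str = ""


@dataclass
class GroupComparison:
    """Per-comparison group t tests with FDR and effect sizes."""

    t: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray
    cohen_d: np.ndarray
    df: float


@dataclass
class ClusterTestResult:
    """Largest-cluster mass permutation test over lag windows."""

    t_values: np.ndarray
    clusters: list = field(default_factory=list)  # index arrays
    cluster_masses: np.ndarray = field(default_factory=lambda: np.empty(0))
    largest_cluster: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    observed_mass: float = 0.0
    null_masses: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_value: float = 1.0
    t_threshold: float = np.inf


def permute_labels(
    n_stimuli: int,
    rng: np.random.Generator,
    classes=None,
) -> np.ndarray:
    """Random response-label permutation, restricted within classes.

    ``classes`` assigns each stimulus to a class (e.g. spoken word vs
    environmental sound); labels are only shuffled among stimuli of the
    same class.
    """
    perm = np.arange(n_stimuli)
    if classes is None:
        classes = np.zeros(n_stimuli)
    classes = np.asarray(classes)
    for c in np.unique(classes):
        ix = np.flatnonzero(classes == c)
        perm[ix] = ix[rng.permutation(ix.size)]
    return perm


def permutation_test(
    evoked: EvokedSet,
    features,
    lags_ms,
    n_permutations: int = 200,
    classes=None,
    seed: int = 0,
    grid=DEFAULT_PENALTY_GRID,
    lambda_mode: str = "once",
    refit_lambda: bool = True,
    add_one: bool = False,
    standardize: bool = True,
) -> PermutationNull:
    """Label-permutation significance of pairwise decoding accuracy.

    Each permutation reassigns the evoked responses to the stimulus
    features (within ``classes``) and reruns the complete leave-two-out
    evaluation.  The p-value counts null accuracies at or above the
    observed one; with ``add_one`` the (count+1)/(n+1) convention is
    used instead.  ``refit_lambda=False`` reuses the observed penalty
    for all permutations (fast mode); by default the penalty is
    reselected per permutation.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    eng = PairwiseEngine(evoked, features, lags_ms, grid, lambda_mode, standardize)
    observed = eng.accuracy()
    fixed = observed.lambdas if not refit_lambda else None
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        perm = permute_labels(eng.n_stimuli, rng, classes)
        null[k] = eng.accuracy(permutation=perm, lambdas=fixed).accuracy
    count = int(np.sum(null >= observed.accuracy))
    p = (count + 1) / (n_permutations + 1) if add_one else count / n_permutations
    return PermutationNull(
        observed.accuracy,
        null,
        float(p),
        float(np.percentile(null, 95)),
        significance_level(null),
        n_permutations,
        add_one,
    )


def default_lag_windows(
    start_ms: float = 20.0, stop_ms: float = 420.0, width_ms: float = 20.0
) -> np.ndarray:
    """Non-overlapping [start, stop) lag windows: 20-40, ..., 400-420 ms."""
    starts = np.arange(start_ms, stop_ms, width_ms)
    return np.column_stack([starts, starts + width_ms])


def lag_sweep(
    evoked: EvokedSet,
    features,
    windows_ms: np.ndarray | None = None,
    grid=DEFAULT_PENALTY_GRID,
    lambda_mode: str = "once",
    lambdas=None,
    standardize: bool = True,
    rate_step_ms: float = 10.0,
    participant_id: str = "",
) -> LagSweepCurve:
    """Decoding accuracy in a moving non-overlapping 20 ms lag window.

    One full leave-two-out evaluation per window; windows are half-open
    ``[start, stop)`` so each 10 ms lag sample belongs to exactly one
    window.  The lagged design spanning all windows is built once and
    each window reuses its column subset.
    """
    if windows_ms is None:
        windows_ms = default_lag_windows()
    windows_ms = np.asarray(windows_ms, dtype=float)
    lo, hi = windows_ms.min(), windows_ms.max()
    all_lags = np.arange(lo, hi, rate_step_ms)  # half-open: hi excluded
    eng = PairwiseEngine(evoked, features, all_lags, grid, lambda_mode, standardize)
    acc = np.empty(len(windows_ms))
    for k, (w0, w1) in enumerate(windows_ms):
        idx = np.flatnonzero((all_lags >= w0 - 1e-9) & (all_lags < w1 - 1e-9))
        acc[k] = eng.lag_subset(idx).accuracy(lambdas=lambdas).accuracy
    return LagSweepCurve(windows_ms, acc, participant_id)


def _cohen_d(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n1, n2 = a.shape[0], b.shape[0]
    s1 = a.var(axis=0, ddof=1)
    s2 = b.var(axis=0, ddof=1)
    sp = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (a.mean(axis=0) - b.mean(axis=0)) / sp
    return np.where(sp == 0, np.where(a.mean(0) == b.mean(0), 0.0, np.nan), d)


def group_compare(
    group1: np.ndarray,
    group2: np.ndarray,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> GroupComparison:
    """Independent-samples t tests between groups with BH-FDR correction.

    ``group1``/``group2`` are (n_participants, n_comparisons) arrays
    (accuracies per model or per lag window).  The pooled-variance
    Student t is the default (df = n1 + n2 - 2); Welch is available via
    ``equal_var=False``.  Cohen's d uses the pooled sd.  Comparisons
    with zero variance in both groups yield NaN and are excluded from
    the FDR step.
    """
    g1 = np.atleast_2d(np.asarray(group1, dtype=float).T).T
    g2 = np.atleast_2d(np.asarray(group2, dtype=float).T).T
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("each group needs at least 2 participants")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = scipy.stats.ttest_ind(g1, g2, axis=0, equal_var=equal_var)
    zero = (g1.var(axis=0) == 0) & (g2.var(axis=0) == 0)
    same = zero & (g1.mean(axis=0) == g2.mean(axis=0))
    t = np.where(same, 0.0, t)
    p = np.where(same, 1.0, p)
    p_fdr = np.full_like(p, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        sig[ok], p_fdr[ok], _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
    df = g1.shape[0] + g2.shape[0] - 2 if equal_var else np.nan
    return GroupComparison(t, p, p_fdr, sig, _cohen_d(g1, g2), float(df))


def _pooled_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched pooled-variance Student t along axis 1.

    ``a``/``b`` are (n_batches, n_i, m); returns (n_batches, m).
    Matches ``scipy.stats.ttest_ind(equal_var=True)``.
    """
    n1, n2 = a.shape[1], b.shape[1]
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a.mean(axis=1) - b.mean(axis=1)) / (sp * np.sqrt(1 / n1 + 1 / n2))


def _contiguous_clusters(mask: np.ndarray) -> list[np.ndarray]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    return np.split(idx, breaks + 1)


def _largest_cluster_mass(
    t: np.ndarray, t_crit: float, tail: str
) -> tuple[float, np.ndarray, list, np.ndarray]:
    """Clusters of contiguous same-sign supra-threshold lags."""
    clusters: list[np.ndarray] = []
    if tail in ("two", "greater"):
        clusters += _contiguous_clusters(t > t_crit)
    if tail == "two":
        clusters += _contiguous_clusters(t < -t_crit)
    if not clusters:
        return 0.0, np.empty(0, int), [], np.empty(0)
    masses = np.array([t[c].sum() for c in clusters])
    best = int(np.argmax(np.abs(masses)))
    return float(masses[best]), clusters[best], clusters, masses


def cluster_permutation(
    group1: np.ndarray,
    group2: np.ndarray,
    alpha_cluster: float = 0.05,
    n_permutations: int = 1000,
    tail: str = "two",
    seed: int = 0,
) -> ClusterTestResult:
    """Cluster-based permutation test of group differences over lags.

    Per lag, an independent-samples (pooled) t test compares the two
    groups' accuracy curves; contiguous lags exceeding the
    ``alpha_cluster`` t threshold form clusters whose mass is the sum of
    their t statistics.  The largest observed cluster's |mass| is
    compared against the null obtained by randomly reassigning
    participants to two groups of the original sizes and re-applying the
    same largest-cluster rule; p = N(null mass > observed) / N.
    With no observed cluster the p-value is 1.
    """
    if n_permutations < 500:
        raise ValueError("need at least 500 permutations")
    if tail not in ("two", "greater"):
        raise ValueError("tail must be 'two' or 'greater'")
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    n1, n2 = g1.shape[0], g2.shape[0]
    df = n1 + n2 - 2
    if tail == "two":
        t_crit = scipy.stats.t.ppf(1 - alpha_cluster / 2, df)
    else:
        t_crit = scipy.stats.t.ppf(1 - alpha_cluster, df)

    t_obs = _pooled_t(g1[None], g2[None])[0]
    obs_mass, obs_cluster, clusters, masses = _largest_cluster_mass(t_obs, t_crit, tail)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([g1, g2], axis=0)
    # all relabelings at once: random orderings via argsort of uniform keys
    order = np.argsort(rng.random((n_permutations, n1 + n2)), axis=1)
    t_null = _pooled_t(pooled[order[:, :n1]], pooled[order[:, n1:]])
    null = np.array(
        [abs(_largest_cluster_mass(t_null[k], t_crit, tail)[0]) for k in range(n_permutations)]
    )
    if obs_cluster.size == 0:
        p = 1.0
    else:
        p = float(np.sum(null > abs(obs_mass)) / n_permutations)
    return ClusterTestResult(
        t_values=t_obs,
        clusters=clusters,
        cluster_masses=masses,
        largest_cluster=obs_cluster,
        observed_mass=obs_mass,
        null_masses=null,
        p_value=p,
        t_threshold=float(t_crit),
    )
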