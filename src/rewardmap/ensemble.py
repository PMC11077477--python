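"""Population-level ensemble analyses.

Covers the motor / nonmotor split of neurons against binarized locomotion,
the pairwise-synchrony connectivity index, consumption-state clustering with
NMF / t-SNE embeddings, pre-vs-post activation and variance contrasts, and
tensor component analysis (TCA): a nonnegative CP decomposition of a
trial x neuron x time activity tensor into neuron loadings, within-trial time
factors, and across-trial factors, with trend and state-contrast statistics.

The nonnegative CP solver is a HALS (hierarchical alternating least squares)
implementation with multi-restart seeding; factors are column-normalized with
the scale absorbed into the trial axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF, PCA
from sklearn.manifold import TSNE

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

SYNC_R_THRESHOLD = 0.3
MOTOR_PCC_GRID = (0.20, 0.25, 0.30, 0.35, 0.40)
MOTOR_MAX_LAG = 10
MOTOR_FALLBACK_THRESHOLD = 0.30


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MotorLabels:
    labels: np.ndarray       # 'motor' / 'nonmotor' per neuron
    best_lag: np.ndarray     # signed frames, |lag| in [1, MOTOR_MAX_LAG];
                             # positive = activity follows movement
    pcc: np.ndarray          # PCC at the best lag
    threshold: float
    threshold_fallback: bool = False


@dataclass
class ConnectivitySeries:
    counts: np.ndarray       # synchronized-pair count per segment
    index: np.ndarray        # counts / baseline count
    baseline_segment: int


@dataclass
class StateMap:
    labels: np.ndarray
    nmf_coords: np.ndarray
    tsne_coords: np.ndarray
    k: int
    seed: int


@dataclass
class TCAResult:
    rank: int
    neuron_factors: np.ndarray   # neurons x rank, >= 0, unit columns
    time_factors: np.ndarray     # time x rank, >= 0, unit columns
    trial_factors: np.ndarray    # trials x rank, >= 0, carries the scale
    rel_error: float
    seed: int
    restarts: int


@dataclass
class TrendStats:
    slopes: np.ndarray           # OLS slope of each trial factor on trial index
    slope_pvalues: np.ndarray
    contributing: np.ndarray     # bool per neuron: (state1 - state2) loading > 0
    contrast_pvalue: float       # paired Wilcoxon, first vs last session
    contrast_sessions: tuple = (0, 0)


# ---------------------------------------------------------------------------
# motor classification
# ---------------------------------------------------------------------------

def binarize_movement(velocity: np.ndarray, threshold: float) -> np.ndarray:
    """Binary moving/not-moving flags: velocity > threshold."""
    if threshold < 0:
        raise InvalidInputError("movement threshold must be >= 0")
    velocity = np.asarray(velocity, dtype=float)
    if not np.all(np.isfinite(velocity)):
        raise InvalidInputError("velocity must be finite")
    return velocity > threshold


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def classify_motor(
    traces: np.ndarray,
    movement: np.ndarray,
    thresholds: tuple[float, ...] = MOTOR_PCC_GRID,
    max_lag: int = MOTOR_MAX_LAG,
    alpha: float = 0.05,
) -> MotorLabels:
    """Split neurons into motor / nonmotor against a binary movement vector.

    Per neuron the lagged Pearson correlation with the movement vector is
    evaluated for lags -max_lag..-1, 1..max_lag (positive lag: activity
    follows movement, the physiological indicator delay; negative: activity
    leads, premotor); the lag maximizing |PCC| is kept.  A neuron is
    motor-associated iff |PCC| at its best lag exceeds the threshold.  The
    symmetric search makes labels invariant under joint time reversal of
    traces and movement.

    The threshold is picked from ``thresholds`` (ascending) as the smallest
    value at which the motor group's mean activity during moving frames
    significantly exceeds non-moving frames (one-sided Wilcoxon signed-rank,
    p < alpha) while the nonmotor group's does not.  If no grid value
    qualifies, the 0.30 midpoint is used and flagged.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    movement = np.asarray(movement, dtype=bool)
    if traces.shape[1] != movement.shape[0]:
        raise InvalidInputError("trace length != movement length")
    if movement.all() or not movement.any():
        raise InvalidInputError("movement vector is constant; PCC undefined")
    if movement.sum() < 20 or (~movement).sum() < 20:
        raise InvalidInputError("need >= 20 moving and >= 20 non-moving frames")

    n = traces.shape[0]
    mov = movement.astype(float)
    lags = [l for l in range(-max_lag, max_lag + 1) if l != 0]

    def aligned(x, y_bool, lag):
        # positive lag: activity at t pairs with movement at t - lag
        if lag > 0:
            return x[lag:], y_bool[: len(y_bool) - lag]
        return x[: len(x) + lag], y_bool[-lag:]

    best_lag = np.zeros(n, dtype=int)
    pcc = np.zeros(n)
    move_diff = np.zeros(n)  # mean activity moving - non-moving, lag-aligned
    for i in range(n):
        rs = [_pearson(*aligned(traces[i], mov, lag)) for lag in lags]
        j = int(np.argmax(np.abs(rs)))
        best_lag[i] = lags[j]
        pcc[i] = rs[j]
        tr, mv = aligned(traces[i], movement, best_lag[i])
        move_diff[i] = tr[mv].mean() - tr[~mv].mean()

    def group_p(diffs: np.ndarray) -> float:
        diffs = diffs[diffs != 0]
        if diffs.size < 3:
            return 1.0
        return float(stats.wilcoxon(diffs, alternative="greater").pvalue)

    chosen, fallback = None, False
    for t in sorted(thresholds):
        is_motor = np.abs(pcc) > t
        p_motor = group_p(move_diff[is_motor])
        p_non = group_p(move_diff[~is_motor])
        if p_motor < alpha and p_non >= alpha:
            chosen = t
            break
    if chosen is None:
        chosen, fallback = MOTOR_FALLBACK_THRESHOLD, True
        logger.warning("no grid threshold satisfied the movement criterion; "
                       "falling back to %.2f", chosen)
    labels = np.where(np.abs(pcc) > chosen, "motor", "nonmotor")
    return MotorLabels(labels, best_lag, pcc, float(chosen), fallback)


# ---------------------------------------------------------------------------
# connectivity index
# ---------------------------------------------------------------------------

def count_synchronized_pairs(segment: np.ndarray,
                             r_threshold: float = SYNC_R_THRESHOLD) -> int:
    """Unordered neuron pairs whose activity correlation exceeds r_threshold."""
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    if segment.shape[0] < 2:
        raise InvalidInputError("need >= 2 neurons")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(segment)
    iu = np.triu_indices(segment.shape[0], k=1)
    vals = r[iu]
    return int(np.sum(vals[np.isfinite(vals)] > r_threshold))


def connectivity_index(
    segments: list[np.ndarray],
    baseline_index: int = 0,
    r_threshold: float = SYNC_R_THRESHOLD,
    baseline_pseudocount: bool = False,
) -> ConnectivitySeries:
    """Synchronized-pair counts per segment, normalized by the baseline count.

    The baseline segment (pre-injection) defines the denominator.  A zero
    baseline count is an error unless ``baseline_pseudocount`` substitutes
    count + 1 in both numerator and denominator (logged).
    """
    if not 0 <= baseline_index < len(segments):
        raise InvalidInputError("baseline segment index out of range")
    counts = np.array(
        [count_synchronized_pairs(s, r_threshold) for s in segments], dtype=float
    )
    base = counts[baseline_index]
    if base == 0:
        if not baseline_pseudocount:
            raise InvalidInputError(
                "baseline has zero synchronized pairs; "
                "enable baseline_pseudocount to proceed"
            )
        logger.warning("zero baseline pair count; applying +1 pseudocount")
        index = (counts + 1) / (base + 1)
    else:
        index = counts / base
    return ConnectivitySeries(counts.astype(int), index, baseline_index)


# ---------------------------------------------------------------------------
# consumption states
# ---------------------------------------------------------------------------

def cluster_states(traces: np.ndarray, k: int, seed: int = 0,
                   perplexity: float = 30.0) -> StateMap:
    """k-means states over per-neuron consumption traces, plus 2-D embeddings.

    NMF requires nonnegative input; traces with negative entries are shifted
    by their global minimum first (logged).  Embeddings are visualization aids
    and deterministic under a fixed seed.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n = traces.shape[0]
    if k < 2:
        raise InvalidInputError("k must be >= 2")
    if n < k:
        raise InvalidInputError("fewer neurons than clusters")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(traces)

    X = traces
    if X.min() < 0:
        logger.info("shifting traces by %.4f for NMF nonnegativity", -X.min())
        X = X - X.min()
    nmf = NMF(n_components=2, init="nndsvda", random_state=seed, max_iter=1000)
    nmf_coords = nmf.fit_transform(X)

    perp = min(perplexity, max(1.0, (n - 1) / 3.0))
    tsne_coords = TSNE(
        n_components=2, random_state=seed, perplexity=perp, init="pca"
    ).fit_transform(traces)
    return StateMap(km.labels_, nmf_coords, tsne_coords, k, seed)


# ---------------------------------------------------------------------------
# pre/post contrasts
# ---------------------------------------------------------------------------

def activation_contrast(pre, post):
    """Fisher's exact comparison of activated fractions in two epochs.

    ``pre`` / ``post`` may be ActivationCall objects or ``(activated, total)``
    pairs.  Returns (percentages, odds_ratio, p).  The odds ratio is NaN when
    undefined (a zero cell in both margins).
    """
    def as_pair(x):
        if hasattr(x, "activated"):
            return int(x.activated.sum()), int(len(x.activated))
        k, n = x
        return int(k), int(n)

    a, n1 = as_pair(pre)
    b, n2 = as_pair(post)
    if n1 == 0 or n2 == 0:
        raise InvalidInputError("zero-size epoch")
    table = np.array([[a, n1 - a], [b, n2 - b]])
    res = stats.fisher_exact(table, alternative="two-sided")
    odds = res.statistic
    if not np.isfinite(odds):
        odds = float("nan")
    pct = (100.0 * a / n1, 100.0 * b / n2)
    return pct, float(odds), float(res.pvalue)


def variance_top_pcs(traces: np.ndarray, n_pcs: int = 3) -> float:
    """Fraction of variance captured by the top principal components.

    PCA over the neuron x time matrix with neurons as observations
    (mean-centered features); returns sum of the top ``n_pcs`` explained
    variance ratios.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] < n_pcs + 1 or traces.shape[1] < n_pcs + 1:
        raise InvalidInputError(f"need more than {n_pcs} neurons and time points")
    if np.ptp(traces) == 0:
        raise InvalidInputError("constant matrix has no variance to explain")
    pca = PCA(n_components=n_pcs).fit(traces)
    return float(pca.explained_variance_ratio_.sum())


# ---------------------------------------------------------------------------
# tensor component analysis
# ---------------------------------------------------------------------------

def _unfold(X: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)


def _khatri_rao(mats: list[np.ndarray]) -> np.ndarray:
    out = mats[0]
    for m in mats[1:]:
        out = (out[:, None, :] * m[None, :, :]).reshape(-1, out.shape[1])
    return out


def _cp_reconstruct(factors: list[np.ndarray]) -> np.ndarray:
    A, B, C = factors
    return np.einsum("ir,jr,kr->ijk", A, B, C)


def _nncp_hals(X: np.ndarray, rank: int, rng: np.random.Generator,
               n_iter: int = 300, tol: float = 1e-10) -> tuple[list[np.ndarray], float]:
    """Nonnegative CP by HALS column updates; returns factors and rel. error."""
    norm_x = np.linalg.norm(X)
    scale = (X.mean() / max(rank, 1)) ** (1 / 3) if X.mean() > 0 else 1.0
    factors = [rng.uniform(0.1, 1.0, (s, rank)) * scale for s in X.shape]
    prev = np.inf
    for _ in range(n_iter):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            kr = _khatri_rao(others)  # slow/fast ordering matches _unfold
            G = (others[0].T @ others[0]) * (others[1].T @ others[1])
            M = _unfold(X, mode) @ kr
            A = factors[mode]
            for j in range(rank):
                g = G[j, j]
                if g < 1e-12:
                    A[:, j] = rng.uniform(0, 1e-3, A.shape[0])
                    continue
                col = A[:, j] + (M[:, j] - A @ G[:, j]) / g
                A[:, j] = np.maximum(col, 0.0)
        err = np.linalg.norm(X - _cp_reconstruct(factors)) / max(norm_x, 1e-30)
        if prev - err < tol:
            break
        prev = err
    return factors, float(err)


def tca_fit(tensor: np.ndarray, rank: int, restarts: int = 10,
            seed: int = 0, n_iter: int = 300) -> TCAResult:
    """Nonnegative CP decomposition of a trials x neurons x time tensor.

    Runs ``restarts`` seeded HALS initializations and keeps the best fit by
    relative reconstruction error.  Neuron and time factor columns are
    normalized to unit L2 norm, with the scale absorbed into the trial
    factors.  Negative tensor entries are clipped to 0 (logged).
    """
    X = np.asarray(tensor, dtype=float)
    if X.ndim != 3:
        raise InvalidInputError("tensor must be 3-way (trials x neurons x time)")
    if X.shape[0] < 2:
        raise InvalidInputError("need >= 2 trials")
    if rank < 1 or rank > min(X.shape):
        raise InvalidInputError(f"rank must be in [1, {min(X.shape)}]")
    if X.min() < 0:
        logger.info("clipping %.3g%% negative tensor entries to 0",
                    100.0 * np.mean(X < 0))
        X = np.clip(X, 0.0, None)

    ss = np.random.SeedSequence([seed, X.shape[0], X.shape[1]])
    best: tuple[float, list[np.ndarray]] | None = None
    for child in ss.spawn(restarts):
        factors, err = _nncp_hals(X, rank, np.random.default_rng(child), n_iter)
        if best is None or err < best[0]:
            best = (err, factors)
    err, (A, B, C) = best  # trials, neurons, time
    nb = np.linalg.norm(B, axis=0)
    nc = np.linalg.norm(C, axis=0)
    nb[nb == 0] = 1.0
    nc[nc == 0] = 1.0
    B = B / nb
    C = C / nc
    A = A * nb * nc
    # deterministic component order: by total trial-factor energy, descending
    order = np.argsort(-A.sum(axis=0), kind="stable")
    return TCAResult(rank, B[:, order], C[:, order], A[:, order],
                     float(err), seed, restarts)


def factor_congruence(result: TCAResult, true_factors: list[np.ndarray]) -> float:
    """Mean congruence with planted factors after optimal component matching.

    Congruence of a component pair is the product over the three modes of the
    cosine similarity between estimated and true factor columns; components
    are matched by maximizing total congruence (Hungarian assignment).
    """
    est = [result.trial_factors, result.neuron_factors, result.time_factors]
    if len(true_factors) != 3:
        raise InvalidInputError("expected factors for 3 modes")
    r_est = result.rank
    r_true = true_factors[0].shape[1]
    sim = np.ones((r_est, r_true))
    for e_mat, t_mat in zip(est, true_factors):
        en = e_mat / np.maximum(np.linalg.norm(e_mat, axis=0), 1e-30)
        tn = t_mat / np.maximum(np.linalg.norm(t_mat, axis=0), 1e-30)
        sim *= en.T @ tn
    rows, cols = linear_sum_assignment(-sim)
    return float(sim[rows, cols].mean())


def tca_trend_and_contrast(
    result: TCAResult,
    session_labels: np.ndarray | None = None,
    tensor: np.ndarray | None = None,
    states: tuple[int, int] = (0, 1),
) -> TrendStats:
    """Across-trial trend of each state plus the state-1-vs-2 neuron contrast.

    Per component, an OLS regression of the trial-factor values on trial index
    gives the slope and its p-value.  Neurons positively contributing to
    state ``states[0]`` relative to ``states[1]`` are those with a strictly
    positive loading difference; if ``tensor`` and ``session_labels`` are
    given, their per-neuron mean responses in the first and last sessions are
    compared with a paired two-sided Wilcoxon signed-rank test.
    """
    A = result.trial_factors
    if A.shape[0] < 3:
        raise InvalidInputError("need >= 3 trials for a trend")
    idx = np.arange(A.shape[0])
    slopes, pvals = [], []
    for j in range(result.rank):
        fit = stats.linregress(idx, A[:, j])
        slopes.append(fit.slope)
        pvals.append(fit.pvalue)

    if result.rank < 2:
        raise InvalidInputError("state contrast requires rank >= 2")
    s1, s2 = states
    diff = result.neuron_factors[:, s1] - result.neuron_factors[:, s2]
    contributing = diff > 0

    contrast_p = float("nan")
    sessions = (0, 0)
    if tensor is not None and session_labels is not None:
        labels = np.asarray(session_labels)
        if labels.shape[0] != A.shape[0]:
            raise InvalidInputError("session_labels length != number of trials")
        uniq = sorted(set(labels.tolist()))
        first, last = uniq[0], uniq[-1]
        sessions = (first, last)
        X = np.asarray(tensor, dtype=float)
        resp_first = X[labels == first][:, contributing, :].mean(axis=(0, 2))
        resp_last = X[labels == last][:, contributing, :].mean(axis=(0, 2))
        d = resp_last - resp_first
        if np.count_nonzero(d) >= 3:
            contrast_p = float(stats.wilcoxon(d[d != 0]).pvalue)
        else:
            contrast_p = 1.0
    return TrendStats(np.array(slopes), np.array(pvals), contributing,
                      contrast_p, sessions)
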