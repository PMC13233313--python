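"""Stroke and image dissimilarity metrics and categorical-structure tests.

Two metrics carry most of the behavioural analyses:

* **Trajectory distance** — a [0, 1) dissimilarity between strokes that
  ignores location and size but keeps the spatiotemporal trajectory.  Each
  stroke is rescaled so its bounding-box diagonal is 1, resampled to N = 70
  points equally spaced in cumulative arc length, and converted to a velocity
  series.  The distance is a regularized dynamic-time-warping cost between
  the two velocity series, squashed to [0, 1) by D = 1 - 1/(D_DTW + 1).

* **Image distance** — a modified Hausdorff distance between two point sets,
  using means instead of minima/maxima so single outlier points do not
  dominate.  Each set is centred on its own centre of mass first, making the
  metric translation-invariant.

On top of these, the primitive alignment score a = d1/(d1 + d2) measures the
relative similarity of one trial to two reference primitive trial sets
(0 = P1-like, 1 = P2-like), and the hallmark tests quantify categorical
(as opposed to tracing-like) behaviour across morph sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import wilcoxon

from .stroke_processing import Stroke, differentiate_five_point

N_TRAJECTORY_POINTS = 70
LAMBDA_COEFF = 0.045

# morph-set condition labels, in morph-fraction order
CONDITIONS = ("P1", "U1", "A", "U2", "P2")


@dataclass
class TrajectoryDistanceParams:
    """Parameters of the trajectory distance.

    lambda_coeff scales the warping penalty; it multiplies the mean absolute
    velocity of the two strokes being compared so the penalty lives on the
    same scale as the velocity mismatch term.
    """

    lambda_coeff: float = LAMBDA_COEFF
    n_points: int = N_TRAJECTORY_POINTS

    def __post_init__(self) -> None:
        if self.lambda_coeff < 0:
            raise ValueError("lambda_coeff must be >= 0")


@dataclass
class TrajectoryVector:
    """Velocity series of a normalized, arc-length-resampled stroke."""

    velocity: np.ndarray            # (n_points, 2)
    positions: np.ndarray | None = None  # the resampled, rescaled positions

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 2 or self.velocity.shape[1] != 2:
            raise ValueError("velocity must be (n, 2)")


@dataclass
class AlignmentScore:
    """Relative similarity of one datum to two reference trial sets."""

    a: float
    d1: float
    d2: float
    metric_tag: str = "trajectory"
    degenerate: bool = False


def _as_positions(stroke) -> np.ndarray:
    if isinstance(stroke, Stroke):
        return stroke.positions
    pts = np.asarray(stroke, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) position array or a Stroke")
    return pts


def resample_by_arc_length(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to n points equally spaced in cumulative distance."""
    seg = np.hypot(*np.diff(points, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate stroke: zero path length")
    target = np.linspace(0.0, total, n)
    x = np.interp(target, s, points[:, 0])
    y = np.interp(target, s, points[:, 1])
    return np.column_stack([x, y])


def normalize_stroke(stroke, params: TrajectoryDistanceParams | None = None) -> TrajectoryVector:
    """Normalize a stroke to a 70-point trajectory vector.

    Steps: rescale so the bounding-box diagonal is 1 (aspect ratio kept),
    resample to n equally spaced points along cumulative arc length, then
    differentiate the resampled series with the five-point stencil.  The
    resampled stroke is treated as spanning unit duration (sample step
    1/(n-1)), so velocities are in bounding-box diagonals per stroke and the
    metric is fully scale- and timing-free.
    """
    params = params or TrajectoryDistanceParams()
    pts = _as_positions(stroke)
    if pts.shape[0] < 2:
        raise ValueError("stroke needs at least 2 points")
    span = pts.max(axis=0) - pts.min(axis=0)
    diag = float(np.hypot(*span))
    if diag <= 0:
        raise ValueError("degenerate stroke: zero bounding box")
    res = resample_by_arc_length(pts / diag, params.n_points)
    span = res.max(axis=0) - res.min(axis=0)
    res = res / float(np.hypot(*span))   # unit diagonal of the resampled points
    h = 1.0 / (params.n_points - 1)
    vx = differentiate_five_point(res[:, 0], h)
    vy = differentiate_five_point(res[:, 1], h)
    return TrajectoryVector(np.column_stack([vx, vy]), positions=res)


def _dtw_cost_py(local: np.ndarray) -> float:
    """Min-cost monotone path from (0,0) to (N-1,M-1), steps right/down/diag."""
    n, m = local.shape
    acc = np.empty((n, m))
    acc[0, 0] = local[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + local[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + local[i, 0]
        for j in range(1, m):
            best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            if acc[i - 1, j - 1] < best:
                best = acc[i - 1, j - 1]
            acc[i, j] = local[i, j] + best
    return float(acc[n - 1, m - 1])


try:  # numba gives ~100x on the DP inner loop; plain numpy fallback otherwise
    from numba import njit as _njit

    _dtw_cost = _njit(cache=True)(_dtw_cost_py)
except ImportError:  # pragma: no cover
    _dtw_cost = _dtw_cost_py


def trajectory_distance(v1, v2, params: TrajectoryDistanceParams | None = None) -> float:
    """Regularized-DTW trajectory distance in [0, 1).

    The local cost is d(i, j) = |v1[i] - v2[j]| + lambda |i - j| with
    lambda = lambda_coeff x the mean per-sample velocity norm of both inputs,
    the path cost is divided by N, and the result is squashed by
    D = 1 - 1/(D_DTW + 1).  Symmetric; 0 iff the velocity series coincide.
    """
    params = params or TrajectoryDistanceParams()
    a = v1.velocity if isinstance(v1, TrajectoryVector) else np.asarray(v1, float)
    b = v2.velocity if isinstance(v2, TrajectoryVector) else np.asarray(v2, float)
    if a.shape != b.shape:
        raise ValueError("velocity series must have equal length")
    n = a.shape[0]
    speed = 0.5 * (np.linalg.norm(a, axis=1).mean() + np.linalg.norm(b, axis=1).mean())
    lam = params.lambda_coeff * speed
    diff = a[:, None, :] - b[None, :, :]
    local = np.linalg.norm(diff, axis=2)
    idx = np.arange(n)
    local = local + lam * np.abs(idx[:, None] - idx[None, :])
    d_dtw = _dtw_cost(local) / n
    return 1.0 - 1.0 / (d_dtw + 1.0)


def stroke_distance(s1, s2, params: TrajectoryDistanceParams | None = None) -> float:
    """Trajectory distance between two raw strokes (normalizes both first)."""
    return trajectory_distance(normalize_stroke(s1, params),
                               normalize_stroke(s2, params), params)


def pairwise_distance_matrix(items, labels=None, metric: str = "trajectory",
                             params: TrajectoryDistanceParams | None = None):
    """Square labelled distance matrix over trials (CSV-ready DataFrame)."""
    import pandas as pd

    n = len(items)
    if metric == "trajectory":
        vecs = [x if isinstance(x, TrajectoryVector) else normalize_stroke(x, params)
                for x in items]
        dist = lambda i, j: trajectory_distance(vecs[i], vecs[j], params)
    elif metric == "image":
        dist = lambda i, j: image_distance(items[i], items[j])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = dist(i, j)
    labels = labels if labels is not None else list(range(n))
    return pd.DataFrame(M, index=labels, columns=labels)


def centre_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    return pts - pts.mean(axis=0)


def image_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Modified Hausdorff distance between two point sets, px.

    Both sets are centred on their own centre of mass; the directed distance
    d(A, B) is the mean over points of A of the distance to the nearest point
    of B, and the image distance averages the two directions.
    """
    if np.size(a) == 0 or np.size(b) == 0:
        raise ValueError("point sets must be non-empty")
    a = centre_points(a)
    b = centre_points(b)
    d_ab = cKDTree(b).query(a)[0].mean()
    d_ba = cKDTree(a).query(b)[0].mean()
    return float(0.5 * (d_ab + d_ba))


def _mean_distance(datum, refs, metric: str,
                   params: TrajectoryDistanceParams | None) -> float:
    ds = []
    for ref in refs:
        if metric == "trajectory":
            if not isinstance(datum, TrajectoryVector):
                datum = normalize_stroke(datum, params)
            r = ref if isinstance(ref, TrajectoryVector) else normalize_stroke(ref, params)
            ds.append(trajectory_distance(datum, r, params))
        elif metric == "image":
            ds.append(image_distance(datum, ref))
        elif metric == "euclidean":
            ds.append(float(np.linalg.norm(np.asarray(datum, float) - np.asarray(ref, float))))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return float(np.mean(ds))


def primitive_alignment(trial_datum, ref_p1, ref_p2, metric: str = "trajectory",
                        params: TrajectoryDistanceParams | None = None) -> AlignmentScore:
    """Alignment a = d1/(d1 + d2) of one datum to two reference trial sets.

    metric selects trajectory distance (strokes), image distance (point
    sets) or plain Euclidean distance (e.g. population activity vectors).
    If d1 + d2 = 0 the score is returned as 0.5 with a degenerate flag.
    """
    if len(ref_p1) == 0 or len(ref_p2) == 0:
        raise ValueError("reference sets must be non-empty")
    d1 = _mean_distance(trial_datum, ref_p1, metric, params)
    d2 = _mean_distance(trial_datum, ref_p2, metric, params)
    if d1 + d2 == 0:
        return AlignmentScore(0.5, d1, d2, metric, degenerate=True)
    return AlignmentScore(d1 / (d1 + d2), d1, d2, metric)


def find_category_boundary(alignments_by_level: dict,
                           low: float = 0.35, high: float = 0.65):
    """Locate the morph level with trial-by-trial switching between primitives.

    A level qualifies when its trial alignments are bimodal (contains scores
    both below `low` and above `high`).  Among qualifying levels the one whose
    mean alignment is closest to 0.5 wins; ties break toward the level with
    the larger minority class.  Returns the level key, or None when no level
    qualifies (downstream analyses then omit the ambiguous conditions).
    """
    best = None
    best_key = None
    for level, scores in alignments_by_level.items():
        a = np.asarray(scores, dtype=float)
        if a.size < 2:
            continue
        n_lo, n_hi = int((a < low).sum()), int((a > high).sum())
        if n_lo == 0 or n_hi == 0:
            continue
        dist = abs(a.mean() - 0.5)
        minority = min(n_lo, n_hi)
        key = (dist, -minority)
        if best is None or key < best:
            best = key
            best_key = level
    return best_key


def label_morph_conditions(levels, boundary_level) -> dict:
    """Map morph levels to P1/U1/A/U2/P2 given the boundary level.

    Endpoints (min/max fraction) are the practised primitives; the boundary
    level is ambiguous (A); remaining levels are unambiguous on their side.
    """
    levels = sorted(levels)
    lo, hi = levels[0], levels[-1]
    out = {}
    for lv in levels:
        if lv == lo:
            out[lv] = "P1"
        elif lv == hi:
            out[lv] = "P2"
        elif boundary_level is not None and lv == boundary_level:
            out[lv] = "A"
        elif boundary_level is not None and lv < boundary_level:
            out[lv] = "U1"
        elif boundary_level is not None:
            out[lv] = "U2"
        else:
            out[lv] = "U1" if lv < 0.5 * (lo + hi) else "U2"
    return out


@dataclass
class HallmarkResult:
    """Categorical-structure hallmark statistics across morph sets.

    nonlinearity: per-set (image - drawing) at U1 plus (drawing - image) at
    U2; positive values mean the drawing alignment profile is sigmoidal
    relative to the linear image profile.  switching: per-set A2 - A1
    drawing-alignment difference; positive values mean trials at the boundary
    morph split into two distinct primitive classes.
    """

    nonlinearity_effects: np.ndarray
    switching_effects: np.ndarray
    nonlinearity_W: float
    nonlinearity_p: float
    switching_W: float
    switching_p: float
    low_power: bool


def categorical_structure_test(per_set_stats: list[dict]) -> HallmarkResult:
    """Test the two categorical hallmarks across morph sets.

    Each element of per_set_stats describes one morph set with keys
    ``drawing`` and ``image`` (dicts condition -> mean alignment, conditions
    among P1/U1/A/U2/P2) and optionally ``A1``/``A2`` (mean drawing or neural
    alignment of boundary trials split by the drawn primitive).  Uses
    one-sided Wilcoxon signed-rank tests on the per-set effects.
    """
    nonlin, switch = [], []
    for st in per_set_stats:
        dr, im = st["drawing"], st["image"]
        if "U1" in dr and "U2" in dr:
            nonlin.append((im["U1"] - dr["U1"]) + (dr["U2"] - im["U2"]))
        if "A1" in st and "A2" in st:
            switch.append(st["A2"] - st["A1"])
    nonlin = np.asarray(nonlin, float)
    switch = np.asarray(switch, float)

    def _signed_rank(x):
        # W reported as the sum of ranks of negative effects (0 when every
        # morph set shows the hallmark); p from a one-sided signed-rank test.
        nz = x[x != 0]
        if nz.size == 0:
            return 0.0, 1.0
        from scipy.stats import rankdata
        ranks = rankdata(np.abs(nz))
        w_neg = float(ranks[nz < 0].sum())
        p = float(wilcoxon(nz, alternative="greater").pvalue)
        return w_neg, p

    w1, p1 = _signed_rank(nonlin)
    w2, p2 = _signed_rank(switch)
    return HallmarkResult(nonlin, switch, w1, p1, w2, p2,
                          low_power=len(per_set_stats) < 5)
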