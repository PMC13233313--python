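"""Primitive templates, stroke classification and the remixed-primitive null.

A subject's repertoire is summarized as one mean trajectory per primitive
(averaged over single-shape trials) plus a per-primitive match threshold
D_max, the 97.5th percentile of within-primitive trajectory distances.  A
character stroke is assigned its best-matching primitive p* = argmin_p
d(s, mu_p) and the match is high quality iff d(s, mu_p*) < D_max,p*.

The remixed-primitive control splices the first half of one primitive (by
distance travelled) onto the second half of another with a sigmoidal blend,
then filters out implausible curves (self-intersection, sharp turns) and
enforces set-level distinctness constraints, providing a null repertoire
that is matched in low-level statistics but was never actually drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .stroke_processing import Stroke
from .trajectory_metrics import (TrajectoryDistanceParams, TrajectoryVector,
                                 normalize_stroke, resample_by_arc_length,
                                 trajectory_distance)

MATCH_PERCENTILE = 97.5
# the sharp-turn bound is in 1/px at the standard rendered shape size: a
# point of curvature 0.8/px has a radius below ~1.3 px, i.e. a splice kink
CURVATURE_BOUND = 0.8
CURVATURE_SCALE_PX = 135.0
CURVATURE_INNER_FRACTION = 0.8
BLEND_ARC_FRACTION = 0.10
DEGENERATE_FLOOR_FACTOR = 0.05


@dataclass
class PrimitiveTemplate:
    primitive_id: str
    mean_vector: TrajectoryVector     # trial-averaged trajectory vector
    mean_positions: np.ndarray        # normalized mean position trajectory
    d_max: float                      # 97.5th-percentile match threshold
    n_source_trials: int
    degenerate_threshold: bool = False


@dataclass
class PrimitiveTemplateSet:
    templates: list[PrimitiveTemplate]
    params: TrajectoryDistanceParams = field(default_factory=TrajectoryDistanceParams)

    @property
    def ids(self) -> list[str]:
        return [t.primitive_id for t in self.templates]

    def __getitem__(self, primitive_id: str) -> PrimitiveTemplate:
        for t in self.templates:
            if t.primitive_id == primitive_id:
                return t
        raise KeyError(primitive_id)


@dataclass
class StrokeClassification:
    stroke_id: int
    best_primitive: str
    distance: float
    quality: str        # "high" | "low"


def _to_vector(stroke, params) -> TrajectoryVector:
    if isinstance(stroke, TrajectoryVector):
        return stroke
    return normalize_stroke(stroke, params)


def fit_primitive_templates(trials_by_primitive: dict,
                            params: TrajectoryDistanceParams | None = None,
                            min_trials: int = 5) -> PrimitiveTemplateSet:
    """Fit mean trajectories and match thresholds from single-shape trials.

    trials_by_primitive maps a primitive label to its list of strokes (or
    trajectory vectors).  D_max_p is the 97.5th percentile of the source
    trials' distances to mu_p; when all trials are identical that percentile
    collapses to ~0 and the threshold is floored at a small fraction of the
    cross-primitive nearest distance, with a flag raised.
    """
    params = params or TrajectoryDistanceParams()
    templates: list[PrimitiveTemplate] = []
    per_prim_vectors: dict[str, list[TrajectoryVector]] = {}
    for pid, trials in trials_by_primitive.items():
        if len(trials) < min_trials:
            raise ValueError(f"primitive {pid!r} has fewer than {min_trials} trials")
        per_prim_vectors[pid] = [_to_vector(s, params) for s in trials]

    for pid, vecs in per_prim_vectors.items():
        mean_vel = np.mean([v.velocity for v in vecs], axis=0)
        pos = [v.positions for v in vecs if v.positions is not None]
        mean_pos = np.mean(pos, axis=0) if pos else None
        mu = TrajectoryVector(mean_vel, positions=mean_pos)
        dists = [trajectory_distance(v, mu, params) for v in vecs]
        d_max = float(np.percentile(dists, MATCH_PERCENTILE))
        templates.append(PrimitiveTemplate(pid, mu, mean_pos, d_max, len(vecs)))

    # degenerate-threshold floor from cross-primitive nearest distances
    if len(templates) >= 2:
        nearest = []
        for t in templates:
            others = [trajectory_distance(t.mean_vector, o.mean_vector, params)
                      for o in templates if o is not t]
            nearest.append(min(others))
        floor = DEGENERATE_FLOOR_FACTOR * float(np.percentile(nearest, MATCH_PERCENTILE))
        for t in templates:
            if t.d_max < floor:
                t.d_max = floor
                t.degenerate_threshold = True
    return PrimitiveTemplateSet(templates, params)


def classify_stroke(stroke, templates: PrimitiveTemplateSet,
                    stroke_id: int = 0) -> StrokeClassification:
    """Assign a stroke its best-matching primitive and a match quality.

    Ties in distance break toward the lowest template index.
    """
    v = _to_vector(stroke, templates.params)
    dists = np.array([trajectory_distance(v, t.mean_vector, templates.params)
                      for t in templates.templates])
    best = int(np.argmin(dists))
    t = templates.templates[best]
    quality = "high" if dists[best] < t.d_max else "low"
    return StrokeClassification(stroke_id, t.primitive_id, float(dists[best]), quality)


# ---------------------------------------------------------------------------
# curvature and remixing
# ---------------------------------------------------------------------------

def curvature(stroke) -> np.ndarray:
    """Signed curvature kappa = (x'y'' - y'x'') / (x'^2 + y'^2)^(3/2).

    Accepts a Stroke with velocity series or an (n, 2) position polyline
    (derivatives then taken with respect to the sample index).  Samples with
    zero speed are masked to NaN.
    """
    if isinstance(stroke, Stroke) and stroke.vx is not None:
        dx, dy = stroke.vx, stroke.vy
        ddx, ddy = np.gradient(dx), np.gradient(dy)
    else:
        pts = stroke.positions if isinstance(stroke, Stroke) else np.asarray(stroke, float)
        dx, dy = np.gradient(pts[:, 0]), np.gradient(pts[:, 1])
        ddx, ddy = np.gradient(dx), np.gradient(dy)
    speed_sq = dx**2 + dy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        k = (dx * ddy - dy * ddx) / speed_sq**1.5
    k[speed_sq == 0] = np.nan
    return k


def _self_intersects(points: np.ndarray, adjacency_window: int = 2) -> bool:
    """Any non-adjacent segment pair of the polyline intersects."""
    p = points[:-1]
    q = points[1:]
    n = len(p)
    for i in range(n):
        for j in range(i + adjacency_window + 1, n):
            if _segments_cross(p[i], q[i], p[j], q[j]):
                return True
    return False


def _segments_cross(a, b, c, d) -> bool:
    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
    o1, o2 = orient(a, b, c), orient(a, b, d)
    o3, o4 = orient(c, d, a), orient(c, d, b)
    return (o1 * o2 < 0) and (o3 * o4 < 0)


@dataclass
class RemixedPrimitive:
    remix_id: str
    first_donor: str
    second_donor: str
    curve: np.ndarray                 # blended normalized positions
    vector: TrajectoryVector
    inherited_threshold: float | None = None


def _split_half(curve: np.ndarray, which: str) -> np.ndarray:
    seg = np.hypot(*np.diff(curve, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    half = np.searchsorted(s, 0.5 * s[-1])
    return curve[:half + 1] if which == "first" else curve[half:]


def _blend_curves(first: np.ndarray, second: np.ndarray,
                  n_points: int, blend_fraction: float = BLEND_ARC_FRACTION) -> np.ndarray:
    """Join halves at the junction with a logistic arc-length blend."""
    second = second - second[0] + first[-1]
    joined = np.vstack([first, second[1:]])
    res = resample_by_arc_length(joined, n_points)
    seg = np.hypot(*np.diff(res, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s = s / s[-1]
    junction = s[np.argmin(np.abs(s - 0.5))]
    w = 1.0 / (1.0 + np.exp(-(s - junction) / (blend_fraction / 4)))
    # smooth transition: blend the joined curve with a locally averaged copy
    sm = res.copy()
    window = max(3, int(blend_fraction * n_points) | 1)
    kernel = np.ones(window) / window
    for k in range(2):
        pad = np.pad(res[:, k], window // 2, mode="edge")
        sm[:, k] = np.convolve(pad, kernel, mode="valid")
    gate = np.exp(-0.5 * ((s - junction) / (blend_fraction / 2))**2)
    return res * (1 - gate[:, None]) + sm * gate[:, None]


def _normalized(curve: np.ndarray) -> np.ndarray:
    span = curve.max(axis=0) - curve.min(axis=0)
    diag = float(np.hypot(*span))
    return (curve - curve[0]) / diag


def generate_remixed_set(templates: PrimitiveTemplateSet, n_remixed: int,
                         seed: int = 0, max_half_reuse: int = 2,
                         curvature_bound: float = CURVATURE_BOUND) -> list[RemixedPrimitive]:
    """Sample a set of remixed primitives satisfying all printed constraints.

    Candidates splice the first half (by distance travelled) of one primitive
    onto the second half of another.  Per-candidate filters: no
    self-intersection; |curvature| on the inner 80% of the (unit-diagonal
    normalized) curve <= 0.8.  Set-level constraints: each donor half used at
    most twice; every remixed-remixed and remixed-actual trajectory distance
    at least the minimum actual-actual distance.
    """
    if len(templates.templates) < 2:
        raise ValueError("need at least 2 actual primitives")
    params = templates.params
    rng = np.random.default_rng(seed)

    actual_vecs = [t.mean_vector for t in templates.templates]
    floor = min(trajectory_distance(a, b, params)
                for i, a in enumerate(actual_vecs)
                for b in actual_vecs[i + 1:])

    # candidate pool: every ordered pair of distinct primitives
    pool = []
    n_pts = params.n_points
    for i, ti in enumerate(templates.templates):
        for j, tj in enumerate(templates.templates):
            if i == j:
                continue
            first = _split_half(ti.mean_positions, "first")
            second = _split_half(tj.mean_positions, "second")
            curve = _normalized(_blend_curves(first, second, n_pts))
            if _self_intersects(curve):
                continue
            # curvature evaluated at the standard rendered size so the px
            # bound applies; unit-diagonal curves would make 0.8 unsatisfiable
            k = curvature(curve * CURVATURE_SCALE_PX)
            lo = int((1 - CURVATURE_INNER_FRACTION) / 2 * len(k))
            inner = k[lo:len(k) - lo]
            if np.nanmax(np.abs(inner)) > curvature_bound:
                continue
            vec = normalize_stroke(curve, params)
            pool.append(RemixedPrimitive(f"remix_{ti.primitive_id}+{tj.primitive_id}",
                                         ti.primitive_id, tj.primitive_id,
                                         curve, vec))
    order = rng.permutation(len(pool))
    chosen: list[RemixedPrimitive] = []
    first_use: dict[str, int] = {}
    second_use: dict[str, int] = {}
    for k in order:
        cand = pool[k]
        if first_use.get(cand.first_donor, 0) >= max_half_reuse:
            continue
        if second_use.get(cand.second_donor, 0) >= max_half_reuse:
            continue
        if any(trajectory_distance(cand.vector, a, params) < floor
               for a in actual_vecs):
            continue
        if any(trajectory_distance(cand.vector, c.vector, params) < floor
               for c in chosen):
            continue
        chosen.append(cand)
        first_use[cand.first_donor] = first_use.get(cand.first_donor, 0) + 1
        second_use[cand.second_donor] = second_use.get(cand.second_donor, 0) + 1
        if len(chosen) == n_remixed:
            return chosen
    raise RuntimeError(f"only {len(chosen)} remixed primitives satisfy the "
                       f"constraints (requested {n_remixed})")


def assign_remixed_thresholds(remixed: list[RemixedPrimitive],
                              templates: PrimitiveTemplateSet,
                              character_strokes) -> None:
    """Inherit actual thresholds onto remixed primitives, leniently.

    The largest (most lenient) actual threshold goes to the remixed primitive
    with the largest average trajectory distance to the character strokes
    (the worst-matching one), the second largest to the second worst, etc.
    """
    params = templates.params
    vecs = [_to_vector(s, params) for s in character_strokes]
    avg = [float(np.mean([trajectory_distance(v, r.vector, params) for v in vecs]))
           for r in remixed]
    thresholds = sorted((t.d_max for t in templates.templates), reverse=True)
    order = np.argsort(avg)[::-1]  # worst-matching first
    for rank, idx in enumerate(order):
        remixed[idx].inherited_threshold = thresholds[min(rank, len(thresholds) - 1)]


def remixed_to_template_set(remixed: list[RemixedPrimitive],
                            params: TrajectoryDistanceParams | None = None) -> PrimitiveTemplateSet:
    """View a remixed set as a classification template set (thresholds assigned)."""
    params = params or TrajectoryDistanceParams()
    temps = []
    for r in remixed:
        if r.inherited_threshold is None:
            raise ValueError("assign thresholds before classification")
        temps.append(PrimitiveTemplate(r.remix_id, r.vector, r.curve,
                                       r.inherited_threshold, 0))
    return PrimitiveTemplateSet(temps, params)


# ---------------------------------------------------------------------------
# reuse analysis and kinematic separability
# ---------------------------------------------------------------------------

def reuse_analysis(character_strokes, template_sets: dict,
                   character_ids=None, n_bootstrap: int = 1000,
                   seed: int = 0) -> dict:
    """Fraction of character strokes matching each primitive set.

    Returns per set: the high-quality match fraction, a percentile bootstrap
    CI (resampling characters), and the per-primitive match frequency table.
    """
    rng = np.random.default_rng(seed)
    if character_ids is None:
        character_ids = np.arange(len(character_strokes))
    character_ids = np.asarray(character_ids)
    out = {}
    for name, tset in template_sets.items():
        cls = [classify_stroke(s, tset, i) for i, s in enumerate(character_strokes)]
        high = np.array([c.quality == "high" for c in cls])
        frac = float(high.mean())
        uniq = np.unique(character_ids)
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            pick = rng.choice(uniq, size=len(uniq), replace=True)
            mask = np.concatenate([np.flatnonzero(character_ids == c) for c in pick])
            boots[b] = high[mask].mean()
        freq = pd.Series([c.best_primitive for c in cls])[high].value_counts()
        out[name] = {
            "match_fraction": frac,
            "ci_low": float(np.percentile(boots, 2.5)),
            "ci_high": float(np.percentile(boots, 97.5)),
            "match_frequency": freq,
            "classifications": cls,
        }
    return out


def _stroke_to_kinematic_vector(stroke, n_time: int = 50) -> np.ndarray:
    """Time-normalized (50 pts), space-normalized (unit bbox diagonal) vector."""
    pts = stroke.positions if isinstance(stroke, Stroke) else np.asarray(stroke, float)
    span = pts.max(axis=0) - pts.min(axis=0)
    diag = float(np.hypot(*span))
    if diag <= 0:
        raise ValueError("degenerate stroke")
    pts = pts / diag
    tau = np.linspace(0, 1, len(pts))
    grid = np.linspace(0, 1, n_time)
    x = np.interp(grid, tau, pts[:, 0])
    y = np.interp(grid, tau, pts[:, 1])
    return np.concatenate([x, y])


def pairwise_kinematic_decoding(strokes, labels, n_components: int = 8,
                                n_folds: int = 10, svc_c: float = 0.1,
                                min_trials: int = 10, seed: int = 0) -> pd.DataFrame:
    """Cross-validated pairwise decoding of primitives from stroke kinematics.

    Strokes are embedded as 100-dim position vectors, reduced to 8 principal
    components, and each primitive pair is decoded with a linear max-margin
    classifier under 10-fold cross-validation.  Returns a symmetric accuracy
    matrix (diagonal NaN); classes with fewer than min_trials are skipped.
    """
    labels = np.asarray(labels)
    X = np.stack([_stroke_to_kinematic_vector(s) for s in strokes])
    keep = [lv for lv in np.unique(labels) if (labels == lv).sum() >= min_trials]
    acc = pd.DataFrame(np.nan, index=keep, columns=keep)
    for i, a in enumerate(keep):
        for b in keep[i + 1:]:
            mask = np.isin(labels, [a, b])
            Xi, yi = X[mask], (labels[mask] == b).astype(int)
            clf = make_pipeline(PCA(n_components=min(n_components, Xi.shape[0] - 1,
                                                     Xi.shape[1])),
                                StandardScaler(),
                                LinearSVC(C=svc_c))
            cv = StratifiedKFold(n_folds, shuffle=True, random_state=seed)
            score = cross_val_score(clf, Xi, yi, cv=cv).mean()
            acc.loc[a, b] = acc.loc[b, a] = float(score)
    return acc


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_templates(path, templates: PrimitiveTemplateSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["lambda_coeff"] = templates.params.lambda_coeff
        f.attrs["n_points"] = templates.params.n_points
        for t in templates.templates:
            g = f.create_group(t.primitive_id)
            g.create_dataset("mean_velocity", data=t.mean_vector.velocity)
            if t.mean_positions is not None:
                g.create_dataset("mean_positions", data=t.mean_positions)
            g.attrs["d_max"] = t.d_max
            g.attrs["n_source_trials"] = t.n_source_trials
            g.attrs["degenerate_threshold"] = t.degenerate_threshold


def load_templates(path) -> PrimitiveTemplateSet:
    with h5py.File(path, "r") as f:
        params = TrajectoryDistanceParams(float(f.attrs["lambda_coeff"]),
                                          int(f.attrs["n_points"]))
        temps = []
        for pid in f:
            g = f[pid]
            pos = g["mean_positions"][:] if "mean_positions" in g else None
            temps.append(PrimitiveTemplate(
                pid, TrajectoryVector(g["mean_velocity"][:], positions=pos), pos,
                float(g.attrs["d_max"]), int(g.attrs["n_source_trials"]),
                bool(g.attrs["degenerate_threshold"])))
    return PrimitiveTemplateSet(temps, params)
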