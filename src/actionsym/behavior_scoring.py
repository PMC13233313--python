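"""Trial scoring and feedback engine for the drawing task.

Performance on each trial is summarized by named factors in three classes:
image similarity (drawing-image overlap and a modified Hausdorff distance),
behavioural efficiency (excess ink), and optional task-specific factors for
practised characters (stroke-count match and stroke-shape spatial
alignment).  Raw factor values are rescaled to [0, 1] against adaptive
bounds tracking the recent trial history, weighted, and aggregated by the
worst weighted factor:

    s_scal = min_i (1 - w_i (1 - f_i))

A categorical score (great/good/OK/fail) then drives four feedback
modalities: screen colour, sound, reward delay and solenoid open duration
(reward = C * m * a * s_scal).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .trajectory_metrics import image_distance
from .primitive_matching import curvature

LOWER_PERCENTILE = 1.0
UPPER_PERCENTILE = 53.0
HISTORY_LENGTH = 50
MIN_HISTORY = 5
EPSILON_WIDTH = 1e-9

CATEGORY_BINS = (("great", 0.82), ("good", 0.65), ("OK", 0.15), ("fail", -np.inf))
CATEGORY_MULTIPLIER = {"great": 1.3, "good": 1.0, "OK": 0.8, "fail": 0.0}
SOUND_CODE = {"great": "triple_1300Hz", "good": "single_1000Hz",
              "OK": "none", "fail": "single_120Hz"}
COLOUR_FAIL = np.array([1.0, 0.2, 0.0])   # red at score 0
COLOUR_GREAT = np.array([0.2, 1.0, 0.2])  # green at score 1

DEFAULT_WEIGHTS = {
    "overlap": 1.0, "hausdorff": 1.0,      # image similarity weighs most
    "efficiency": 0.5,
    "stroke_count": 0.5, "spatial_alignment": 0.5,
}


def categorize(s_scal: float) -> str:
    for name, lo in CATEGORY_BINS:
        if s_scal > lo:
            return name
    return "fail"


# ---------------------------------------------------------------------------
# raw factors
# ---------------------------------------------------------------------------

def _feature_weights(image: np.ndarray, boost: float = 2.0) -> np.ndarray:
    """Up-weight characteristic image points: end points and curvature maxima."""
    w = np.ones(len(image))
    if len(image) >= 5:
        k = np.abs(curvature(image))
        thresh = np.nanpercentile(k, 90)
        w[np.nan_to_num(k) >= thresh] = boost
    w[0] = w[-1] = boost
    return w


def compute_raw_factors(strokes, image: np.ndarray, task_type: str = "single_shape",
                        n_image_shapes: int = 1, touch_margin_px: float = 20.0,
                        segmentation: np.ndarray | None = None) -> dict:
    """Raw (pre-rescaling) factor values for one trial.

    overlap: weighted fraction of image points with a drawn point within the
    touch margin.  hausdorff: negated image distance (larger is better).
    efficiency: -max(0, ink_drawn - ink_image)/ink_image.  For practised
    characters two task factors are added: negated stroke-count mismatch and
    negated mean distance between each drawn stroke and its nearest image
    shape (spatial alignment).
    """
    if len(strokes) == 0:
        raise ValueError("empty drawing")
    image = np.asarray(image, dtype=float)
    drawn = np.vstack([s.positions for s in strokes])

    from scipy.spatial import cKDTree
    tree = cKDTree(drawn)
    d_img = tree.query(image)[0]
    w = _feature_weights(image)
    overlap = float(np.sum(w * (d_img <= touch_margin_px)) / np.sum(w))

    hausdorff = -image_distance(drawn, image)

    ink_drawn = float(sum(s.path_length() for s in strokes))
    seg_img = np.hypot(*np.diff(image, axis=0).T)
    if segmentation is not None:
        seg_img = seg_img[np.diff(segmentation) == 0]  # skip jumps between shapes
    ink_image = float(seg_img.sum())
    efficiency = -max(0.0, ink_drawn - ink_image) / max(ink_image, 1e-9)

    factors = {"overlap": overlap, "hausdorff": hausdorff, "efficiency": efficiency}
    if task_type == "character_practised":
        factors["stroke_count"] = -abs(len(strokes) - n_image_shapes)
        if segmentation is not None:
            align = []
            for s in strokes:
                cents = [image[segmentation == k].mean(axis=0)
                         for k in np.unique(segmentation)]
                c = s.positions.mean(axis=0)
                align.append(min(np.linalg.norm(c - sc) for sc in cents))
            factors["spatial_alignment"] = -float(np.mean(align))
    return factors


# ---------------------------------------------------------------------------
# adaptive rescaling
# ---------------------------------------------------------------------------

@dataclass
class AdaptiveBounds:
    """Per-factor rescaling bounds tracking the last 50 trials.

    The lower bound is the 1st percentile and the upper the 53rd percentile
    of the recent raw values, so the feedback dynamic range follows the
    subject's recent performance.  Needs at least MIN_HISTORY values before
    rescaling engages; degenerate (equal) bounds are widened by epsilon.
    """

    history: dict = field(default_factory=dict)

    def bounds_for(self, factor: str) -> tuple[float, float] | None:
        h = self.history.get(factor)
        if h is None or len(h) < MIN_HISTORY:
            return None
        vals = np.asarray(h)
        lo = float(np.percentile(vals, LOWER_PERCENTILE))
        hi = float(np.percentile(vals, UPPER_PERCENTILE))
        if hi - lo < EPSILON_WIDTH:
            lo -= EPSILON_WIDTH
            hi += EPSILON_WIDTH
        return lo, hi

    def push(self, factor: str, raw: float) -> None:
        self.history.setdefault(factor, deque(maxlen=HISTORY_LENGTH)).append(float(raw))


def update_and_rescale(raw_factors: dict, bounds: AdaptiveBounds) -> dict:
    """Clamp-rescale raw factors to [0, 1] against the adaptive bounds.

    Each raw value is rescaled against the bounds computed from history
    *before* it is appended; trials arriving before MIN_HISTORY values exist
    score a neutral 0.5 for that factor.
    """
    rescaled = {}
    for name, raw in raw_factors.items():
        b = bounds.bounds_for(name)
        if b is None:
            rescaled[name] = 0.5
        else:
            lo, hi = b
            rescaled[name] = float(np.clip((raw - lo) / (hi - lo), 0.0, 1.0))
        bounds.push(name, raw)
    return rescaled


# ---------------------------------------------------------------------------
# aggregation and feedback
# ---------------------------------------------------------------------------

def aggregate_score(factors: dict, weights: dict | None = None) -> tuple[float, str]:
    """Worst weighted factor: s_scal = min_i (1 - w_i (1 - f_i))."""
    if not factors:
        raise ValueError("need at least one factor")
    weights = weights or DEFAULT_WEIGHTS
    s = min(1.0 - weights.get(name, 1.0) * (1.0 - f) for name, f in factors.items())
    return float(s), categorize(s)


@dataclass
class FeedbackResult:
    s_scal: float
    category: str
    screen_colour: np.ndarray
    sound_code: str
    delay_s: float
    reward_s: float


def feedback(s_scal: float, category: str | None = None, C: float = 0.4,
             rng: np.random.Generator | None = None) -> FeedbackResult:
    """Map a trial score to the four feedback modalities.

    reward = C * m * a * s_scal with m the category multiplier
    (great 1.3 / good 1.0 / OK 0.8 / fail 0) and a ~ 0.75 + 0.5 U(0,1).
    The pre-reward delay maps score 0 to 5 s (+ uniform 0-2.5 s jitter) and
    score 1 to 0 s, multiplied by 0.65 unless the trial failed.  Screen
    colour interpolates linearly red (0) to green (1).
    """
    if not 0.15 <= C <= 0.6:
        raise ValueError("reward constant C must lie in [0.15, 0.6]")
    rng = rng or np.random.default_rng()
    category = category or categorize(s_scal)
    a = 0.75 + 0.5 * rng.uniform()
    reward = C * CATEGORY_MULTIPLIER[category] * a * s_scal
    jitter = rng.uniform(0.0, 2.5)
    delay = (5.0 + jitter) * (1.0 - s_scal)
    if category != "fail":
        delay *= 0.65
    colour = COLOUR_FAIL + s_scal * (COLOUR_GREAT - COLOUR_FAIL)
    return FeedbackResult(s_scal, category, colour, SOUND_CODE[category],
                          float(delay), float(reward))


def append_trial_log(path, trial_id: int, result: "FeedbackResult") -> None:
    """Append one scored trial to a CSV trial log (creates it if absent)."""
    import csv
    import os

    exists = os.path.exists(path)
    with open(path, "a", newline="") as f:
        w = csv.writer(f)
        if not exists:
            w.writerow(["trial_id", "s_scal", "category", "reward_s",
                        "delay_s"])
        w.writerow([trial_id, result.s_scal, result.category,
                    result.reward_s, result.delay_s])


def score_trial(strokes, image, bounds: AdaptiveBounds,
                task_type: str = "single_shape", weights: dict | None = None,
                C: float = 0.4, rng: np.random.Generator | None = None,
                **raw_kwargs) -> FeedbackResult:
    """Full scoring pipeline for one trial: factors -> rescale -> aggregate -> feedback."""
    raw = compute_raw_factors(strokes, image, task_type, **raw_kwargs)
    factors = update_and_rescale(raw, bounds)
    s, cat = aggregate_score(factors, weights)
    return feedback(s, cat, C, rng)
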