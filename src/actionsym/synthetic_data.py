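"""Synthetic strokes, morph sets, characters and population activity.

Generates data with the statistical structure the behavioural and neural
analyses assume, so the full pipeline runs without recorded data:

* a library of distinct one-stroke *primitives* (idiosyncratic canonical
  curves), drawn with trial-to-trial jitter and variation in location/size;
* *morph sets* interpolating linearly between two primitives' control
  parameters, with either categorical (switch at a boundary) or tracing
  (continuous) drawing policies;
* multi-stroke *characters* assembled by attaching 2-6 primitives, accepted
  only when shapes cross minimally;
* *population tensors* (trials x units x time) whose units carry
  configurable primitive/location/size/task tuning plus noise.

Canonical curves are clamped cubic B-splines whose control-point coordinates
are the named control parameters, so morphing is literal linear interpolation
of parameters and the curve itself is linear in them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.ndimage import gaussian_filter1d
from shapely.geometry import LineString

from .stroke_processing import Stroke
from .trajectory_metrics import (TrajectoryDistanceParams, normalize_stroke,
                                 resample_by_arc_length, stroke_distance)

N_CONTROL_POINTS = 6
CURVE_SAMPLES = 100
SPLINE_DEGREE = 3
DEFAULT_SHAPE_SIZE_PX = 135.0   # average shape extent on screen, px
STROKE_RATE_HZ = 60.0

CONTROL_SCHEMA = tuple(
    f"ctrl{i}_{ax}" for i in range(N_CONTROL_POINTS) for ax in ("x", "y")
)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _spline_knots(n_ctrl: int, degree: int = SPLINE_DEGREE) -> np.ndarray:
    inner = np.linspace(0, 1, n_ctrl - degree + 1)
    return np.concatenate([np.zeros(degree), inner, np.ones(degree)])


def curve_from_params(control_params: np.ndarray,
                      n_samples: int = CURVE_SAMPLES) -> np.ndarray:
    """Evaluate the clamped B-spline defined by flattened control points.

    The output is normalized to bounding-box diagonal 1 with the start point
    at the origin; consecutive samples are guaranteed distinct.
    """
    ctrl = np.asarray(control_params, dtype=float).reshape(-1, 2)
    knots = _spline_knots(len(ctrl))
    spl = BSpline(knots, ctrl, SPLINE_DEGREE)
    pts = spl(np.linspace(0, 1, n_samples))
    span = pts.max(axis=0) - pts.min(axis=0)
    diag = float(np.hypot(*span))
    if diag <= 0:
        raise ValueError("degenerate control polygon")
    pts = (pts - pts[0]) / diag
    # arc-length resampling also removes any accidental duplicate samples
    return resample_by_arc_length(pts, n_samples)


@dataclass
class PrimitiveSpec:
    """A stroke primitive: named control parameters plus its canonical curve."""

    primitive_id: str
    control_params: np.ndarray          # flattened control points, CONTROL_SCHEMA
    canonical_curve: np.ndarray = field(default=None)  # (n, 2), unit scale
    schema: tuple = CONTROL_SCHEMA

    def __post_init__(self) -> None:
        self.control_params = np.asarray(self.control_params, dtype=float)
        if self.canonical_curve is None:
            self.canonical_curve = curve_from_params(self.control_params)
        if len(self.canonical_curve) < 10:
            raise ValueError("canonical curve needs >= 10 points")
        if np.any(np.all(np.diff(self.canonical_curve, axis=0) == 0, axis=1)):
            raise ValueError("consecutive curve points must be distinct")


def _random_control_params(rng: np.random.Generator) -> np.ndarray:
    """Random-walk control polygon with directional persistence."""
    theta = rng.uniform(0, 2 * np.pi)
    pts = [np.zeros(2)]
    for _ in range(N_CONTROL_POINTS - 1):
        theta += rng.normal(0, 1.2)
        step = rng.uniform(0.5, 1.5)
        pts.append(pts[-1] + step * np.array([np.cos(theta), np.sin(theta)]))
    return np.asarray(pts).ravel()


def make_primitive_library(n_primitives: int, seed: int,
                           distinctness_floor: float = 0.25,
                           max_attempts: int = 2000) -> list[PrimitiveSpec]:
    """Sample distinct primitives (pairwise trajectory distance above floor).

    Deterministic given the seed; raises if the floor cannot be met within
    max_attempts candidate draws.
    """
    if n_primitives < 2:
        raise ValueError("need at least 2 primitives")
    rng = np.random.default_rng(seed)
    params = TrajectoryDistanceParams()
    library: list[PrimitiveSpec] = []
    vectors = []
    for attempt in range(max_attempts):
        cand = PrimitiveSpec(f"prim{len(library)}", _random_control_params(rng))
        v = normalize_stroke(cand.canonical_curve, params)
        from .trajectory_metrics import trajectory_distance
        if all(trajectory_distance(v, u, params) > distinctness_floor
               for u in vectors):
            library.append(cand)
            vectors.append(v)
            if len(library) == n_primitives:
                return library
    raise RuntimeError(
        f"could not draw {n_primitives} primitives above distance floor "
        f"{distinctness_floor} in {max_attempts} attempts")


# ---------------------------------------------------------------------------
# stroke sampling
# ---------------------------------------------------------------------------

@dataclass
class StrokeNoise:
    """Trial-to-trial variability of a drawn stroke.

    jitter_px: s.d. of smooth positional jitter (low-pass-filtered Gaussian);
    jitter_smooth_samples: Gaussian smoothing width of the jitter, in samples;
    duration_sigma: lognormal s.d. of the duration multiplier.
    """

    jitter_px: float = 1.5
    jitter_smooth_samples: float = 4.0
    duration_sigma: float = 0.15


def _minimum_jerk_profile(n: int) -> np.ndarray:
    tau = np.linspace(0, 1, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def place_curve(curve: np.ndarray, location, size: float) -> np.ndarray:
    """Scale a unit curve to `size` px (bounding-box diagonal), centre at location."""
    if size <= 0:
        raise ValueError("size must be positive")
    c = curve - curve.mean(axis=0)
    return np.asarray(location, dtype=float) + size * c


def sample_stroke(prim: PrimitiveSpec, location=(0.0, 0.0),
                  size: float = DEFAULT_SHAPE_SIZE_PX,
                  noise: StrokeNoise | None = None, seed: int = 0,
                  base_duration_s: float = 0.7) -> Stroke:
    """Draw one noisy repetition of a primitive at 60 Hz.

    The finger traces the placed canonical curve with a minimum-jerk speed
    profile; smooth positional jitter and lognormal duration variability are
    added on top.  With noise=None (or all-zero noise) the samples lie
    exactly on the transformed canonical curve.
    """
    rng = np.random.default_rng(seed)
    noise = noise or StrokeNoise(0.0, 1.0, 0.0)
    duration = base_duration_s * float(np.exp(rng.normal(0.0, noise.duration_sigma))) \
        if noise.duration_sigma > 0 else base_duration_s
    n = max(12, int(round(duration * STROKE_RATE_HZ)))
    t = np.arange(n) / STROKE_RATE_HZ

    placed = place_curve(prim.canonical_curve, location, size)
    seg = np.hypot(*np.diff(placed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    frac = _minimum_jerk_profile(n) * s[-1]
    x = np.interp(frac, s, placed[:, 0])
    y = np.interp(frac, s, placed[:, 1])

    if noise.jitter_px > 0:
        jit = rng.normal(0.0, 1.0, size=(n, 2))
        jit = gaussian_filter1d(jit, noise.jitter_smooth_samples, axis=0,
                                mode="reflect")
        sd = jit.std(axis=0)
        sd[sd == 0] = 1.0
        jit = jit / sd * noise.jitter_px
        x = x + jit[:, 0]
        y = y + jit[:, 1]
    return Stroke(t, x, y)


# ---------------------------------------------------------------------------
# morph sets
# ---------------------------------------------------------------------------

def render_image(prim: PrimitiveSpec, location=(0.0, 0.0),
                 size: float = DEFAULT_SHAPE_SIZE_PX,
                 n_points: int = 60) -> np.ndarray:
    """Render a primitive as an image point set (px)."""
    placed = place_curve(prim.canonical_curve, location, size)
    return resample_by_arc_length(placed, n_points)


@dataclass
class MorphSet:
    """Two practised primitives plus images interpolating between them."""

    prim_a: PrimitiveSpec
    prim_b: PrimitiveSpec
    morphs: list            # [(morph_fraction, image point set), ...] incl. endpoints
    morph_specs: list       # PrimitiveSpec at each fraction (for tracing policy)

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for f, _ in self.morphs])


def make_morph_set(prim_a: PrimitiveSpec, prim_b: PrimitiveSpec,
                   n_morphs: int = 5) -> MorphSet:
    """Interpolate control parameters linearly between two primitives.

    n_morphs interior images plus the two practised end points (fractions 0
    and 1, whose images reproduce the primitives exactly).
    """
    if prim_a.schema != prim_b.schema or \
            prim_a.control_params.shape != prim_b.control_params.shape:
        raise ValueError("primitives do not share a control-parameter schema")
    fractions = np.linspace(0.0, 1.0, n_morphs + 2)
    morphs, specs = [], []
    for f in fractions:
        if f == 0.0:
            spec = prim_a
        elif f == 1.0:
            spec = prim_b
        else:
            params = (1 - f) * prim_a.control_params + f * prim_b.control_params
            spec = PrimitiveSpec(f"{prim_a.primitive_id}-{prim_b.primitive_id}@{f:.2f}",
                                 params)
        specs.append(spec)
        morphs.append((float(f), render_image(spec)))
    return MorphSet(prim_a, prim_b, morphs, specs)


@dataclass
class DrawnTrial:
    """One simulated trial of a morph-set session."""

    morph_fraction: float
    level_index: int
    condition: str          # P1 / U1 / A / U2 / P2
    stroke: Stroke
    drawn: str              # "A", "B" or "morph" (tracing)
    image: np.ndarray


def simulate_drawing_policy(morph_set: MorphSet, policy: str,
                            boundary_fraction: float = 0.5, seed: int = 0,
                            n_trials_per_level: int = 8,
                            noise: StrokeNoise | None = None) -> list[DrawnTrial]:
    """Simulate per-trial drawings of a morph set under a response policy.

    ``categorical``: each interior image is drawn as whichever practised
    primitive its fraction falls nearest to, with a stochastic 50/50 mixture
    at the level closest to boundary_fraction; ``tracing``: the interpolated
    shape itself is traced.
    """
    if not 0.0 < boundary_fraction < 1.0:
        raise ValueError("boundary_fraction must be in (0, 1)")
    if policy not in ("categorical", "tracing"):
        raise ValueError(f"unknown policy {policy!r}")
    rng = np.random.default_rng(seed)
    noise = noise if noise is not None else StrokeNoise()
    fracs = morph_set.fractions
    interior = np.arange(1, len(fracs) - 1)
    boundary_level = int(interior[np.argmin(np.abs(fracs[interior] - boundary_fraction))])

    trials: list[DrawnTrial] = []
    for lv, (f, image) in enumerate(morph_set.morphs):
        if lv == 0:
            cond = "P1"
        elif lv == len(fracs) - 1:
            cond = "P2"
        elif lv == boundary_level:
            cond = "A"
        else:
            cond = "U1" if f < fracs[boundary_level] else "U2"
        for _ in range(n_trials_per_level):
            sub = int(rng.integers(0, 2**31 - 1))
            if policy == "tracing":
                spec, drawn = morph_set.morph_specs[lv], "morph"
            else:
                if lv == boundary_level:
                    pick_b = bool(rng.integers(0, 2))
                else:
                    pick_b = f > fracs[boundary_level] or (cond == "P2")
                spec = morph_set.prim_b if pick_b else morph_set.prim_a
                drawn = "B" if pick_b else "A"
            stroke = sample_stroke(spec, noise=noise, seed=sub)
            trials.append(DrawnTrial(float(f), lv, cond, stroke, drawn, image))
    return trials


# ---------------------------------------------------------------------------
# characters
# ---------------------------------------------------------------------------

@dataclass
class CharacterSpec:
    """A multi-shape character assembled by attaching primitives end to end."""

    n_shapes: int
    shapes: list                 # PrimitiveSpec per stroke
    relations: list              # (attach fraction on shape i, on shape i+1)
    placements: list             # (location centre px, size px) per shape
    image: np.ndarray            # merged point set
    ground_truth_segmentation: np.ndarray  # shape index per image point


def _count_crossings(a: np.ndarray, b: np.ndarray) -> int:
    inter = LineString(a).intersection(LineString(b))
    if inter.is_empty:
        return 0
    if inter.geom_type == "Point":
        return 1
    if inter.geom_type == "MultiPoint":
        return len(inter.geoms)
    return 10**6  # overlapping segments: reject outright


def _point_at_fraction(curve: np.ndarray, frac: float) -> np.ndarray:
    seg = np.hypot(*np.diff(curve, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    x = np.interp(frac * s[-1], s, curve[:, 0])
    y = np.interp(frac * s[-1], s, curve[:, 1])
    return np.array([x, y])


def sample_character(library: list[PrimitiveSpec], n_shapes: int, seed: int = 0,
                     size: float = DEFAULT_SHAPE_SIZE_PX,
                     max_crossings: int = 1, max_attempts: int = 500,
                     points_per_shape: int = 50) -> CharacterSpec:
    """Sample a character of N shapes and N - 1 attachment relations.

    Rejection-samples until the crossing filter passes: no pair of distinct
    placed shape curves intersects more than max_crossings times.
    """
    if not 2 <= n_shapes <= 6:
        raise ValueError("n_shapes must be between 2 and 6")
    rng = np.random.default_rng(seed)
    attach_choices = np.array([0.0, 0.25, 0.5, 0.75, 1.0])

    for _ in range(max_attempts):
        idx = rng.choice(len(library), size=n_shapes,
                         replace=n_shapes > len(library))
        shapes = [library[i] for i in idx]
        relations = [(float(rng.choice(attach_choices)),
                      float(rng.choice(attach_choices)))
                     for _ in range(n_shapes - 1)]
        placed, placements = [], []
        loc = np.zeros(2)
        for k, spec in enumerate(shapes):
            curve = place_curve(spec.canonical_curve, loc, size)
            placed.append(curve)
            placements.append((loc.copy(), size))
            if k < n_shapes - 1:
                fr_here, fr_next = relations[k]
                anchor = _point_at_fraction(curve, fr_here)
                nxt = place_curve(shapes[k + 1].canonical_curve, (0, 0), size)
                offset = _point_at_fraction(nxt, fr_next)
                loc = anchor - offset
        ok = True
        for i in range(n_shapes):
            for j in range(i + 1, n_shapes):
                allowed = max_crossings
                if _count_crossings(placed[i], placed[j]) > allowed:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        pts, seg_idx = [], []
        for k, curve in enumerate(placed):
            res = resample_by_arc_length(curve, points_per_shape)
            pts.append(res)
            seg_idx.append(np.full(points_per_shape, k))
        return CharacterSpec(n_shapes, shapes, relations, placements,
                             np.vstack(pts), np.concatenate(seg_idx))
    raise RuntimeError(f"no character passed the crossing filter in "
                       f"{max_attempts} attempts")


def replay_character_strokes(char: CharacterSpec, noise: StrokeNoise | None = None,
                             seed: int = 0) -> list[Stroke]:
    """Draw each shape of a character as one stroke (ground-truth order)."""
    rng = np.random.default_rng(seed)
    out = []
    for k, (spec, (loc, size)) in enumerate(zip(char.shapes, char.placements)):
        st = sample_stroke(spec, loc, size, noise,
                           seed=int(rng.integers(0, 2**31 - 1)))
        st.stroke_index = k
        out.append(st)
    return out


# ---------------------------------------------------------------------------
# trial events
# ---------------------------------------------------------------------------

TRIAL_ANCHORS = ("fixation_touch", "image_onset", "go_cue", "finger_raise",
                 "stroke_onset", "stroke_offset", "done_press", "reward")


def sample_trial_events(n_trials: int, seed: int = 0) -> pd.DataFrame:
    """Event times for single-stroke trials (anchors strictly ordered)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_trials):
        t = 0.0
        times = {}
        durs = {
            "image_onset": rng.uniform(0.4, 1.0),
            "go_cue": rng.uniform(0.6, 1.6),
            "finger_raise": rng.uniform(0.15, 0.4),
            "stroke_onset": rng.uniform(0.2, 0.5),
            "stroke_offset": rng.uniform(0.4, 1.2),
            "done_press": rng.uniform(0.2, 0.6),
            "reward": rng.uniform(0.3, 1.5),
        }
        times["fixation_touch"] = t
        for name in TRIAL_ANCHORS[1:]:
            t += durs[name]
            times[name] = t
        rows.append({"trial_id": i, **times})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population activity
# ---------------------------------------------------------------------------

REGIONS = ("M1", "PMd", "PMv", "SMA", "preSMA", "dlPFC", "vlPFC", "FP")


@dataclass
class PopulationDesign:
    """Design of a simulated population recording.

    Units respond as baseline + sum of gain-weighted tunings to the condition
    variables, modulated by a shared temporal profile, plus noise.  With
    categorical_flag set, morph trials are routed through the boundary rule
    (fraction vs 0.5) before primitive tuning is applied; otherwise tuning
    interpolates linearly between the two end-point primitives.
    """

    conditions: pd.DataFrame          # columns: primitive, location, size, task_type
    n_units: int = 40
    n_trials_per_condition: int = 10
    time_base: np.ndarray = field(default_factory=lambda: np.arange(0.0, 0.6, 0.02))
    bin_width_s: float = 0.02
    baseline_hz: float = 8.0
    primitive_gain: float = 1.0
    location_gain: float = 0.0
    size_gain: float = 0.0
    task_gain: float = 0.0
    # primitive x location interaction: a location-specific primitive code
    # (each location gets its own random primitive tuning)
    interaction_gain: float = 0.0
    categorical_flag: bool = True
    noise_model: str = "gaussian"     # or "poisson"
    noise_sd: float = 1.0
    region: str = "PMv"
    seed: int = 0

    def __post_init__(self) -> None:
        for g in (self.primitive_gain, self.location_gain, self.size_gain,
                  self.task_gain):
            if g < 0:
                raise ValueError("gains must be >= 0")
        if np.any(np.diff(self.time_base) <= 0):
            raise ValueError("time bins must be strictly increasing")


@dataclass
class PopulationTensor:
    """Trials x units x time firing rates with per-trial condition labels."""

    rates: np.ndarray          # (K, N, T)
    trials: pd.DataFrame       # K rows of condition labels
    time: np.ndarray           # bin starts, s
    bin_width_s: float
    unit_region: np.ndarray    # region label per unit

    def __post_init__(self) -> None:
        if self.rates.shape[0] != len(self.trials):
            raise ValueError("label table row count must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_units(self) -> int:
        return self.rates.shape[1]


REQUIRED_TRIAL_COLUMNS = ("primitive", "location", "size", "task_type")


def validate_tensor(tensor: PopulationTensor) -> None:
    """Check the label schema required by the population analyses."""
    for col in REQUIRED_TRIAL_COLUMNS:
        if col not in tensor.trials.columns:
            raise ValueError(f"trial table missing column {col!r}")
    if tensor.rates.ndim != 3:
        raise ValueError("rates must be (trials, units, bins)")
    if tensor.rates.shape[2] != len(tensor.time):
        raise ValueError("time base does not match rate bins")
    if len(tensor.unit_region) != tensor.rates.shape[1]:
        raise ValueError("unit_region length must equal unit count")


def _level_weights(rng, levels, n_units):
    return {lv: rng.normal(0.0, 1.0, size=n_units) for lv in levels}


def simulate_population(design: PopulationDesign) -> PopulationTensor:
    """Simulate a population tensor from a tuning design (seed-deterministic)."""
    rng = np.random.default_rng(design.seed)
    cond = design.conditions.reset_index(drop=True)
    n_units, tt = design.n_units, design.time_base
    profile = np.exp(-0.5 * ((tt - tt.mean()) / (0.25 * (tt[-1] - tt[0] + 1e-12)))**2)

    has_morph = "morph_fraction" in cond.columns and \
        cond["morph_fraction"].notna().any()
    prim_levels = set()
    for col in ("primitive", "prim_a", "prim_b"):
        if col in cond.columns:
            prim_levels |= set(cond[col].dropna().unique())
    w_prim = _level_weights(rng, sorted(prim_levels, key=str), n_units)
    w_loc = _level_weights(rng, sorted(cond["location"].unique(), key=str), n_units)
    w_size = _level_weights(rng, sorted(cond["size"].unique(), key=str), n_units)
    w_task = _level_weights(rng, sorted(cond["task_type"].unique(), key=str), n_units)
    w_inter = _level_weights(
        rng, [(p, l) for p in sorted(prim_levels, key=str)
              for l in sorted(cond["location"].unique(), key=str)], n_units)

    rows, rates = [], []
    for _, c in cond.iterrows():
        for _ in range(design.n_trials_per_condition):
            drawn = c.get("primitive", None)
            if has_morph and pd.notna(c.get("morph_fraction", np.nan)):
                f = float(c["morph_fraction"])
                if design.categorical_flag:
                    if f < 0.5:
                        drawn = c["prim_a"]
                    elif f > 0.5:
                        drawn = c["prim_b"]
                    else:
                        drawn = c["prim_b"] if rng.integers(0, 2) else c["prim_a"]
                    tune_p = w_prim[drawn]
                else:
                    drawn = "morph"
                    tune_p = (1 - f) * w_prim[c["prim_a"]] + f * w_prim[c["prim_b"]]
            else:
                tune_p = w_prim[c["primitive"]]
            amp = (design.primitive_gain * tune_p
                   + design.location_gain * w_loc[c["location"]]
                   + design.size_gain * w_size[c["size"]]
                   + design.task_gain * w_task[c["task_type"]])
            if design.interaction_gain > 0 and (drawn, c["location"]) in w_inter:
                amp = amp + design.interaction_gain * w_inter[(drawn, c["location"])]
            rate = design.baseline_hz + amp[:, None] * profile[None, :]
            if design.noise_model == "poisson":
                lam = np.clip(rate, 0, None) * design.bin_width_s
                rate = rng.poisson(lam) / design.bin_width_s
            else:
                rate = rate + rng.normal(0.0, design.noise_sd, size=rate.shape)
            rates.append(rate)
            row = dict(c)
            row["drawn_primitive"] = drawn
            rows.append(row)
    trials = pd.DataFrame(rows)
    if "primitive" not in trials.columns:
        trials["primitive"] = trials["drawn_primitive"]
    if "first_stroke" not in trials.columns:
        trials["first_stroke"] = True
    if "stroke_index" not in trials.columns:
        trials["stroke_index"] = 0
    tensor = PopulationTensor(np.stack(rates), trials, tt, design.bin_width_s,
                              np.array([design.region] * n_units))
    validate_tensor(tensor)
    return tensor


# ---------------------------------------------------------------------------
# YAML-driven generation
# ---------------------------------------------------------------------------

def generate_from_config(path) -> dict:
    """Generate synthetic data from a YAML config.

    Recognized blocks (each with its own seed): ``primitives``
    (n_primitives), ``morphs`` (pair indices, n_morphs), ``characters``
    (n_characters, n_shapes) and ``population`` (PopulationDesign keyword
    arguments plus a conditions table as a list of records).
    """
    import yaml

    with open(path) as f:
        cfg = yaml.safe_load(f)
    out: dict = {}
    if "primitives" in cfg:
        c = cfg["primitives"]
        out["primitives"] = make_primitive_library(
            c.get("n_primitives", 5), seed=c.get("seed", 0),
            distinctness_floor=c.get("distinctness_floor", 0.25))
    if "morphs" in cfg:
        c = cfg["morphs"]
        lib = out["primitives"]
        i, j = c.get("pair", [0, 1])
        out["morph_set"] = make_morph_set(lib[i], lib[j],
                                          c.get("n_morphs", 5))
    if "characters" in cfg:
        c = cfg["characters"]
        out["characters"] = [
            sample_character(out["primitives"], c.get("n_shapes", 3),
                             seed=c.get("seed", 0) + k)
            for k in range(c.get("n_characters", 1))]
    if "population" in cfg:
        c = dict(cfg["population"])
        conds = pd.DataFrame(c.pop("conditions"))
        out["population"] = simulate_population(
            PopulationDesign(conditions=conds, **c))
    return out


# ---------------------------------------------------------------------------
# HDF5 round trip
# ---------------------------------------------------------------------------

def save_tensor(path, tensor: PopulationTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=tensor.rates)
        f.create_dataset("time_base", data=tensor.time)
        f.attrs["bin_width_s"] = tensor.bin_width_s
        f.create_dataset("unit_region",
                         data=np.asarray(tensor.unit_region, dtype="S"))
        g = f.create_group("trials")
        for col in tensor.trials.columns:
            vals = tensor.trials[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "U":
                vals = np.asarray(vals, dtype="S")
            g.create_dataset(col, data=vals)


def load_tensor(path) -> PopulationTensor:
    with h5py.File(path, "r") as f:
        rates = f["rates"][:]
        time = f["time_base"][:]
        bw = float(f.attrs["bin_width_s"])
        region = f["unit_region"][:].astype(str)
        cols = {}
        for col in f["trials"]:
            v = f["trials"][col][:]
            if v.dtype.kind == "S":
                v = v.astype(str)
            cols[col] = v
    return PopulationTensor(rates, pd.DataFrame(cols), time, bw, region)
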