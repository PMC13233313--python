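"""Population-geometry analyses of condition-labelled firing-rate tensors.

The central quantity is the debiased, normalized *neural distance* between
two trial conditions A and B,

    D*_AB = D_AB - (D_AA + D_BB) / 2,

where D_AB is the mean pairwise Euclidean distance between A and B trials,
per time bin, divided by d_max(t) (the 98th percentile of all pairwise
trial distances) and averaged across bins.  Subtracting the within-condition
terms makes the expected distance between two samples of the same
distribution zero, so small negative values are meaningful and are kept.

Built on that are: encoding strength (mean D* over condition pairs that
differ only in the target variable), an OLS-based region comparison with
Bonferroni correction and per-region "beaten counts", cross-condition
decoder generalization (accuracy rescaled so chance maps to 0), a
Euclidean-metric primitive alignment feeding the categorical hallmark
tests, an initial-reach correction regression, a linear velocity-encoding
model scored by FVAF = 1 - SS_err/SS_tot, and a fixation-aligned
one-vs-rest primitive decoder.

Analysis windows default to the printed task epochs (0.05-0.6 s planning,
0.6-1.0 s categorical time-average, -0.5 to -0.05 s pre-stroke) and are
plain keyword arguments throughout.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, cdist, squareform
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import LinearSVC

from .synthetic_data import PopulationTensor, validate_tensor
from .trajectory_metrics import AlignmentScore

logger = logging.getLogger("actionsym")

N_PCA_COMPONENTS = 8
N_PCA_SPLITS = 8
D_MAX_PERCENTILE = 98.0
SVC_C = 0.1
PLANNING_WINDOW = (0.05, 0.6)
CATEGORICAL_WINDOW = (0.6, 1.0)
PRESTROKE_WINDOW = (-0.5, -0.05)
NONFIRST_WINDOW = (-0.35, -0.05)
FVAF_LAGS = np.arange(-0.3, 0.3001, 0.05)
FVAF_SUMMARY_LAGS = (-0.15, -0.05)
FIXATION_EXCLUDE_PX = 70.0


def _window_mask(time: np.ndarray, window) -> np.ndarray:
    if window is None:
        return np.ones_like(time, dtype=bool)
    lo, hi = window
    return (time >= lo) & (time <= hi)


def rebin(rates: np.ndarray, time: np.ndarray, bin_s: float,
          slide_s: float, window=None) -> tuple[np.ndarray, np.ndarray]:
    """Average (trials, units, bins) rates into sliding windows."""
    mask = _window_mask(time, window)
    t = time[mask]
    r = rates[:, :, mask]
    starts = np.arange(t[0], t[-1] - bin_s + 1e-9, slide_s)
    if len(starts) == 0:
        starts = np.array([t[0]])
    out = np.empty(r.shape[:2] + (len(starts),))
    for k, s in enumerate(starts):
        sel = (t >= s - 1e-9) & (t < s + bin_s + 1e-9)
        out[:, :, k] = r[:, :, sel].mean(axis=2)
    return out, starts + bin_s / 2


# ---------------------------------------------------------------------------
# condition-averaged, cross-validated PCA
# ---------------------------------------------------------------------------

@dataclass
class ConditionPCASplit:
    pca: PCA
    train_idx: np.ndarray
    test_idx: np.ndarray
    projected: np.ndarray      # (trials, components, bins) -- all trials projected
    time: np.ndarray


def _combo_key(trials: pd.DataFrame, key) -> np.ndarray:
    if isinstance(key, str):
        return trials[key].to_numpy().astype(str)
    return trials[list(key)].astype(str).agg("|".join, axis=1).to_numpy()


def fit_condition_pca(tensor: PopulationTensor, condition_key,
                      window=PLANNING_WINDOW, n_components: int = N_PCA_COMPONENTS,
                      n_splits: int = N_PCA_SPLITS, bin_s: float = 0.15,
                      slide_s: float = 0.02, seed: int = 0,
                      stratify_key=None) -> list[ConditionPCASplit]:
    """PCA on condition-averaged activity, cross-validated over trial splits.

    Per split, trials are stratified-halved (by `stratify_key`, default the
    PCA condition key); the PCA loadings are fitted on the train half's
    condition-mean N x (K_C T) matrix and all trials are projected.
    Downstream analyses use the test half and average over the n_splits
    randomized splits.
    """
    validate_tensor(tensor)
    rates, t = rebin(tensor.rates, tensor.time, bin_s, slide_s, window)
    keys = _combo_key(tensor.trials, condition_key)
    strat = keys if stratify_key is None else _combo_key(tensor.trials, stratify_key)
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        train, test = [], []
        for lv in np.unique(strat):
            idx = np.flatnonzero(strat == lv)
            if len(idx) < 2:
                raise ValueError(f"condition {lv!r} has fewer than 2 trials")
            idx = rng.permutation(idx)
            half = len(idx) // 2
            train.extend(idx[:half])
            test.extend(idx[half:])
        train = np.sort(np.asarray(train))
        test = np.sort(np.asarray(test))
        cond_means = [rates[train[keys[train] == lv]].mean(axis=0)
                      for lv in np.unique(keys[train])]
        X_c = np.hstack(cond_means)                      # N x (K_C T)
        pca = PCA(n_components=min(n_components, X_c.shape[0], X_c.shape[1]))
        pca.fit(X_c.T)
        K, N, T = rates.shape
        flat = rates.transpose(0, 2, 1).reshape(-1, N)
        proj = pca.transform(flat).reshape(K, T, -1).transpose(0, 2, 1)
        splits.append(ConditionPCASplit(pca, train, test, proj, t))
    return splits


# ---------------------------------------------------------------------------
# neural distance
# ---------------------------------------------------------------------------

def _dmax_per_bin(X: np.ndarray) -> np.ndarray:
    """98th percentile of pairwise trial distances, per time bin."""
    T = X.shape[2]
    out = np.empty(T)
    for k in range(T):
        d = pdist(X[:, :, k])
        out[k] = np.percentile(d, D_MAX_PERCENTILE)
    if np.any(out == 0):
        raise ValueError("degenerate data: d_max is zero in some bin")
    return out


def _mean_cross(Xa, Xb, dmax) -> float:
    vals = []
    for k in range(Xa.shape[2]):
        vals.append(cdist(Xa[:, :, k], Xb[:, :, k]).mean() / dmax[k])
    return float(np.mean(vals))


def _mean_within(Xa, dmax) -> float:
    if Xa.shape[0] < 2:
        raise ValueError("need >= 2 trials per condition")
    vals = []
    for k in range(Xa.shape[2]):
        vals.append(pdist(Xa[:, :, k]).mean() / dmax[k])
    return float(np.mean(vals))


def neural_distance(X: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
                    dmax: np.ndarray | None = None) -> float:
    """Debiased normalized distance D*_AB between two trial sets.

    X is (trials, features, bins); idx_a/idx_b select the two conditions'
    trials.  Within-condition means use distinct trial pairs only, which
    makes D* of a condition with itself exactly zero (self-pair convention)
    and D* of two samples from one distribution zero in expectation.
    """
    idx_a = np.asarray(idx_a)
    idx_b = np.asarray(idx_b)
    if dmax is None:
        dmax = _dmax_per_bin(X)
    if idx_a.size == idx_b.size and np.array_equal(np.sort(idx_a), np.sort(idx_b)):
        return 0.0
    d_ab = _mean_cross(X[idx_a], X[idx_b], dmax)
    d_aa = _mean_within(X[idx_a], dmax)
    d_bb = _mean_within(X[idx_b], dmax)
    return d_ab - 0.5 * (d_aa + d_bb)


def condition_distance_table(X: np.ndarray, labels: pd.DataFrame,
                             keys) -> pd.DataFrame:
    """D* for every pair of conditions defined by the key columns."""
    combo = labels[list(keys)].astype(str).agg("|".join, axis=1).to_numpy()
    dmax = _dmax_per_bin(X)
    conds = np.unique(combo)
    rows = []
    for a, b in itertools.combinations(conds, 2):
        d = neural_distance(X, np.flatnonzero(combo == a),
                            np.flatnonzero(combo == b), dmax)
        va = dict(zip(keys, a.split("|")))
        vb = dict(zip(keys, b.split("|")))
        rows.append({"cond_a": a, "cond_b": b, "dstar": d,
                     **{f"{k}_a": va[k] for k in keys},
                     **{f"{k}_b": vb[k] for k in keys}})
    return pd.DataFrame(rows)


def encoding_strength(dist_table: pd.DataFrame, variable: str,
                      controls) -> float:
    """Mean D* over condition pairs differing only in `variable`.

    controls lists the variables that must match across the pair (e.g.
    location when the target variable is primitive).
    """
    mask = dist_table[f"{variable}_a"] != dist_table[f"{variable}_b"]
    for c in controls:
        mask &= dist_table[f"{c}_a"] == dist_table[f"{c}_b"]
    if not mask.any():
        raise ValueError("no qualifying condition pair")
    return float(dist_table.loc[mask, "dstar"].mean())


def encoding_strengths_from_tensor(tensor: PopulationTensor, variable: str,
                                   control: str, window=PLANNING_WINDOW,
                                   n_splits: int = N_PCA_SPLITS,
                                   seed: int = 0) -> dict:
    """Condition-PCA -> distance table -> encoding strength, split-averaged.

    Returns mean encoding strengths for the target and control variables.
    """
    splits = fit_condition_pca(tensor, variable, window=window,
                               n_splits=n_splits, seed=seed,
                               stratify_key=(variable, control))
    var_vals, ctl_vals = [], []
    for sp in splits:
        X = sp.projected[sp.test_idx]
        tab = condition_distance_table(X, tensor.trials.iloc[sp.test_idx]
                                       .reset_index(drop=True), (variable, control))
        var_vals.append(encoding_strength(tab, variable, (control,)))
        ctl_vals.append(encoding_strength(tab, control, (variable,)))
    return {variable: float(np.mean(var_vals)), control: float(np.mean(ctl_vals))}


# ---------------------------------------------------------------------------
# region comparison
# ---------------------------------------------------------------------------

@dataclass
class EncodingSummary:
    per_pair: pd.DataFrame     # region_a, region_b, variable, beta_r, p, p_corrected
    beaten_counts: pd.DataFrame  # region x variable counts
    n_comparisons: int


def compare_regions(datasets: dict, variables) -> EncodingSummary:
    """Pairwise OLS comparison of regions in variable-encoding strength.

    datasets maps region -> {variable -> DataFrame(pair_id, dstar)}; for
    each region pair and variable, the two regions' distance datasets are
    stacked and y = b0 + b_r X_r + sum_j g_j Z_j + e is fitted with
    condition-pair indicator variables Z_j.  Two-sided t-tests on b_r are
    Bonferroni-corrected over (n_variables x n_region_pairs) comparisons;
    each region's beaten count per variable is the number of other regions
    it exceeds significantly (positive corrected effect).
    """
    regions = sorted(datasets)
    pairs = list(itertools.combinations(regions, 2))
    n_comparisons = len(variables) * len(pairs)
    rows = []
    for var in variables:
        for ra, rb in pairs:
            da = datasets[ra][var]
            db = datasets[rb][var]
            y = np.concatenate([da["dstar"], db["dstar"]])
            xr = np.concatenate([np.zeros(len(da)), np.ones(len(db))])
            pair_ids = np.concatenate([da["pair_id"], db["pair_id"]])
            Z = pd.get_dummies(pd.Series(pair_ids), drop_first=True).to_numpy(float)
            design = sm.add_constant(np.column_stack([xr, Z]))
            if np.linalg.matrix_rank(design) < design.shape[1]:
                logger.warning("rank-deficient design for %s vs %s (%s)", ra, rb, var)
            fit = sm.OLS(y, design).fit()
            rows.append({"region_a": ra, "region_b": rb, "variable": var,
                         "beta_r": float(fit.params[1]),
                         "p": float(fit.pvalues[1])})
    table = pd.DataFrame(rows)
    table["p_corrected"] = np.minimum(table["p"] * n_comparisons, 1.0)
    beaten = pd.DataFrame(0, index=regions, columns=list(variables))
    for _, r in table.iterrows():
        if r["p_corrected"] < 0.05:
            # beta_r > 0 means region_b has larger distances
            winner = r["region_b"] if r["beta_r"] > 0 else r["region_a"]
            beaten.loc[winner, r["variable"]] += 1
    return EncodingSummary(table, beaten, n_comparisons)


# ---------------------------------------------------------------------------
# cross-condition decoding
# ---------------------------------------------------------------------------

def rescale_accuracy(acc: float, n_classes: int) -> float:
    """Map chance (1/n_classes) to 0 and perfect accuracy to 1."""
    chance = 1.0 / n_classes
    return (acc - chance) / (1.0 - chance)


def cross_condition_decode(X: np.ndarray, labels: np.ndarray,
                           condition: np.ndarray, train_condition,
                           test_conditions=None, svc_c: float = SVC_C,
                           seed: int = 0) -> dict:
    """Linear one-vs-rest decoding trained at one condition, tested at others.

    X: (trials, features, bins).  A LinearSVC is trained per time bin on the
    trials of `train_condition` and tested on trials of each other
    condition; accuracy is averaged over bins and rescaled so chance maps to
    0.  Within-condition accuracy (split-half on the training condition) is
    reported alongside.
    """
    labels = np.asarray(labels)
    condition = np.asarray(condition)
    classes = np.unique(labels)
    if test_conditions is None:
        test_conditions = [c for c in np.unique(condition) if c != train_condition]
    tr = np.flatnonzero(condition == train_condition)
    te = np.flatnonzero(np.isin(condition, test_conditions))
    for c in list(test_conditions) + [train_condition]:
        for lv in classes:
            if not np.any((condition == c) & (labels == lv)):
                raise ValueError(f"class {lv!r} missing in condition {c!r}")
    T = X.shape[2]
    cross_acc, within_acc = [], []
    rng = np.random.default_rng(seed)
    half = rng.permutation(tr)
    a_half, b_half = half[:len(half) // 2], half[len(half) // 2:]
    for k in range(T):
        clf = LinearSVC(C=svc_c).fit(X[tr, :, k], labels[tr])
        cross_acc.append((clf.predict(X[te, :, k]) == labels[te]).mean())
        clf2 = LinearSVC(C=svc_c).fit(X[a_half, :, k], labels[a_half])
        within_acc.append((clf2.predict(X[b_half, :, k]) == labels[b_half]).mean())
    n = len(classes)
    return {
        "cross_accuracy": float(np.mean(cross_acc)),
        "cross_rescaled": rescale_accuracy(float(np.mean(cross_acc)), n),
        "within_accuracy": float(np.mean(within_acc)),
        "within_rescaled": rescale_accuracy(float(np.mean(within_acc)), n),
        "n_classes": n,
    }


def cross_condition_decode_tensor(tensor: PopulationTensor, label_key: str,
                                  condition_key: str, train_condition,
                                  window=PLANNING_WINDOW, seed: int = 0,
                                  n_splits: int = N_PCA_SPLITS) -> dict:
    """Tensor-level wrapper: condition PCA then cross-condition decoding.

    The PCA conditions are the label x condition conjunctions: averaging
    over the generalization condition instead would project away any
    condition-specific component of the code and make even a fully
    condition-specific code appear to generalize.
    """
    splits = fit_condition_pca(tensor, (label_key, condition_key), window=window,
                               n_splits=n_splits, seed=seed,
                               stratify_key=(label_key, condition_key))
    keys = ("cross_rescaled", "within_rescaled", "cross_accuracy", "within_accuracy")
    acc = {k: [] for k in keys}
    for sp in splits:
        res = cross_condition_decode(
            sp.projected[sp.test_idx],
            tensor.trials[label_key].to_numpy()[sp.test_idx],
            tensor.trials[condition_key].to_numpy()[sp.test_idx],
            train_condition, seed=seed)
        for k in keys:
            acc[k].append(res[k])
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# neural primitive alignment (categorical structure)
# ---------------------------------------------------------------------------

def neural_primitive_alignment(X: np.ndarray, trials: pd.DataFrame,
                               time: np.ndarray,
                               window=CATEGORICAL_WINDOW) -> pd.DataFrame:
    """Per-trial Euclidean-metric primitive alignment of population activity.

    Activity is time-averaged in the (late-planning) window; each trial's
    alignment is d1/(d1+d2) with d1/d2 the mean Euclidean distances to the
    P1/P2 reference trials.  Returns the trial table with an ``a_neural``
    column; ambiguous-condition trials can then be split into A1/A2 by the
    drawn primitive.
    """
    mask = _window_mask(time, window)
    V = X[:, :, mask].mean(axis=2)
    cond = trials["trial_condition"].to_numpy()
    p1 = V[cond == "P1"]
    p2 = V[cond == "P2"]
    if len(p1) == 0 or len(p2) == 0:
        raise ValueError("P1/P2 reference trials required")
    out = trials.copy()
    d1 = cdist(V, p1)
    d2 = cdist(V, p2)
    # leave-self-out means for reference trials themselves
    a = np.empty(len(V))
    for i in range(len(V)):
        m1 = d1[i][d1[i] > 0] if cond[i] == "P1" else d1[i]
        m2 = d2[i][d2[i] > 0] if cond[i] == "P2" else d2[i]
        s1, s2 = m1.mean(), m2.mean()
        a[i] = 0.5 if s1 + s2 == 0 else s1 / (s1 + s2)
    out["a_neural"] = a
    return out


def hallmark_stats_from_alignment(aligned: pd.DataFrame,
                                  value_col: str = "a_neural") -> dict:
    """Per-morph-set condition means plus the A1/A2 split, for hallmark tests."""
    stats = {}
    means = aligned.groupby("trial_condition")[value_col].mean()
    stats["drawing"] = means.to_dict()
    amb = aligned[aligned["trial_condition"] == "A"]
    if len(amb) and "drawn_primitive" in amb.columns:
        prims = amb["drawn_primitive"].unique()
        if len(prims) == 2:
            lo, hi = sorted(prims, key=lambda p: amb[amb["drawn_primitive"] == p][value_col].mean())
            stats["A1"] = float(amb[amb["drawn_primitive"] == lo][value_col].mean())
            stats["A2"] = float(amb[amb["drawn_primitive"] == hi][value_col].mean())
    return stats


# ---------------------------------------------------------------------------
# pairwise primitive decoding across regions
# ---------------------------------------------------------------------------

def trial_vectors(tensor: PopulationTensor, window=PLANNING_WINDOW,
                  bin_s: float = 0.2, slide_s: float = 0.1,
                  n_pcs: int = 50) -> np.ndarray:
    """K x (N T) trial vectors, PCA-reduced to at most n_pcs dimensions."""
    rates, _ = rebin(tensor.rates, tensor.time, bin_s, slide_s, window)
    K = rates.shape[0]
    D = rates.reshape(K, -1)
    n = min(n_pcs, K - 1, D.shape[1])
    return PCA(n_components=n).fit_transform(D)


def pairwise_primitive_decoding(tensors_by_region: dict, window=PLANNING_WINDOW,
                                condition_key: str = "location",
                                svc_c: float = SVC_C, n_subsample_repeats: int = 10,
                                min_units: int | None = None,
                                seed: int = 0) -> dict:
    """Cross-condition primitive-pair decoding per region, unit-matched.

    Regions are first matched in unit count by randomly subsampling (without
    replacement) to the smallest region, repeated n_subsample_repeats times
    and averaged.  For each primitive pair a linear classifier is trained on
    trials of one condition level (location or size) and tested on the
    others, averaging over training levels.  Returns region -> accuracy
    DataFrame over primitive pairs.
    """
    rng = np.random.default_rng(seed)
    n_min = min(t.n_units for t in tensors_by_region.values())
    if min_units is not None and n_min < min_units:
        tensors_by_region = {r: t for r, t in tensors_by_region.items()
                             if t.n_units >= min_units}
        n_min = min(t.n_units for t in tensors_by_region.values())
    out = {}
    for region, tensor in tensors_by_region.items():
        prims = np.unique(tensor.trials["primitive"])
        acc = pd.DataFrame(np.nan, index=prims, columns=prims)
        conds = tensor.trials[condition_key].to_numpy()
        labels = tensor.trials["primitive"].to_numpy()
        reps = []
        for _ in range(n_subsample_repeats):
            units = rng.choice(tensor.n_units, size=n_min, replace=False)
            sub = PopulationTensor(tensor.rates[:, units, :], tensor.trials,
                                   tensor.time, tensor.bin_width_s,
                                   tensor.unit_region[units])
            D = trial_vectors(sub, window)
            rep = pd.DataFrame(np.nan, index=prims, columns=prims)
            for i, a in enumerate(prims):
                for b in prims[i + 1:]:
                    mask = np.isin(labels, [a, b])
                    scores = []
                    for lv in np.unique(conds):
                        tr = mask & (conds == lv)
                        te = mask & (conds != lv)
                        if len(np.unique(labels[tr])) < 2 or te.sum() == 0:
                            continue
                        clf = LinearSVC(C=svc_c).fit(D[tr], labels[tr])
                        scores.append((clf.predict(D[te]) == labels[te]).mean())
                    rep.loc[a, b] = rep.loc[b, a] = float(np.mean(scores))
            reps.append(rep)
        acc = sum(reps) / len(reps)
        out[region] = acc
    return out


# ---------------------------------------------------------------------------
# initial-reach correction
# ---------------------------------------------------------------------------

def correct_initial_reach(tensor: PopulationTensor) -> tuple[PopulationTensor, np.ndarray]:
    """Remove the mean initial-reach transient from first-stroke activity.

    Per unit and time bin, y = b0 + b_f X_f + b_t X_t + sum_j g_j Z_j + e is
    fitted with X_f the first-stroke indicator, X_t the task-type indicator
    and Z_j primitive-class indicators; only b_f is subtracted, and only
    from first strokes.  Returns the corrected tensor and the fitted b_f
    (units x bins).
    """
    trials = tensor.trials
    xf = trials["first_stroke"].to_numpy().astype(float)
    if np.all(xf == 1) or np.all(xf == 0):
        raise ValueError("need both first and non-first strokes to fit the reach effect")
    task_levels = np.unique(trials["task_type"])
    xt = (trials["task_type"] == task_levels[-1]).to_numpy().astype(float)
    Z = pd.get_dummies(trials["drawn_primitive"]
                       if "drawn_primitive" in trials.columns
                       else trials["primitive"], drop_first=True).to_numpy(float)
    design = np.column_stack([np.ones_like(xf), xf, xt, Z])
    K, N, T = tensor.rates.shape
    Y = tensor.rates.reshape(K, N * T)
    beta = np.linalg.lstsq(design, Y, rcond=None)[0]
    beta_f = beta[1].reshape(N, T)
    corrected = tensor.rates.copy()
    corrected[xf == 1] -= beta_f[None, :, :]
    return PopulationTensor(corrected, trials, tensor.time, tensor.bin_width_s,
                            tensor.unit_region), beta_f


# ---------------------------------------------------------------------------
# FVAF kinematic encoding
# ---------------------------------------------------------------------------

def _fvaf(pred: np.ndarray, actual: np.ndarray) -> float:
    ss_err = float(np.sum((pred - actual)**2))
    ss_tot = float(np.sum(actual**2))
    return 1.0 - ss_err / ss_tot


def fvaf_kinematics(components: np.ndarray, velocity: np.ndarray,
                    primitive_labels: np.ndarray,
                    lags_s=FVAF_LAGS, dt_s: float = 0.01,
                    summary_window=FVAF_SUMMARY_LAGS) -> dict:
    """Linear velocity-encoding model f_t = E v_t + b, scored by FVAF.

    components: (samples, n_dims) neural activity (top PCs) concatenated over
    trials; velocity: (samples, 2) finger velocity on the same clock;
    primitive_labels: per-sample primitive, used for the held-one-out
    generalization scheme.  The lag shifts neural activity relative to
    behaviour (negative = neural leads); FVAF uses the uncentred total sum
    of squares as printed, with the intercept included in the predictions.
    Returns the per-lag FVAF curve, the summary (mean over -0.15..-0.05 s)
    and the argmax lag.
    """
    velocity = np.asarray(velocity, float)
    if np.allclose(velocity, 0):
        raise ValueError("degenerate velocity: all zero")
    labels = np.asarray(primitive_labels)
    prims = np.unique(labels)
    if len(prims) < 3:
        raise ValueError("held-one-out scheme needs >= 3 primitives")
    curve = []
    for lag in lags_s:
        shift = int(round(lag / dt_s))
        if shift < 0:         # neural leads: pair f_t with later v
            f = components[:shift] if shift else components
            v = velocity[-shift:]
            lab = labels[-shift:]
        elif shift > 0:
            f = components[shift:]
            v = velocity[:-shift]
            lab = labels[:-shift]
        else:
            f, v, lab = components, velocity, labels
        scores = []
        for p in prims:
            tr = lab != p
            te = lab == p
            A = np.column_stack([v[tr], np.ones(tr.sum())])
            coef = np.linalg.lstsq(A, f[tr], rcond=None)[0]
            pred = np.column_stack([v[te], np.ones(te.sum())]) @ coef
            scores.append(_fvaf(pred, f[te]))
        curve.append(float(np.mean(scores)))
    curve = np.asarray(curve)
    lags_s = np.asarray(lags_s)
    lo, hi = summary_window
    sel = (lags_s >= lo - 1e-9) & (lags_s <= hi + 1e-9)
    return {"lags_s": lags_s, "fvaf": curve,
            "summary": float(curve[sel].mean()),
            "peak_lag_s": float(lags_s[int(np.argmax(curve))])}


# ---------------------------------------------------------------------------
# fixation-aligned decoding
# ---------------------------------------------------------------------------

def fixation_decoding(train_snippets: np.ndarray, train_labels: np.ndarray,
                      fixation_activity: np.ndarray, fixations: pd.DataFrame,
                      shape_positions: dict,
                      exclude_px: float = FIXATION_EXCLUDE_PX,
                      seed: int = 0) -> pd.DataFrame:
    """Probability time courses of fixated vs planned primitives.

    A multilabel one-vs-rest logistic decoder is trained on planning-epoch
    population snippets (rows of train_snippets with primitive labels) and
    applied to fixation-aligned activity.  Each fixation is labelled with
    its nearest shape's primitive; fixations further than 70 px from every
    shape are excluded (count logged).  fixations needs columns fix_x,
    fix_y and planned_primitive; shape_positions maps primitive -> (x, y).
    Returns one row per kept fixation with probabilities for every
    primitive plus ``p_fixated`` and ``p_planned``.
    """
    clf = OneVsRestClassifier(LogisticRegression(max_iter=2000,
                                                 random_state=seed))
    clf.fit(train_snippets, np.asarray(train_labels))
    classes = clf.classes_

    keep_rows, probs = [], []
    n_excluded = 0
    for i, row in fixations.reset_index(drop=True).iterrows():
        pos = np.array([row["fix_x"], row["fix_y"]])
        dists = {p: np.linalg.norm(pos - np.asarray(xy))
                 for p, xy in shape_positions.items()}
        nearest = min(dists, key=dists.get)
        if dists[nearest] > exclude_px:
            n_excluded += 1
            continue
        pr = clf.predict_proba(fixation_activity[i][None, :])[0]
        rec = dict(row)
        rec["fixated_primitive"] = nearest
        for c, v in zip(classes, pr):
            rec[f"p_{c}"] = float(v)
        rec["p_fixated"] = float(pr[list(classes).index(nearest)])
        planned = row["planned_primitive"]
        rec["p_planned"] = float(pr[list(classes).index(planned)]) \
            if planned in classes else np.nan
        keep_rows.append(rec)
        probs.append(pr)
    if n_excluded:
        logger.info("fixation_decoding: excluded %d fixation(s) farther than "
                    "%.0f px from every shape", n_excluded, exclude_px)
    out = pd.DataFrame(keep_rows)
    out.attrs["n_excluded"] = n_excluded
    return out
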