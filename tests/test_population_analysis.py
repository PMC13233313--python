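import numpy as np
import pandas as pd
import pytest

import actionsym as a
from actionsym.population_analysis import (compare_regions,
                                           condition_distance_table,
                                           correct_initial_reach,
                                           cross_condition_decode_tensor,
                                           encoding_strength,
                                           encoding_strengths_from_tensor,
                                           fit_condition_pca,
                                           fixation_decoding, fvaf_kinematics,
                                           hallmark_stats_from_alignment,
                                           neural_distance,
                                           neural_primitive_alignment,
                                           pairwise_primitive_decoding,
                                           rescale_accuracy)


def basic_conditions(prims="abcd", locs="LR"):
    return pd.DataFrame([{"primitive": p, "location": l, "size": "M",
                          "task_type": "single"}
                         for p in prims for l in locs])


def make_tensor(primitive_gain=1.5, location_gain=0.0, interaction_gain=0.0,
                n_units=25, n_trials=8, noise_sd=1.0, seed=1, conds=None):
    des = a.PopulationDesign(
        conditions=conds if conds is not None else basic_conditions(),
        n_units=n_units, n_trials_per_condition=n_trials,
        primitive_gain=primitive_gain, location_gain=location_gain,
        interaction_gain=interaction_gain, noise_sd=noise_sd, seed=seed)
    return a.simulate_population(des)


class TestConditionPCA:
    def test_train_test_disjoint(self):
        t = make_tensor()
        for sp in fit_condition_pca(t, "primitive", window=None, seed=0):
            assert set(sp.train_idx).isdisjoint(sp.test_idx)
            assert len(sp.train_idx) + len(sp.test_idx) == t.n_trials

    def test_planar_signal_captured_by_two_components(self):
        rng = np.random.default_rng(0)
        t = make_tensor(primitive_gain=0.0, noise_sd=0.01)
        # inject a 2-D signal in unit space varying with primitive
        u1, u2 = rng.normal(size=(2, t.n_units))
        codes = {p: rng.normal(size=2) for p in "abcd"}
        for k, p in enumerate(t.trials["primitive"]):
            c = codes[p]
            t.rates[k] += (c[0] * u1 + c[1] * u2)[:, None]
        (sp,) = fit_condition_pca(t, "primitive", window=None, n_splits=1,
                                  seed=0)
        assert sp.pca.explained_variance_ratio_[:2].sum() > 0.99

    def test_split_determinism(self):
        t = make_tensor()
        s1 = fit_condition_pca(t, "primitive", window=None, seed=5)
        s2 = fit_condition_pca(t, "primitive", window=None, seed=5)
        for x, y in zip(s1, s2):
            assert np.array_equal(x.train_idx, y.train_idx)
            assert np.allclose(x.projected, y.projected)

    def test_single_trial_condition_rejected(self):
        t = make_tensor(n_trials=1)
        with pytest.raises(ValueError):
            fit_condition_pca(t, ("primitive", "location"), window=None, seed=0)


class TestNeuralDistance:
    def test_same_trial_set_exactly_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5, 3))
        idx = np.arange(5)
        assert neural_distance(X, idx, idx) == 0.0

    def test_debiased_null_mean_near_zero(self):
        """Same-distribution condition pairs average to D* ~ 0."""
        rng = np.random.default_rng(2)
        vals = [neural_distance(rng.normal(size=(16, 10, 3)),
                                np.arange(8), np.arange(8, 16))
                for _ in range(200)]
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_point_mass_closed_form(self):
        # two point-mass conditions at distance delta: D* = delta / d_max
        delta = 2.0
        Xa = np.zeros((4, 2, 1))
        Xb = np.zeros((4, 2, 1))
        Xb[:, 0, 0] = delta
        X = np.concatenate([Xa, Xb])
        d = neural_distance(X, np.arange(4), np.arange(4, 8))
        assert d == pytest.approx(delta / delta, abs=1e-9)

    def test_degenerate_data_rejected(self):
        X = np.zeros((6, 3, 2))
        with pytest.raises(ValueError):
            neural_distance(X, np.arange(3), np.arange(3, 6))


class TestEncodingStrength:
    def test_gain_recovery_and_control_null(self):
        t = make_tensor(primitive_gain=1.5, location_gain=0.0)
        res = encoding_strengths_from_tensor(t, "primitive", "location",
                                             window=None, seed=0)
        assert res["primitive"] > 0.2
        assert abs(res["location"]) < 0.05

    def test_label_permutation_destroys_encoding(self):
        t = make_tensor(primitive_gain=1.5)
        rng = np.random.default_rng(3)
        t.trials["primitive"] = rng.permutation(t.trials["primitive"].to_numpy())
        res = encoding_strengths_from_tensor(t, "primitive", "location",
                                             window=None, seed=0)
        assert abs(res["primitive"]) < 0.1

    def test_monotone_in_gain(self):
        vals = []
        for g in (0.0, 0.5, 1.0, 2.0):
            t = make_tensor(primitive_gain=g, seed=4)
            vals.append(encoding_strengths_from_tensor(
                t, "primitive", "location", window=None, seed=0)["primitive"])
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_no_qualifying_pair_raises(self):
        tab = pd.DataFrame({"primitive_a": ["a"], "primitive_b": ["a"],
                            "location_a": ["L"], "location_b": ["R"],
                            "dstar": [0.1]})
        with pytest.raises(ValueError):
            encoding_strength(tab, "primitive", ("location",))


class TestCompareRegions:
    def _dataset(self, rng, offset=0.0, n=60):
        pair_ids = np.arange(n) % 20
        return pd.DataFrame({"pair_id": pair_ids,
                             "dstar": 0.3 + 0.02 * pair_ids / 20
                             + rng.normal(0, 0.02, n) + offset})

    def test_identical_regions_not_significant(self):
        rng = np.random.default_rng(5)
        d = self._dataset(rng)
        res = compare_regions({"A": {"v": d}, "B": {"v": d.copy()}}, ["v"])
        row = res.per_pair.iloc[0]
        assert abs(row["beta_r"]) < 1e-9

    def test_injected_offset_recovered(self):
        rng = np.random.default_rng(6)
        base = self._dataset(rng, n=200)
        shifted = base.copy()
        shifted["dstar"] = shifted["dstar"] + 0.1
        res = compare_regions({"A": {"v": base}, "B": {"v": shifted}}, ["v"])
        row = res.per_pair.iloc[0]
        assert row["beta_r"] == pytest.approx(0.1, rel=0.05)
        assert row["p_corrected"] < 0.05
        assert res.beaten_counts.loc["B", "v"] == 1

    def test_eight_regions_two_variables_give_56_comparisons(self):
        rng = np.random.default_rng(7)
        regions = ["M1", "PMd", "PMv", "SMA", "preSMA", "dlPFC", "vlPFC", "FP"]
        datasets = {r: {"v1": self._dataset(rng), "v2": self._dataset(rng)}
                    for r in regions}
        res = compare_regions(datasets, ["v1", "v2"])
        assert res.n_comparisons == 56
        assert len(res.per_pair) == 56
        assert res.beaten_counts.to_numpy().max() <= 7


class TestCrossConditionDecoding:
    @pytest.mark.parametrize("raw,expect", [(0.25, 0.0), (1.0, 1.0),
                                            (0.625, 0.5)])
    def test_rescaling_formula(self, raw, expect):
        assert rescale_accuracy(raw, 4) == pytest.approx(expect)

    def test_invariant_code_generalizes(self):
        t = make_tensor(primitive_gain=1.5, n_units=30, n_trials=15)
        res = cross_condition_decode_tensor(t, "primitive", "location", "L",
                                            window=None, seed=0)
        assert res["cross_rescaled"] >= 0.8

    def test_location_specific_code_does_not_generalize(self):
        t = make_tensor(primitive_gain=0.0, interaction_gain=1.5,
                        n_units=30, n_trials=15)
        res = cross_condition_decode_tensor(t, "primitive", "location", "L",
                                            window=None, seed=0)
        assert res["cross_rescaled"] <= 0.2
        assert res["within_rescaled"] >= 0.8

    def test_missing_class_rejected(self):
        t = make_tensor()
        t.trials.loc[(t.trials["primitive"] == "a")
                     & (t.trials["location"] == "R"), "location"] = "L"
        from actionsym.population_analysis import cross_condition_decode
        with pytest.raises(ValueError):
            cross_condition_decode(t.rates,
                                   t.trials["primitive"].to_numpy(),
                                   t.trials["location"].to_numpy(), "R")


def morph_conditions():
    fracs = np.linspace(0, 1, 7)
    conds = ["P1", "U1", "U1", "A", "U2", "U2", "P2"]
    return pd.DataFrame([{"prim_a": "p1", "prim_b": "p2", "morph_fraction": f,
                          "location": "L", "size": "M", "task_type": "single",
                          "trial_condition": c}
                         for f, c in zip(fracs, conds)])


class TestNeuralAlignment:
    def test_reference_centroid_scores_near_end(self):
        des = a.PopulationDesign(conditions=morph_conditions(), n_units=30,
                                 n_trials_per_condition=8, primitive_gain=1.5,
                                 noise_sd=1.0, categorical_flag=True, seed=7)
        t = a.simulate_population(des)
        out = neural_primitive_alignment(t.rates, t.trials, t.time, window=None)
        means = out.groupby("trial_condition")["a_neural"].mean()
        assert means["P1"] < 0.35
        assert means["P2"] > 0.65

    def test_categorical_tensor_splits_ambiguous_trials(self):
        des = a.PopulationDesign(conditions=morph_conditions(), n_units=30,
                                 n_trials_per_condition=8, primitive_gain=1.5,
                                 noise_sd=1.0, categorical_flag=True, seed=8)
        t = a.simulate_population(des)
        out = neural_primitive_alignment(t.rates, t.trials, t.time, window=None)
        st = hallmark_stats_from_alignment(out)
        assert st["A2"] - st["A1"] > 0.3

    def test_linear_tensor_alignment_linear_in_fraction(self):
        des = a.PopulationDesign(conditions=morph_conditions(), n_units=30,
                                 n_trials_per_condition=8, primitive_gain=1.5,
                                 noise_sd=1.0, categorical_flag=False, seed=9)
        t = a.simulate_population(des)
        out = neural_primitive_alignment(t.rates, t.trials, t.time, window=None)
        g = out.groupby("morph_fraction")["a_neural"].mean()
        r = np.corrcoef(g.index, g.values)[0, 1]
        assert r * r > 0.95

    def test_missing_references_rejected(self):
        des = a.PopulationDesign(conditions=morph_conditions(), n_units=10,
                                 n_trials_per_condition=3, seed=0)
        t = a.simulate_population(des)
        t.trials.loc[t.trials["trial_condition"] == "P1", "trial_condition"] = "U1"
        with pytest.raises(ValueError):
            neural_primitive_alignment(t.rates, t.trials, t.time, window=None)


class TestPairwisePrimitiveDecoding:
    def test_unit_matching_and_separable_codes(self):
        conds = basic_conditions("abc")
        tensors = {}
        for reg, nu in [("PMv", 24), ("M1", 16)]:
            tensors[reg] = make_tensor(primitive_gain=2.0, n_units=nu,
                                       n_trials=6, seed=11, conds=conds)
        res = pairwise_primitive_decoding(tensors, window=None,
                                          n_subsample_repeats=3, seed=0)
        for reg, acc in res.items():
            off = acc.to_numpy()[~np.isnan(acc.to_numpy())]
            assert np.all(off > 0.9)

    def test_no_signal_near_chance(self):
        conds = basic_conditions("abc")
        tensors = {"PMv": make_tensor(primitive_gain=0.0, n_units=20,
                                      n_trials=8, seed=12, conds=conds)}
        res = pairwise_primitive_decoding(tensors, window=None,
                                          n_subsample_repeats=3, seed=0)
        off = res["PMv"].to_numpy()
        off = off[~np.isnan(off)]
        assert abs(off.mean() - 0.5) < 0.25


class TestInitialReachCorrection:
    def _tensor_with_reach(self, r):
        conds = pd.DataFrame([{"primitive": p, "location": "L", "size": "M",
                               "task_type": tt, "first_stroke": fs}
                              for p in "abc"
                              for tt, fs in [("single", True),
                                             ("character", True),
                                             ("character", False)]])
        des = a.PopulationDesign(conditions=conds, n_units=12,
                                 n_trials_per_condition=8, primitive_gain=1.0,
                                 noise_sd=0.5, seed=2)
        t = a.simulate_population(des)
        t.rates[t.trials["first_stroke"].to_numpy()] += r
        return t

    def test_additive_reach_effect_recovered(self):
        r = 1.7
        t = self._tensor_with_reach(r)
        corrected, beta_f = correct_initial_reach(t)
        assert beta_f.mean() == pytest.approx(r, abs=0.15)
        first = t.trials["first_stroke"].to_numpy()
        m_first = corrected.rates[first].mean()
        m_rest = corrected.rates[~first].mean()
        assert abs(m_first - m_rest) < 0.1

    def test_zero_effect_is_noop(self):
        t = self._tensor_with_reach(0.0)
        corrected, beta_f = correct_initial_reach(t)
        assert abs(beta_f.mean()) < 0.1

    def test_non_first_strokes_unchanged(self):
        t = self._tensor_with_reach(1.0)
        corrected, _ = correct_initial_reach(t)
        rest = ~t.trials["first_stroke"].to_numpy()
        assert np.array_equal(corrected.rates[rest], t.rates[rest])

    def test_all_first_strokes_rejected(self):
        t = make_tensor()
        with pytest.raises(ValueError):
            correct_initial_reach(t)


class TestFVAF:
    def _linear_data(self, seed=1, n=4000, noise=0.0, lag_samples=0):
        rng = np.random.default_rng(seed)
        from scipy.ndimage import gaussian_filter1d
        v = gaussian_filter1d(rng.normal(0, 1, size=(n, 2)), 5, axis=0)
        E = rng.normal(0, 1, size=(10, 2))
        f = np.empty((n, 10))
        if lag_samples > 0:
            f[:-lag_samples] = v[lag_samples:] @ E.T
            f[-lag_samples:] = 0.0
        else:
            f = v @ E.T
        f = f + noise * rng.normal(size=f.shape)
        labels = np.repeat(np.arange(4), n // 4)
        return f, v, labels

    def test_exact_linear_gives_unit_fvaf(self):
        f, v, labels = self._linear_data()
        res = fvaf_kinematics(f, v, labels)
        at_zero = res["fvaf"][np.argmin(np.abs(res["lags_s"]))]
        assert at_zero > 1 - 1e-9

    def test_zero_predictor_gives_zero_fvaf(self):
        rng = np.random.default_rng(2)
        f = rng.normal(size=(600, 10))
        v = np.zeros((600, 2))
        v[0, 0] = 1e-6   # avoid the all-zero guard; predictor still ~ 0
        labels = np.repeat(np.arange(3), 200)
        res = fvaf_kinematics(f, v, labels)
        at_zero = res["fvaf"][np.argmin(np.abs(res["lags_s"]))]
        assert at_zero == pytest.approx(0.0, abs=0.01)

    def test_injected_lag_recovered(self):
        f, v, labels = self._linear_data(noise=0.05, lag_samples=10)
        res = fvaf_kinematics(f, v, labels)
        assert res["peak_lag_s"] == pytest.approx(-0.1, abs=1e-9)

    def test_all_zero_velocity_rejected(self):
        with pytest.raises(ValueError):
            fvaf_kinematics(np.zeros((100, 10)), np.zeros((100, 2)),
                            np.repeat(np.arange(4), 25))

    def test_fvaf_never_exceeds_one(self):
        f, v, labels = self._linear_data(noise=0.5)
        res = fvaf_kinematics(f, v, labels)
        assert np.all(res["fvaf"] <= 1.0)


class TestFixationDecoding:
    def _setup(self, planned_only=False):
        rng = np.random.default_rng(3)
        n_units = 20
        w = {p: rng.normal(0, 1, n_units) for p in "abc"}
        X = np.vstack([w[p] + 0.3 * rng.normal(0, 1, (30, n_units))
                       for p in "abc"])
        y = np.repeat(list("abc"), 30)
        shapes = {"a": (0, 0), "b": (100, 0), "c": (200, 0)}
        fix = pd.DataFrame({"fix_x": [0.0, 100.0, 300.0],
                            "fix_y": [0.0, 0.0, 0.0],
                            "planned_primitive": ["a", "a", "a"]})
        key = "a" if planned_only else None
        act = np.vstack([(w["a"] if planned_only else w["a"]),
                         (w["a"] if planned_only else w["b"]),
                         w["c"]]) + 0.1 * rng.normal(size=(3, n_units))
        return X, y, act, fix, shapes

    def test_distant_fixation_excluded(self):
        X, y, act, fix, shapes = self._setup()
        out = fixation_decoding(X, y, act, fix, shapes)
        assert out.attrs["n_excluded"] == 1
        assert len(out) == 2

    def test_probabilities_in_unit_interval(self):
        X, y, act, fix, shapes = self._setup()
        out = fixation_decoding(X, y, act, fix, shapes)
        probs = out[[c for c in out.columns if c.startswith("p_")]]
        assert ((probs >= 0) & (probs <= 1)).all().all()

    def test_planned_code_dominates_fixated(self):
        # activity encodes the planned primitive only: its probability beats
        # the fixated primitive's at fixations away from the planned shape
        X, y, act, fix, shapes = self._setup(planned_only=True)
        out = fixation_decoding(X, y, act, fix, shapes)
        row = out[out["fixated_primitive"] == "b"].iloc[0]
        assert row["p_planned"] > row["p_fixated"]


def test_distance_table_symmetric_layout():
    t = make_tensor(n_trials=6)
    tab = condition_distance_table(
        t.rates, t.trials, ("primitive", "location"))
    # every unordered condition pair appears exactly once
    n_conds = t.trials.groupby(["primitive", "location"]).ngroups
    assert len(tab) == n_conds * (n_conds - 1) // 2
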