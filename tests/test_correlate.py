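"""Spearman/FDR machinery, ROI pruning, hypothesis pipeline, power."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from painweights.correlate import (
    HypothesisMap,
    ROIRecord,
    bh_fdr,
    power_corr,
    prune_redundant,
    run_exploratory,
    run_hypothesised,
    simulate_power,
    spearman,
)


def exact_permutation_p(x, y, observed_rho, tails=2):
    """Brute-force two-sided p: enumerate all orderings of y."""
    n = len(x)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = stats.spearmanr(x, [y[i] for i in perm]).statistic
        if tails == 2:
            count += abs(r) >= abs(observed_rho) - 1e-12
        else:
            count += r >= observed_rho - 1e-12
        total += 1
    return count / total


def step_up_bh(p):
    """Independent oracle: literal Benjamini-Hochberg step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return adj


class TestSpearman:
    def test_monotone_transform_gives_unity(self, rng):
        x = rng.uniform(0, 1, 20)
        rho, _ = spearman(x, np.exp(3 * x))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, -(x**3))
        assert rho == pytest.approx(-1.0)

    def test_known_small_sample(self):
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        y = np.array([1, 3, 2, 5, 4], dtype=float)
        rho, p = spearman(x, y)
        assert rho == pytest.approx(0.8)

    def test_p_matches_exact_permutation_distribution(self, rng):
        for n in (5, 6, 7):
            x = rng.uniform(0, 1, n)
            y = rng.uniform(0, 1, n)
            rho, p = spearman(x, y)
            exact = exact_permutation_p(list(x), list(y), rho)
            assert abs(p - exact) < 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(10), np.arange(10.0))

    def test_one_tailed_halves_p_for_positive_rho(self, rng):
        x = rng.uniform(0, 1, 30)
        y = x + rng.normal(0, 0.5, 30)
        _, p2 = spearman(x, y, tails=2)
        _, p1 = spearman(x, y, tails=1)
        assert p1 == pytest.approx(p2 / 2, rel=1e-9)


class TestBhFdr:
    def test_hand_worked_example(self):
        out = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_and_tied_inputs(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_fdr([0.04, 0.04, 0.04]), 0.04)

    def test_adjusted_at_least_raw_and_order_preserved(self, rng):
        p = rng.uniform(0, 1, 20)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        # adjustment is monotone in the raw p-values
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8)
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_step_up_definition(self, p):
        assert np.allclose(bh_fdr(p), step_up_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def make_roi(structure, hemisphere, window, activity, offset=(0.0, 0.0, 0.0)):
    from painweights.correlate import STRUCTURE_CENTROIDS

    centre = np.asarray(STRUCTURE_CENTROIDS[(structure, hemisphere)])
    return ROIRecord(
        structure=structure,
        hemisphere=hemisphere,
        mni=tuple(centre + np.asarray(offset)),
        window=window,
        activity=activity,
    )


class TestPruneRedundant:
    def test_redundant_pair_keeps_nearer_roi(self, rng):
        base = rng.standard_normal(40)
        near = make_roi("postcentral gyrus", "R", "late_anticipation", base,
                        offset=(2, 0, 0))
        far = make_roi("postcentral gyrus", "R", "late_anticipation",
                       base + rng.normal(0, 0.1, 40), offset=(10, 5, 3))
        kept, dropped = prune_redundant([far, near])
        assert kept == [near]
        assert dropped[0]["structure"] == "postcentral gyrus"

    def test_uncorrelated_pair_kept(self, rng):
        a = make_roi("postcentral gyrus", "R", "late_anticipation",
                     rng.standard_normal(40))
        b = make_roi("postcentral gyrus", "R", "late_anticipation",
                     rng.standard_normal(40), offset=(8, 0, 0))
        kept, dropped = prune_redundant([a, b])
        assert len(kept) == 2 and not dropped

    def test_boundary_rho_exactly_point7_kept(self):
        # n = 9 with sum of squared rank differences 36 gives
        # rho = 1 - 6*36/(9*80) = 0.7 exactly; strict rule keeps both
        x = np.arange(9.0)
        y = np.array([3, 1, 2, 0, 7, 5, 6, 4, 8], dtype=float)
        assert stats.spearmanr(x, y).statistic == pytest.approx(0.7, abs=1e-12)
        a = make_roi("postcentral gyrus", "R", "late_anticipation", x)
        b = make_roi("postcentral gyrus", "R", "late_anticipation", y,
                     offset=(9, 0, 0))
        kept, _ = prune_redundant([a, b])
        assert len(kept) == 2

    def test_input_order_invariance(self, rng):
        base = rng.standard_normal(40)
        rois = [
            make_roi("postcentral gyrus", "R", "late_anticipation",
                     base + rng.normal(0, 0.05, 40), offset=(d, 0, 0))
            for d in (12, 2, 7)
        ]
        kept_fwd, _ = prune_redundant(rois)
        kept_rev, _ = prune_redundant(rois[::-1])
        assert {r.name for r in kept_fwd} == {r.name for r in kept_rev}

    def test_missing_centroid_is_config_error(self, rng):
        roi = ROIRecord("mystery area", "L", (0, 0, 0), "baseline",
                        rng.standard_normal(40))
        base = roi.activity + rng.normal(0, 0.01, 40)
        twin = ROIRecord("mystery area", "L", (5, 0, 0), "baseline", base)
        with pytest.raises(ValueError, match="centre-of-mass"):
            prune_redundant([roi, twin])


def cohort_tables(rng, n=40):
    params = pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "w_stim": rng.lognormal(-5, 0.5, n),
            "w_cue": rng.lognormal(-6, 0.5, n),
            "w_bias": rng.lognormal(-7, 0.5, n),
            "eta": rng.normal(0, 0.5, n),
            "mu": rng.normal(50, 15, n),
        }
    )
    p2 = pd.DataFrame(
        {"participant_id": params.participant_id, "amplitude": rng.normal(5, 1.5, n)}
    )
    rois = [
        make_roi("postcentral gyrus", "R", "late_anticipation", rng.standard_normal(n)),
        make_roi("middle frontal gyrus", "L", "post_stimulation", rng.standard_normal(n)),
        make_roi("inferior temporal gyrus", "R", "late_anticipation", rng.standard_normal(n)),
    ]
    return params, rois, p2


class TestHypothesisPipeline:
    def test_abs_eta_negation_invariance(self, rng):
        params, rois, p2 = cohort_tables(rng)
        res1 = run_hypothesised(params, rois, p2)
        params_neg = params.copy()
        params_neg["eta"] = -params_neg["eta"]
        res2 = run_hypothesised(params_neg, rois, p2)
        eta1 = res1[res1.parameter == "abs_eta"].reset_index(drop=True)
        eta2 = res2[res2.parameter == "abs_eta"].reset_index(drop=True)
        pd.testing.assert_frame_equal(eta1, eta2)

    def test_families_are_per_parameter_and_window(self, rng):
        params, rois, p2 = cohort_tables(rng)
        res = run_hypothesised(params, rois, p2)
        roi_rows = res[res.target != "P2 amplitude"]
        for fam, grp in roi_rows.groupby("family"):
            assert grp.parameter.nunique() == 1
            assert grp.window.nunique() == 1
        p2_rows = res[res.target == "P2 amplitude"]
        assert set(p2_rows.parameter) == {"w_stim", "abs_eta", "mu"}
        assert (p2_rows.family == "p2").all()

    def test_adjusted_never_below_raw(self, rng):
        params, rois, p2 = cohort_tables(rng)
        res = run_hypothesised(params, rois, p2)
        assert (res.p_adjusted >= res.p_raw - 1e-12).all()

    def test_partition_with_exploratory_is_exact(self, rng):
        params, rois, p2 = cohort_tables(rng)
        hyp = run_hypothesised(params, rois, p2)
        exp = run_exploratory(params, rois, p2)
        both = pd.concat([hyp, exp])
        combos = both.groupby(["parameter", "target"]).size()
        assert (combos == 1).all()

    def test_empty_exploratory_when_map_covers_everything(self, rng):
        params, rois, p2 = cohort_tables(rng)
        windows = ("late_anticipation", "post_stimulation")
        full_map = HypothesisMap(
            roi_map={
                p: frozenset(
                    (r.structure, w) for r in rois for w in windows
                )
                for p in ("w_stim", "w_cue", "w_bias", "abs_eta", "mu")
            },
            p2_parameters=("w_stim", "w_cue", "w_bias", "abs_eta", "mu"),
        )
        exp = run_exploratory(params, rois, p2, hmap=full_map)
        assert exp.empty

    def test_null_cohort_type_one_control(self):
        # fraction of null (parameter, window) families with any adjusted
        # p < 0.05 stays near the nominal level
        reps, hits, fams = 100, 0, 0
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            params, rois, p2 = cohort_tables(rng, n=40)
            res = run_hypothesised(params, rois, p2)
            for _, grp in res.groupby("family"):
                fams += 1
                hits += (grp.p_adjusted < 0.05).any()
        rate = hits / fams
        se = np.sqrt(0.05 * 0.95 / fams)
        assert rate <= 0.05 + 3 * se

    def test_dominant_bias_links_mu_to_mean_rating(self):
        from painweights.cohort import PopulationSpec, generate_cohort

        pop = PopulationSpec(
            n_participants=40,
            nu2_logmean=np.log(25.0),  # tight bias: ratings hug mu
            beta2_logmean=np.log(5000.0),
            rho2_logmean=np.log(5000.0),
            seed=42,
        )
        bundle = generate_cohort(pop)
        mean_rating = (
            bundle.trials.groupby("participant_id")["rating"].mean().to_numpy()
        )
        rho, _ = spearman(bundle.params_truth["mu"].to_numpy(), mean_rating)
        assert rho > 0.8


class TestPower:
    def test_null_effect_power_tends_to_alpha(self):
        assert power_corr(50, 1e-9, alpha=0.05, tails=1) == pytest.approx(
            0.05, abs=1e-3
        )

    @pytest.mark.parametrize("n", [70, 63])
    def test_planned_sample_sizes_reach_point8(self, n):
        assert power_corr(n, 0.33, alpha=0.05, tails=1) >= 0.8

    def test_simulation_agrees_with_closed_form(self):
        analytic = power_corr(40, 0.4, alpha=0.05, tails=2)
        sim = simulate_power(40, 0.4, alpha=0.05, tails=2, reps=20000, seed=9)
        assert sim == pytest.approx(analytic, abs=0.02)

    def test_invalid_domain_rejected(self):
        with pytest.raises(ValueError):
            power_corr(3, 0.3)
        with pytest.raises(ValueError):
            power_corr(50, 1.2)
        with pytest.raises(ValueError):
            simulate_power(50, 0.3, alpha=2.0)
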