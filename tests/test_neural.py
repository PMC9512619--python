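"""Alignment, z-scoring, gap-statistic clustering, typing, distributions."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from fidgetlab import neural, synthdata
from fidgetlab.behavior import FidgetEvent
from fidgetlab.neural import ThresholdCriterion
from fidgetlab.synthdata import SynthConfig


def _simulated_mean_z(n, noise=0.1, probs=(0.528, 0.139, 0.120, 0.213), seed=0):
    """Mean-z matrices drawn directly from the four archetypes."""
    rng = np.random.default_rng(seed)
    tpl = synthdata.generate_response_templates()
    types = rng.choice(4, size=n, p=np.asarray(probs))
    scale = {"neutral": 0.0, "phasic": 5.0, "active": 3.3, "depressed": 2.0}
    x = np.empty((n, 300))
    labels = []
    for i, ti in enumerate(types):
        lab = synthdata.TYPE_LABELS[ti]
        labels.append(lab)
        x[i] = scale[lab] * tpl[lab].waveform + noise * rng.standard_normal(300)
    return x, np.asarray(labels)


class TestAlignAndZscore:
    def test_trial_shape_and_windows(self, trace_session):
        _, sess = trace_session
        z, raw = neural.align_and_zscore(sess.dff, sess.truth["events"])
        assert z.data.shape[2] == 300
        assert raw.data.shape == z.data.shape
        assert z.n_trials == len(sess.truth["events"])

    def test_baseline_mean_zero_sd_one(self, trace_session):
        # per-trial z-scoring leaves every baseline with mean 0 and SD 1
        _, sess = trace_session
        z, _ = neural.align_and_zscore(sess.dff, sess.truth["events"])
        base = z.data[:, :, :100]
        assert np.nanmax(np.abs(base.mean(axis=2))) < 1e-9
        assert np.nanmax(np.abs(base.std(axis=2) - 1.0)) < 1e-9

    def test_event_without_full_window_dropped(self):
        dff = np.random.default_rng(0).standard_normal((3, 400))
        z, _ = neural.align_and_zscore(dff, [FidgetEvent(50, 70), FidgetEvent(150, 170)])
        assert z.n_dropped_events == 1
        assert list(z.onsets) == [150]

    def test_zero_baseline_sd_trial_excluded(self):
        dff = np.ones((1, 400))
        dff[0, 250:] += np.arange(150)
        with pytest.warns(UserWarning, match="zero baseline SD"):
            z, _ = neural.align_and_zscore(dff, [FidgetEvent(150, 170)])
        assert np.isnan(z.data[0, 0]).all()
        assert z.n_excluded_trials == 1

    def test_min_trials_mask(self):
        dff = np.random.default_rng(1).standard_normal((2, 2000))
        events = [FidgetEvent(200 + 400 * i, 230 + 400 * i) for i in range(4)]
        z, raw = neural.align_and_zscore(dff, events)
        _, keep = neural.mean_responses(z, raw, min_trials=3)
        assert keep.all()
        _, keep5 = neural.mean_responses(z, raw, min_trials=5)
        assert not keep5.any()


class TestGapStatistic:
    def test_four_archetypes_recovered(self):
        x, _ = _simulated_mean_z(240, noise=0.1, seed=1)
        g = neural.cluster_mean_responses(x, k_range=range(1, 7), n_ref=8, seed=0)
        assert g.optimal_k == 4

    def test_single_gaussian_gives_one(self):
        rng = np.random.default_rng(2)
        x = 0.2 * rng.standard_normal((300, 300))
        g = neural.cluster_mean_responses(x, k_range=range(1, 7), n_ref=8, seed=0)
        assert g.optimal_k == 1

    def test_same_seed_identical_assignments(self):
        x, _ = _simulated_mean_z(150, seed=3)
        g1 = neural.cluster_mean_responses(x, k_range=range(2, 6), n_ref=5, seed=9)
        g2 = neural.cluster_mean_responses(x, k_range=range(2, 6), n_ref=5, seed=9)
        assert np.array_equal(g1.labels, g2.labels)
        assert g1.optimal_k == g2.optimal_k

    def test_neuron_order_invariance(self):
        x, _ = _simulated_mean_z(150, seed=4)
        perm = np.random.default_rng(0).permutation(len(x))
        g1 = neural.cluster_mean_responses(x, k_range=[4], n_ref=3, seed=0)
        g2 = neural.cluster_mean_responses(x[perm], k_range=[4], n_ref=3, seed=0)
        assert adjusted_rand_score(g1.labels[perm], g2.labels) == 1.0

    def test_empty_k_range_rejected(self):
        with pytest.raises(ValueError, match="k_range"):
            neural.cluster_mean_responses(np.zeros((10, 5)), k_range=[])

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValueError, match="neurons"):
            neural.cluster_mean_responses(np.zeros((3, 5)), k_range=[8])

    def test_tibshirani_rule_available(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((200, 10))
        g = neural.cluster_mean_responses(
            x, k_range=range(1, 5), n_ref=5, seed=0, selection_rule="tibshirani"
        )
        assert g.optimal_k == 1


class TestLabelClusters:
    def test_flat_centroid_neutral(self):
        assert neural.label_clusters(np.zeros((1, 300))) == ["neutral"]

    def test_sustained_positive_is_active(self):
        c = np.zeros((1, 300))
        c[0, 100:] = 1.0
        assert neural.label_clusters(c) == ["active"]

    def test_sustained_negative_is_depressed(self):
        c = np.zeros((1, 300))
        c[0, 100:] = -1.0
        assert neural.label_clusters(c) == ["depressed"]

    def test_transient_is_phasic(self):
        tpl = synthdata.generate_response_templates()
        c = 5.0 * tpl["phasic"].waveform[None, :]
        assert neural.label_clusters(c) == ["phasic"]

    def test_ambiguous_falls_back_with_warning(self):
        c = np.zeros((1, 300))
        c[0, 140:160] = 0.8  # tiny mean, sizable peak
        with pytest.warns(UserWarning, match="ambiguous"):
            labels = neural.label_clusters(c)
        assert labels[0] in synthdata.TYPE_LABELS

    def test_noise_free_recovery_is_exact(self):
        x, truth = _simulated_mean_z(200, noise=0.02, seed=6)
        asg = neural.assign_response_types(x, k=4, seed=0)
        assert adjusted_rand_score(truth, asg.cluster_id) == 1.0
        assert (asg.type_label.to_numpy() == truth).all()

    def test_default_noise_accuracy(self, trace_session):
        # full chain on the default generator: >= 90% agreement with truth
        _, sess = trace_session
        z, raw = neural.align_and_zscore(sess.dff, sess.truth["events"])
        resp, keep = neural.mean_responses(z, raw)
        asg = neural.assign_response_types(resp.mean_z, k=4, seed=0)
        truth = sess.truth["neurons"].type_label.to_numpy()
        assert np.mean(asg.type_label.to_numpy() == truth) >= 0.90


class TestThresholdCriteria:
    def _responses(self, mean_post, max_post):
        n = len(mean_post)
        return neural.MeanResponses(
            mean_z=np.zeros((n, 300)),
            n_trials=np.full(n, 10),
            mean_dff_post=np.asarray(mean_post),
            max_dff_post=np.asarray(max_post),
        )

    def _assignments(self, labels):
        return pd.DataFrame(
            {
                "neuron_id": np.arange(len(labels)),
                "cluster_id": np.zeros(len(labels), int),
                "type_label": labels,
                "distance_to_centroid": np.zeros(len(labels)),
            }
        )

    def test_mean_criterion_boundary(self):
        # 7% mean passes the >6% criterion; 4% max fails the >5% criterion
        resp = self._responses([0.07, 0.03], [0.2, 0.04])
        asg = self._assignments(["phasic", "active"])
        out = neural.apply_threshold_criteria(asg, resp, ThresholdCriterion("mean_post", 0.06))
        assert list(out.type_label) == ["phasic", "criteria neutral"]
        out2 = neural.apply_threshold_criteria(asg, resp, ThresholdCriterion("max_post", 0.05))
        assert list(out2.type_label) == ["phasic", "criteria neutral"]

    def test_neutral_never_relabeled(self):
        resp = self._responses([0.0], [0.0])
        asg = self._assignments(["neutral"])
        out = neural.apply_threshold_criteria(asg, resp, ThresholdCriterion("mean_post", 0.06))
        assert list(out.type_label) == ["neutral"]

    def test_depressed_passes_on_magnitude(self):
        resp = self._responses([-0.08], [-0.1])
        asg = self._assignments(["depressed"])
        out = neural.apply_threshold_criteria(asg, resp, ThresholdCriterion("mean_post", 0.06))
        assert list(out.type_label) == ["depressed"]

    def test_stricter_threshold_gives_subset(self):
        rng = np.random.default_rng(7)
        means = rng.uniform(0, 0.15, size=50)
        resp = self._responses(means, means * 2)
        asg = self._assignments(["active"] * 50)
        loose = neural.apply_threshold_criteria(asg, resp, ThresholdCriterion("mean_post", 0.05))
        strict = neural.apply_threshold_criteria(asg, resp, ThresholdCriterion("mean_post", 0.10))
        kept_loose = set(loose.loc[loose.type_label != "criteria neutral", "neuron_id"])
        kept_strict = set(strict.loc[strict.type_label != "criteria neutral", "neuron_id"])
        assert kept_strict <= kept_loose

    def test_invalid_criterion_rejected(self):
        with pytest.raises(ValueError):
            ThresholdCriterion("median_post", 0.05)
        with pytest.raises(ValueError):
            ThresholdCriterion("mean_post", 0.0)


class TestTypeDistribution:
    def _toy(self, n_per_area=5000, probs=(0.528, 0.139, 0.120, 0.213), seed=0):
        rng = np.random.default_rng(seed)
        areas = ["VISp", "VISpm", "VISal", "VISl"]
        rows, labels = [], []
        for ai, area in enumerate(areas):
            types = rng.choice(4, size=n_per_area, p=np.asarray(probs))
            for t in types:
                rows.append(
                    {
                        "neuron_id": len(rows),
                        "area": area,
                        "depth_um": [175, 275, 350, 375][ai],
                        "cre_line": "Cux2",
                    }
                )
                labels.append(synthdata.TYPE_LABELS[t])
        meta = pd.DataFrame(rows)
        asg = pd.DataFrame(
            {
                "neuron_id": meta.neuron_id,
                "cluster_id": 0,
                "type_label": labels,
                "distance_to_centroid": 0.0,
            }
        )
        return asg, meta

    def test_percentages_sum_to_100(self):
        asg, meta = self._toy(n_per_area=200)
        table = neural.type_distribution(asg, meta, "area")
        pct = table[[c for c in table.columns if c.startswith("pct_")]]
        assert np.allclose(pct.sum(axis=1), 100.0, atol=1e-9)

    def test_counts_sum_to_total(self):
        asg, meta = self._toy(n_per_area=200)
        table = neural.type_distribution(asg, meta, "area")
        n = table[[c for c in table.columns if c.startswith("n_")]]
        assert n.to_numpy().sum() == len(asg)

    def test_homogeneous_cohort_inter_area_spread(self):
        # equal generating prevalences: max inter-area difference in any
        # type's percentage < 5 points at n = 5000 per area
        asg, meta = self._toy(n_per_area=5000)
        table = neural.type_distribution(asg, meta, "area")
        pct = table[[c for c in table.columns if c.startswith("pct_")]]
        assert (pct.max(axis=0) - pct.min(axis=0)).max() < 5.0

    def test_layer_mapping(self):
        asg, meta = self._toy(n_per_area=50)
        table = neural.type_distribution(asg, meta, "layer")
        assert set(table.index) == {"L2/3", "L4", "L5"}  # 350 merges into L4

    def test_unknown_depth_rejected(self):
        asg, meta = self._toy(n_per_area=10)
        meta.loc[0, "depth_um"] = 999
        with pytest.raises(ValueError, match="depth"):
            neural.type_distribution(asg, meta, "layer")


class TestCohortAssembly:
    def test_pooled_shapes_and_metadata(self):
        cfg = SynthConfig(session_duration=120.0, n_fidgets=6, n_neurons=30, seed=31)
        sessions = synthdata.generate_cohort(4, config=cfg)
        resp, meta = neural.cohort_mean_responses(sessions)
        assert resp.mean_z.shape == (120, 300)
        assert set(meta.area) == {"VISp", "VISpm", "VISal", "VISl"}
        assert (meta.groupby("session").size() == 30).all()
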