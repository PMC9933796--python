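"""Tasks, splits, AUC, sliding windows, bootstrap tests, cross-region."""

import numpy as np
import pandas as pd
import pytest

import vaxstance.classifier as clf
import vaxstance.evaluation as ev
import vaxstance.synthetic_data as sd
from vaxstance.features import ModalityToggles

# printed 4-way annotation counts of the emulated collection
PAPER_COUNTS = {"pro": 2625, "irrelevant": 1436, "skeptic": 676, "anti": 344}


def _paper_labels() -> np.ndarray:
    return np.concatenate([[lab] * n for lab, n in PAPER_COUNTS.items()])


class TestBinarize:
    def test_skeptic_task_positive_count(self):
        y = ev.binarize(_paper_labels(), ev.SKEPTIC_TASK)
        assert y.sum() == 1020 and len(y) == 5081

    def test_pro_task_positive_count(self):
        y = ev.binarize(_paper_labels(), ev.PRO_TASK)
        assert y.sum() == 2625

    def test_irrelevant_negative_under_both_tasks(self):
        for task in (ev.SKEPTIC_TASK, ev.PRO_TASK):
            assert ev.binarize(["irrelevant"], task).tolist() == [0]

    def test_unlabeled_rejected(self):
        with pytest.raises(ValueError):
            ev.binarize(["pro", "unlabeled"], ev.SKEPTIC_TASK)


def _tweet_frame(n, rng=None, t0="2021-01-01"):
    rng = rng or np.random.default_rng(0)
    ts = pd.Timestamp(t0) + pd.to_timedelta(
        rng.choice(n * 100, size=n, replace=False), unit="m"
    )
    return pd.DataFrame({"tweet_id": np.arange(n), "timestamp": ts})


class TestTemporalSplit:
    def test_collection_scale_split_sizes(self):
        split = ev.temporal_split(_tweet_frame(5081), train_frac=0.7)
        assert (len(split.train_idx), len(split.test_idx)) == (3556, 1525)

    def test_small_split_floor(self):
        split = ev.temporal_split(_tweet_frame(10), train_frac=0.7)
        assert (len(split.train_idx), len(split.test_idx)) == (7, 3)

    def test_train_strictly_precedes_test(self, rng):
        frame = _tweet_frame(200, rng)
        split = ev.temporal_split(frame)
        assert (
            frame["timestamp"].iloc[split.train_idx].max()
            <= frame["timestamp"].iloc[split.test_idx].min()
        )

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ev.temporal_split(_tweet_frame(10), train_frac=1.0)


class TestAUC:
    def test_perfect_ranking(self):
        assert ev.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert ev.auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_exhaustive_pair_count_example(self):
        assert ev.auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_single_class_signaled_distinctly(self):
        with pytest.raises(ev.UndefinedAUCError):
            ev.auc([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pair_comparison(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = rng.choice(np.linspace(0, 1, 13), size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        wins = 0.0
        pos, neg = scores[labels == 1], scores[labels == 0]
        for sp in pos:
            for sn in neg:
                wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        assert abs(ev.auc(scores, labels) - wins / (len(pos) * len(neg))) < 1e-12


class TestPrintedTableArithmetic:
    def test_relative_gain_recomputes_ablation_column(self):
        assert ev.relative_gain(0.840, 0.810) == 3.7
        assert ev.relative_gain(0.832, 0.810) == 2.7
        assert ev.relative_gain(0.786, 0.753) == 4.4

    @pytest.mark.parametrize(
        "same,out,printed,tol",
        [
            # skeptic task transfer matrix (same-domain, out-of-domain, printed diff%)
            (0.775, 0.771, 0.5, 0.1), (0.745, 0.711, 4.7, 0.1),
            (0.836, 0.826, 1.2, 0.1), (0.811, 0.783, 3.6, 0.1),
            (0.842, 0.780, 7.9, 0.1), (0.769, 0.717, 7.2, 0.1),
            (0.885, 0.874, 1.2, 0.1), (0.846, 0.803, 5.3, 0.1),
            (0.888, 0.876, 1.4, 0.1), (0.847, 0.832, 1.8, 0.1),
            # pro task; the two EU cells with tol 0.35 cannot be reproduced
            # to 0.1 from their printed AUC pairs under any rounding of the
            # out-of-domain-normalized formula (the source normalized those
            # two by the same-domain AUC instead: -5.99 -> -5.9, -5.5)
            (0.735, 0.779, -5.9, 0.35), (0.721, 0.687, 4.9, 0.1),
            (0.764, 0.806, -5.5, 0.35), (0.762, 0.728, 4.6, 0.1),
            (0.774, 0.773, 0.1, 0.1), (0.732, 0.680, 7.6, 0.1),
            (0.829, 0.843, -1.7, 0.1), (0.792, 0.757, 4.6, 0.1),
            (0.829, 0.837, -0.9, 0.1), (0.797, 0.762, 4.5, 0.1),
        ],
    )
    def test_diff_percent_reproduces_transfer_tables(self, same, out, printed, tol):
        # one-decimal rounding of the printed AUC pairs; the source tables
        # rounded from unrounded AUCs, so allow 0.1 on the last digit
        assert abs(ev.diff_percent(same, out) - printed) <= tol + 1e-9

    def test_equal_aucs_zero_diff(self):
        assert ev.diff_percent(0.8, 0.8) == 0.0


class TestRunConfig:
    def test_single_run_equals_direct_train_eval(self, skeptic_view):
        cfg = clf.ModelConfig(epochs=15, seed=0)
        toggles = ModalityToggles(use_text=True)
        result = ev.run_config(skeptic_view, toggles, n_runs=1, model_cfg=cfg, seed=7)
        direct = ev._fit_eval(
            skeptic_view.blocks, skeptic_view.y,
            skeptic_view.split.train_idx, skeptic_view.split.test_idx,
            toggles, clf.ModelConfig(epochs=15, seed=7),
            tweet_ids=skeptic_view.tweets["tweet_id"].to_numpy(),
        )
        assert result.aucs == [direct]

    def test_mean_within_run_range(self, skeptic_view):
        result = ev.run_config(
            skeptic_view, ModalityToggles(use_text=True), n_runs=3,
            model_cfg=clf.ModelConfig(epochs=15), seed=0,
        )
        assert min(result.aucs) <= result.mean <= max(result.aucs)

    def test_network_modality_adds_signal(self, skeptic_view):
        cfg = clf.ModelConfig(epochs=40)
        text = ev.run_config(skeptic_view, ModalityToggles(use_text=True),
                             n_runs=3, model_cfg=cfg, seed=0)
        both = ev.run_config(
            skeptic_view, ModalityToggles(use_text=True, use_raw_network=True),
            n_runs=3, model_cfg=cfg, seed=0,
        )
        assert both.mean > text.mean

    def test_mean_auc_invariant_to_tweet_id_relabeling(
        self, small_dataset, small_embedding, small_node_stats
    ):
        relabeled = sd.SimDataset(
            config=small_dataset.config,
            users=small_dataset.users,
            tweets=small_dataset.tweets.assign(
                tweet_id=small_dataset.tweets["tweet_id"] * 13 + 100_000
            ),
            text_vecs=small_dataset.text_vecs,
            replies=small_dataset.replies,
            truth=small_dataset.truth,
        )
        cfg = clf.ModelConfig(epochs=15)
        results = []
        for dataset in (small_dataset, relabeled):
            view = ev.prepare_view(dataset, ev.SKEPTIC_TASK,
                                   embedding=small_embedding,
                                   node_stats=small_node_stats)
            results.append(
                ev.run_config(view, ModalityToggles(use_text=True, use_history=True),
                              n_runs=2, model_cfg=cfg, seed=3).mean
            )
        assert results[0] == results[1]


class TestSlidingWindow:
    def test_perfect_classifier_all_windows_unit_auc(self):
        ts = pd.date_range("2021-05-01", periods=40, freq="6h")
        labels = np.tile([1, 0], 20)
        scores = np.where(labels == 1, 0.9, 0.1)
        series = ev.sliding_window(scores, labels, ts)
        defined = series["auc"].dropna()
        assert len(defined) > 0 and (defined == 1.0).all()

    def test_single_class_window_reports_ratio_only(self):
        ts = pd.to_datetime(["2021-05-01", "2021-05-02"])
        series = ev.sliding_window([0.4, 0.6], [1, 1], ts, window_days=7)
        assert series["auc"].isna().all()
        assert (series["pos_ratio"] == 1.0).all()

    def test_ratio_matches_direct_recount(self, rng):
        n = 300
        ts = pd.Timestamp("2021-05-01") + pd.to_timedelta(
            rng.integers(0, 30 * 24 * 60, size=n), unit="m"
        )
        labels = rng.integers(0, 2, size=n)
        series = ev.sliding_window(rng.random(n), labels, ts, window_days=7)
        for row in series.itertuples(index=False):
            mask = (ts >= row.window_start) & (
                ts < row.window_start + pd.Timedelta(days=7)
            )
            mask = np.asarray(mask)
            assert row.n == mask.sum()
            assert row.pos_ratio == labels[mask].mean()


class TestBootstrapCompare:
    def test_auc_lists_have_length_n_boot(self, skeptic_view):
        res = ev.bootstrap_compare(
            skeptic_view, ModalityToggles(use_text=True),
            ModalityToggles(use_text=True, use_history=True),
            n_boot=4, model_cfg=clf.ModelConfig(epochs=10), seed=0,
        )
        assert len(res.aucs_a) == len(res.aucs_b) == 4

    def test_too_few_bootstrap_samples_rejected(self, skeptic_view):
        with pytest.raises(ValueError):
            ev.bootstrap_compare(
                skeptic_view, ModalityToggles(use_text=True),
                ModalityToggles(use_history=True), n_boot=1,
            )

    def test_strong_network_signal_detected(self, skeptic_view):
        res = ev.bootstrap_compare(
            skeptic_view, ModalityToggles(use_text=True),
            ModalityToggles(use_text=True, use_raw_network=True),
            n_boot=8, model_cfg=clf.ModelConfig(epochs=40), seed=1,
        )
        assert res.p < 0.01 and res.t < 0


class TestCrossRegion:
    def test_matrix_structure_and_diff_consistency(self, small_dataset,
                                                   small_embedding):
        result = ev.cross_region(
            small_dataset, ModalityToggles(use_text=True, use_raw_network=True),
            ev.SKEPTIC_TASK, embedding=small_embedding, n_runs=1,
            model_cfg=clf.ModelConfig(epochs=15), seed=0,
        )
        mat = result.matrix
        assert list(mat.index) == ["EU", "US"] and list(mat.columns) == ["EU", "US"]
        assert np.isfinite(mat.to_numpy(dtype=float)).all()
        for r in ("EU", "US"):
            other = "US" if r == "EU" else "EU"
            assert result.diff[r] == ev.diff_percent(mat.loc[r, r], mat.loc[r, other])


class TestAUCProperties:
    """Hypothesis property tests against the exhaustive pair-counting oracle."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @staticmethod
    def _brute_force(scores, labels):
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        wins = sum(
            1.0 if sp > sn else (0.5 if sp == sn else 0.0)
            for sp in pos for sn in neg
        )
        return wins / (len(pos) * len(neg))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(st.integers(0, 8), st.integers(0, 1)),
            min_size=2, max_size=60,
        ).filter(lambda rows: 0 < sum(l for _, l in rows) < len(rows))
    )
    def test_auc_equals_pairwise_counting(self, rows):
        scores = [s / 8 for s, _ in rows]
        labels = [l for _, l in rows]
        assert abs(ev.auc(scores, labels) - self._brute_force(scores, labels)) < 1e-12

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        st.lists(
            st.tuples(st.integers(0, 8), st.integers(0, 1)),
            min_size=2, max_size=40,
        ).filter(lambda rows: 0 < sum(l for _, l in rows) < len(rows)),
        st.floats(0.1, 10.0),
    )
    def test_auc_invariant_under_monotone_score_transform(self, rows, scale):
        scores = np.array([s / 8 for s, _ in rows])
        labels = [l for _, l in rows]
        assert ev.auc(scores, labels) == ev.auc(scale * scores + 1.0, labels)
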