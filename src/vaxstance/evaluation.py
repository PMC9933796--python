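"""Evaluation protocols: tasks, temporal split, AUC, sliding windows,
bootstrap significance tests and the cross-region transfer matrix.

Two binary tasks are defined over the 4-way stance labels: *skeptic*
(vax-skeptic + anti-vaxxer vs the rest) and *pro* (pro-vaxxer vs the rest).
Evaluation is transductive and temporal: node embeddings may use the whole
collection graph, but labeled tweets are ordered by time and split 70/30,
training strictly preceding testing.  Reported AUCs average ten classifier
instances (seeds) on the identical split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.utils import resample

from . import classifier as clf
from .features import (
    FeatureMatrix,
    ModalityToggles,
    assemble,
    history_block,
    net_stats_block,
    raw_network_block,
)


@dataclass(frozen=True)
class TaskSpec:
    name: str
    positive_labels: frozenset


SKEPTIC_TASK = TaskSpec("skeptic", frozenset({"skeptic", "anti"}))
PRO_TASK = TaskSpec("pro", frozenset({"pro"}))
TASKS = {"skeptic": SKEPTIC_TASK, "pro": PRO_TASK}


def binarize(labels, task: TaskSpec) -> np.ndarray:
    """1 for the task's positive labels, 0 otherwise; rejects 'unlabeled'."""
    labels = np.asarray(labels, dtype=object)
    if (labels == "unlabeled").any():
        raise ValueError("binarize received unlabeled tweets")
    return np.isin(labels, list(task.positive_labels)).astype(np.int64)


@dataclass(frozen=True)
class SplitSpec:
    train_idx: np.ndarray  # positions into the labeled-tweet table
    test_idx: np.ndarray
    train_frac: float


def temporal_split(tweets: pd.DataFrame, train_frac: float = 0.7) -> SplitSpec:
    """Time-ordered 70/30 split: the first floor(train_frac*N) tweets train.

    Ordering is by timestamp with ties broken by tweet id; returned indices
    are positions into the input frame's row order.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    n = len(tweets)
    if n < 2:
        raise ValueError("need at least 2 tweets to split")
    order = np.lexsort(
        (tweets["tweet_id"].to_numpy(), tweets["timestamp"].to_numpy())
    )
    n_train = int(np.floor(train_frac * n))
    return SplitSpec(order[:n_train], order[n_train:], train_frac)


class UndefinedAUCError(ValueError):
    """AUC is undefined when only one class is present."""


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("both classes required for AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def relative_gain(value: float, baseline: float) -> float:
    """Percentage gain over a baseline AUC, rounded to one decimal."""
    return round((value - baseline) / baseline * 100.0, 1)


def diff_percent(auc_same: float, auc_out: float) -> float:
    """Same-domain vs out-of-domain relative AUC difference (one decimal)."""
    return round((auc_same - auc_out) / auc_out * 100.0, 1)


# ---------------------------------------------------------------------------
# feature preparation on a simulated (or loaded) dataset


@dataclass
class LabeledView:
    """Labeled-tweet slice of a dataset with per-task blocks precomputed."""

    tweets: pd.DataFrame  # labeled rows, original order
    y: np.ndarray
    blocks: dict[str, np.ndarray]
    split: SplitSpec
    task: TaskSpec

    @property
    def train_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.y), dtype=bool)
        mask[self.split.train_idx] = True
        return mask


def prepare_view(
    dataset,
    task: TaskSpec,
    embedding=None,
    node_stats: pd.DataFrame | None = None,
    train_frac: float = 0.7,
    history_train_only: bool = False,
) -> LabeledView:
    """Select labeled tweets, binarize, split temporally and build blocks."""
    labeled_mask = (dataset.tweets["label"] != "unlabeled").to_numpy()
    tweets = dataset.tweets.loc[labeled_mask].reset_index(drop=True)
    y = binarize(tweets["label"].to_numpy(), task)
    split = temporal_split(tweets, train_frac)
    train_mask = np.zeros(len(tweets), dtype=bool)
    train_mask[split.train_idx] = True

    blocks: dict[str, np.ndarray] = {
        "text": np.asarray(dataset.text_vecs)[labeled_mask],
        "history": history_block(
            tweets["user_id"].to_numpy(),
            tweets["timestamp"].to_numpy(),
            y,
            train_mask if history_train_only else None,
        ),
    }
    if node_stats is not None:
        blocks["net_stats"] = net_stats_block(
            tweets["user_id"].to_numpy(), node_stats, dataset.users
        )
    if embedding is not None:
        blocks["raw_network"] = raw_network_block(tweets["user_id"].to_numpy(), embedding)
    return LabeledView(tweets=tweets, y=y, blocks=blocks, split=split, task=task)


def _fit_eval(
    blocks: dict,
    y: np.ndarray,
    rows_train: np.ndarray,
    rows_test: np.ndarray,
    toggles: ModalityToggles,
    model_cfg: clf.ModelConfig,
    tweet_ids=None,
) -> float:
    """Assemble features for the given rows, train once and score the test rows."""
    rows = np.concatenate([rows_train, rows_test])
    sub_blocks = {k: np.asarray(v)[rows] for k, v in blocks.items()}
    train_mask = np.zeros(len(rows), dtype=bool)
    train_mask[: len(rows_train)] = True
    ids = np.asarray(tweet_ids)[rows] if tweet_ids is not None else rows
    fm = assemble(ids, sub_blocks, toggles, train_mask)
    model = clf.train(fm.X[train_mask], y[rows_train], model_cfg)
    scores = clf.predict_proba(model, fm.X[~train_mask])
    return auc(scores, y[rows_test])


@dataclass
class RunResult:
    aucs: list[float]
    toggles: ModalityToggles
    task: str
    seeds: list[int]

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0


def run_config(
    view: LabeledView,
    toggles: ModalityToggles,
    n_runs: int = 10,
    model_cfg: clf.ModelConfig | None = None,
    seed: int = 0,
) -> RunResult:
    """Mean test AUC over ``n_runs`` classifier seeds on the identical split."""
    model_cfg = model_cfg or clf.ModelConfig()
    seeds = [seed + i for i in range(n_runs)]
    aucs = [
        _fit_eval(
            view.blocks,
            view.y,
            view.split.train_idx,
            view.split.test_idx,
            toggles,
            _with_seed(model_cfg, s),
            tweet_ids=view.tweets["tweet_id"].to_numpy(),
        )
        for s in seeds
    ]
    return RunResult(aucs=aucs, toggles=toggles, task=view.task.name, seeds=seeds)


def _with_seed(cfg: clf.ModelConfig, seed: int) -> clf.ModelConfig:
    import dataclasses

    return dataclasses.replace(cfg, seed=seed)


# ---------------------------------------------------------------------------
# sliding window


def sliding_window(
    scores, labels, timestamps, window_days: int = 7
) -> pd.DataFrame:
    """Per-day series of AUC and positive ratio over [day, day + window).

    Windows containing a single class get a missing AUC but still report the
    ratio; empty windows are omitted.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    ts = pd.to_datetime(pd.Series(np.asarray(timestamps)))
    day0 = ts.min().normalize()
    day_last = ts.max().normalize()
    rows = []
    day = day0
    while day <= day_last:
        mask = ((ts >= day) & (ts < day + pd.Timedelta(days=window_days))).to_numpy()
        if mask.any():
            y = labels[mask]
            try:
                window_auc = auc(scores[mask], y)
            except UndefinedAUCError:
                window_auc = np.nan
            rows.append(
                {
                    "window_start": day,
                    "auc": window_auc,
                    "pos_ratio": float(np.mean(y == 1)),
                    "n": int(mask.sum()),
                }
            )
        day += pd.Timedelta(days=1)
    return pd.DataFrame(rows, columns=["window_start", "auc", "pos_ratio", "n"])


# ---------------------------------------------------------------------------
# bootstrap comparison


@dataclass
class BootstrapResult:
    t: float
    p: float
    aucs_a: list[float]
    aucs_b: list[float]


def bootstrap_compare(
    view: LabeledView,
    toggles_a: ModalityToggles,
    toggles_b: ModalityToggles,
    n_boot: int = 20,
    model_cfg: clf.ModelConfig | None = None,
    seed: int = 0,
    paired: bool = False,
    shared_samples: bool = False,
) -> BootstrapResult:
    """Compare two modality configurations over bootstrap samples.

    Each configuration is evaluated on ``n_boot`` training-testing bootstrap
    samples: train rows are resampled with replacement within the temporal
    training set and test rows within the test set, preserving the split
    proportions.  By default each configuration draws its own independent
    sample stream and the two AUC lists are compared with an unpaired Welch
    t-test; ``shared_samples=True`` reuses one stream for both (then
    ``paired=True`` is the calibrated choice).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    model_cfg = model_cfg or clf.ModelConfig()
    master = np.random.default_rng([30, seed])
    sample_seeds = master.integers(2**31, size=(2, n_boot))
    if shared_samples:
        sample_seeds[1] = sample_seeds[0]
    train_seeds = master.integers(2**31, size=(2, n_boot))

    ids = view.tweets["tweet_id"].to_numpy()
    auc_lists: list[list[float]] = []
    for c, toggles in enumerate((toggles_a, toggles_b)):
        vals = []
        for b in range(n_boot):
            rs = int(sample_seeds[c, b])
            rows_train = resample(view.split.train_idx, replace=True, random_state=rs)
            rows_test = resample(view.split.test_idx, replace=True, random_state=rs + 1)
            vals.append(
                _fit_eval(
                    view.blocks,
                    view.y,
                    np.asarray(rows_train),
                    np.asarray(rows_test),
                    toggles,
                    _with_seed(model_cfg, int(train_seeds[c, b])),
                    tweet_ids=ids,
                )
            )
        auc_lists.append(vals)
    a, b = auc_lists
    if paired:
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return BootstrapResult(t=float(t), p=float(p), aucs_a=a, aucs_b=b)


# ---------------------------------------------------------------------------
# cross-region transfer


@dataclass
class CrossRegionResult:
    matrix: pd.DataFrame  # rows = test region, columns = train region
    diff: pd.Series  # per test region, diff% of same- vs out-of-domain AUC

    def __str__(self) -> str:
        out = self.matrix.copy()
        out["diff%"] = self.diff
        return out.to_string()


def cross_region(
    dataset,
    toggles: ModalityToggles,
    task: TaskSpec,
    embedding=None,
    node_stats: pd.DataFrame | None = None,
    n_runs: int = 10,
    model_cfg: clf.ModelConfig | None = None,
    seed: int = 0,
    train_frac: float = 0.7,
    regions: tuple[str, str] = ("EU", "US"),
) -> CrossRegionResult:
    """Train/test AUC matrix across regions plus the per-row diff% column.

    Each region's labeled tweets get their own 70/30 temporal split; cell
    (test=r, train=c) trains on region c's training period and scores region
    r's test period, averaged over ``n_runs`` seeds.  A cell whose test set
    has a single class is NaN.
    """
    model_cfg = model_cfg or clf.ModelConfig()
    view = prepare_view(dataset, task, embedding=embedding, node_stats=node_stats,
                        train_frac=train_frac)
    region_col = view.tweets["region"].to_numpy()
    splits = {}
    for r in regions:
        rows = np.flatnonzero(region_col == r)
        sub = temporal_split(view.tweets.iloc[rows], train_frac)
        splits[r] = (rows[sub.train_idx], rows[sub.test_idx])

    ids = view.tweets["tweet_id"].to_numpy()
    mat = pd.DataFrame(index=list(regions), columns=list(regions), dtype=float)
    for test_r in regions:
        for train_r in regions:
            rows_train = splits[train_r][0]
            rows_test = splits[test_r][1]
            try:
                vals = [
                    _fit_eval(
                        view.blocks, view.y, rows_train, rows_test, toggles,
                        _with_seed(model_cfg, seed + i), tweet_ids=ids,
                    )
                    for i in range(n_runs)
                ]
                mat.loc[test_r, train_r] = float(np.mean(vals))
            except (UndefinedAUCError, ValueError):
                mat.loc[test_r, train_r] = np.nan
    diff = {}
    for test_r in regions:
        same = mat.loc[test_r, test_r]
        others = [c for c in regions if c != test_r]
        out = mat.loc[test_r, others[0]]
        diff[test_r] = diff_percent(same, out) if np.isfinite(same) and np.isfinite(out) else np.nan
    return CrossRegionResult(matrix=mat, diff=pd.Series(diff, name="diff%"))


# ---------------------------------------------------------------------------
# report container


@dataclass
class EvalReport:
    """JSON-serializable record of an evaluation run with full provenance."""

    task: str
    toggles: tuple
    seed: int
    n_runs: int
    mean_auc: float
    sd_auc: float
    per_run_auc: list
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "toggles": list(self.toggles),
            "seed": self.seed,
            "n_runs": self.n_runs,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "per_run_auc": self.per_run_auc,
            **self.extras,
        }
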