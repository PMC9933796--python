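"""Synthetic reply-network datasets with planted vaccine-stance structure.

Generates the three tables a stance-classification study needs — users, tweets
and reply events — with controllable latent-attitude mixture, attitude
homophily on the reply graph, heavy-tailed degrees via preferential
attachment, a sparsely labeled tweet subset, and class-conditional text
vectors whose skeptic-class mean direction differs by region.  The latent
attitude of each user is stored separately (``SimDataset.truth``) and must
never be consumed by feature-construction code; classifiers only see the
sparse noisy labels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ATTITUDES = ("skeptic", "pro", "irrelevant")
REGIONS = ("EU", "US", "other")
LABELS = ("pro", "irrelevant", "skeptic", "anti")

#: anti-vaxxer share among skeptic-latent labels, mirroring the 344:676
#: anti/skeptic annotation ratio of the emulated collection.
DEFAULT_ANTI_SPLIT = 344 / (344 + 676)


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated collection.

    Parameters
    ----------
    n_users, n_tweets, n_replies
        Population size, seed-tweet count and reply-event count.
    time_span
        Inclusive start / exclusive end of the collection period; timestamps
        of tweets and replies are uniform over it.
    attitude_probs
        Mixture weights of the latent user attitudes
        ``(skeptic, pro, irrelevant)``; must sum to 1.
    labeled_fraction
        Probability that a tweet receives a manual 4-way label
        (default 0.1145, the emulated annotation coverage).
    label_noise
        Probability that a label is flipped to a uniformly random other label.
    homophily
        Probability ``h`` that a reply joins two users of the same latent
        attitude; with probability ``1 - h`` the replier is drawn from the
        whole population.
    pref_attachment, pa_exponent
        When on, reply targets are drawn proportionally to
        ``(current degree + 1) ** pa_exponent``, producing heavy-tailed
        degrees; otherwise uniformly.
    text_dim, text_separation
        Width of the synthetic text vectors and the distance ``s`` between
        the skeptic-class mean and the origin (non-skeptic classes are
        centered at 0, unit spherical noise for all).
    region_probs, region_shift
        ``(EU, US)`` region probabilities (remainder is "other") and the
        strength of the region-specific rotation of the skeptic text
        direction: the skeptic mean is ``s * normalize(mu0 + region_shift *
        e_region)`` with ``mu0 ⟂ e_EU ⟂ e_US`` fixed unit axes, so EU and US
        skeptic content is separable from each region's own background but
        transfers imperfectly across regions.
    anti_split
        Share of skeptic-latent labels recorded as "anti" rather than
        "skeptic".
    seed
        Master seed; identical configs are bit-reproducible.
    """

    n_users: int = 2000
    n_tweets: int = 5000
    n_replies: int = 15000
    time_span: tuple[str, str] = ("2021-01-01", "2021-08-01")
    attitude_probs: tuple[float, float, float] = (0.2, 0.51, 0.29)
    labeled_fraction: float = 0.1145
    label_noise: float = 0.0
    homophily: float = 0.7
    pref_attachment: bool = True
    pa_exponent: float = 1.0
    text_dim: int = 768
    text_separation: float = 1.0
    region_probs: tuple[float, float] = (0.45, 0.45)
    region_shift: float = 1.0
    anti_split: float = DEFAULT_ANTI_SPLIT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 2:
            raise ConfigError("n_users must be >= 2")
        if self.n_tweets < 0 or self.n_replies < 0:
            raise ConfigError("n_tweets and n_replies must be non-negative")
        probs = np.asarray(self.attitude_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or (probs > 1).any():
            raise ConfigError("attitude_probs must be three probabilities")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError("attitude_probs must sum to 1")
        for name in ("labeled_fraction", "label_noise", "homophily", "anti_split"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        rp = np.asarray(self.region_probs, dtype=float)
        if rp.shape != (2,) or (rp < 0).any() or rp.sum() > 1.0 + 1e-9:
            raise ConfigError("region_probs must be two probabilities summing to <= 1")
        if self.text_dim < 1:
            raise ConfigError("text_dim must be >= 1")
        if self.region_shift > 0 and self.text_dim < 3:
            raise ConfigError("region_shift > 0 requires text_dim >= 3")
        if self.text_separation < 0 or self.region_shift < 0:
            raise ConfigError("text_separation and region_shift must be >= 0")
        start, end = pd.Timestamp(self.time_span[0]), pd.Timestamp(self.time_span[1])
        if not start < end:
            raise ConfigError("time_span start must precede end")


@dataclass
class SimDataset:
    """One simulated collection.

    ``tweets`` rows align with ``text_vecs`` rows.  ``truth`` (per-user
    latent attitude) exists for recovery tests only and is never an input to
    features or classifiers.
    """

    config: SimConfig
    users: pd.DataFrame
    tweets: pd.DataFrame
    text_vecs: np.ndarray
    replies: pd.DataFrame
    truth: pd.Series = field(repr=False, default=None)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, seed])


def generate_users(config: SimConfig) -> pd.DataFrame:
    """Draw the user table: latent attitudes, regions and profile counts.

    Profile counts (followers/friends/posts/likes) are independent rounded
    log-normals (mu=4, sigma=2), a generic heavy-tailed activity model.
    """
    rng = _rng(config.seed, 0)
    n = config.n_users
    attitudes = rng.choice(ATTITUDES, size=n, p=np.asarray(config.attitude_probs))
    p_eu, p_us = config.region_probs
    regions = rng.choice(REGIONS, size=n, p=[p_eu, p_us, 1.0 - p_eu - p_us])
    counts = {
        name: np.round(rng.lognormal(mean=4.0, sigma=2.0, size=n)).astype(np.int64)
        for name in ("followers", "friends", "posts", "likes")
    }
    return pd.DataFrame(
        {
            "user_id": np.arange(n, dtype=np.int64),
            "latent_attitude": attitudes,
            "region": regions,
            **counts,
        }
    )


def _uniform_timestamps(rng: np.random.Generator, n: int, span: tuple[str, str]) -> pd.Series:
    start = pd.Timestamp(span[0]).value
    end = pd.Timestamp(span[1]).value
    vals = start + (rng.random(n) * (end - start)).astype(np.int64)
    return pd.Series(pd.to_datetime(vals), name="timestamp")


def generate_interactions(
    users: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate seed tweets and reply events.

    Tweets are authored uniformly at random with timestamps uniform over the
    collection span.  Each reply event picks its target by preferential
    attachment over current (multiplicity) degree when enabled, then its
    replier: with probability ``homophily`` uniformly among users sharing the
    target's latent attitude, otherwise uniformly from the whole population.
    """
    if len(users) == 0:
        raise ConfigError("user table is empty")
    rng = _rng(config.seed, 1)
    n_users = len(users)

    authors = rng.integers(0, n_users, size=config.n_tweets)
    tweets = pd.DataFrame(
        {
            "tweet_id": np.arange(config.n_tweets, dtype=np.int64),
            "user_id": users["user_id"].to_numpy()[authors],
            "timestamp": _uniform_timestamps(rng, config.n_tweets, config.time_span),
            "region": users["region"].to_numpy()[authors],
        }
    )

    attitude = users["latent_attitude"].to_numpy()
    groups = {a: np.flatnonzero(attitude == a) for a in ATTITUDES}
    degree = np.zeros(n_users, dtype=np.float64)
    src_arr = np.empty(config.n_replies, dtype=np.int64)
    dst_arr = np.empty(config.n_replies, dtype=np.int64)
    for i in range(config.n_replies):
        if config.pref_attachment:
            w = (degree + 1.0) ** config.pa_exponent
            dst = rng.choice(n_users, p=w / w.sum())
        else:
            dst = int(rng.integers(0, n_users))
        while True:
            if rng.random() < config.homophily:
                pool = groups[attitude[dst]]
                src = int(pool[rng.integers(0, len(pool))])
            else:
                src = int(rng.integers(0, n_users))
            if src != dst:
                break
        degree[src] += 1
        degree[dst] += 1
        src_arr[i], dst_arr[i] = src, dst
    ids = users["user_id"].to_numpy()
    replies = pd.DataFrame(
        {
            "src_user": ids[src_arr],
            "dst_user": ids[dst_arr],
            "timestamp": _uniform_timestamps(rng, config.n_replies, config.time_span),
        }
    ).sort_values("timestamp", kind="stable", ignore_index=True)
    return tweets, replies


def _skeptic_directions(config: SimConfig) -> dict[str, np.ndarray]:
    """Per-region unit mean directions for skeptic-class text vectors."""
    d = config.text_dim
    mu0 = np.zeros(d)
    mu0[0] = 1.0
    out: dict[str, np.ndarray] = {"other": mu0}
    for i, region in enumerate(("EU", "US"), start=1):
        if config.region_shift > 0:
            v = mu0.copy()
            v[i] = config.region_shift
            out[region] = v / np.linalg.norm(v)
        else:
            out[region] = mu0
    return out


def attach_text_vectors(
    tweets: pd.DataFrame, users: pd.DataFrame, config: SimConfig
) -> np.ndarray:
    """Draw one text vector per tweet (rows aligned with ``tweets``).

    Unit-variance spherical Gaussians: mean 0 for tweets of non-skeptic
    users, ``text_separation * u_region`` for tweets of skeptic-latent users,
    where ``u_region`` is the region-rotated unit direction of
    :func:`_skeptic_directions`.
    """
    rng = _rng(config.seed, 2)
    attitude = users.set_index("user_id")["latent_attitude"]
    tweet_attitude = attitude.loc[tweets["user_id"]].to_numpy()
    means = np.zeros((len(tweets), config.text_dim))
    dirs = _skeptic_directions(config)
    skeptic = tweet_attitude == "skeptic"
    for region in REGIONS:
        mask = skeptic & (tweets["region"].to_numpy() == region)
        means[mask] = config.text_separation * dirs[region]
    return means + rng.standard_normal((len(tweets), config.text_dim))


def label_subset(
    tweets: pd.DataFrame, users: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Annotate a random ``labeled_fraction`` of tweets with a 4-way label.

    The label derives from the author's latent attitude (skeptic-latent
    authors split "anti" vs "skeptic" by ``anti_split``) and is flipped to a
    uniformly random *other* label with probability ``label_noise``.  All
    remaining tweets carry the sentinel label "unlabeled".
    """
    rng = _rng(config.seed, 3)
    attitude = users.set_index("user_id")["latent_attitude"]
    tweet_attitude = attitude.loc[tweets["user_id"]].to_numpy()
    n = len(tweets)
    labeled = rng.random(n) < config.labeled_fraction

    labels = np.full(n, "unlabeled", dtype=object)
    base = np.empty(n, dtype=object)
    base[tweet_attitude == "pro"] = "pro"
    base[tweet_attitude == "irrelevant"] = "irrelevant"
    skeptic = tweet_attitude == "skeptic"
    anti = rng.random(n) < config.anti_split
    base[skeptic & anti] = "anti"
    base[skeptic & ~anti] = "skeptic"

    flip = rng.random(n) < config.label_noise
    flip_pick = rng.integers(0, 3, size=n)  # index among the 3 other labels
    for i in np.flatnonzero(labeled):
        lab = base[i]
        if flip[i]:
            others = [x for x in LABELS if x != lab]
            lab = others[flip_pick[i]]
        labels[i] = lab
    out = tweets.copy()
    out["label"] = labels
    return out


def generate_dataset(config: SimConfig) -> SimDataset:
    """Run the full generator: users, interactions, text vectors, labels."""
    users = generate_users(config)
    tweets, replies = generate_interactions(users, config)
    text_vecs = attach_text_vectors(tweets, users, config)
    tweets = label_subset(tweets, users, config)
    truth = users.set_index("user_id")["latent_attitude"].rename("truth")
    return SimDataset(
        config=config,
        users=users,
        tweets=tweets,
        text_vecs=text_vecs,
        replies=replies,
        truth=truth,
    )


def simulate_term_usage(
    users: pd.DataFrame,
    n_terms: int = 30,
    p_in: float = 0.3,
    p_out: float = 0.05,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Attitude-conditioned term usage for topic-space experiments.

    Each simulated term is affiliated with one latent attitude (round-robin);
    a user employs it with probability ``p_in`` when attitudes match and
    ``p_out`` otherwise.  Returns term -> array of user ids.
    """
    rng = np.random.default_rng([4, seed])
    attitude = users["latent_attitude"].to_numpy()
    ids = users["user_id"].to_numpy()
    out: dict[str, np.ndarray] = {}
    for t in range(n_terms):
        a = ATTITUDES[t % len(ATTITUDES)]
        p = np.where(attitude == a, p_in, p_out)
        out[f"{a}_term_{t}"] = ids[rng.random(len(users)) < p]
    return out


# ---------------------------------------------------------------------------
# on-disk round trip (plain-text formats only)


def write_dataset(ds: SimDataset, outdir: str | Path) -> None:
    """Write users.csv, tweets.csv, text_vecs.tsv, tweets.jsonl, replies.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.users.to_csv(outdir / "users.csv", index=False)
    ds.tweets.to_csv(outdir / "tweets.csv", index=False)
    vec = pd.DataFrame(ds.text_vecs)
    vec.insert(0, "tweet_id", ds.tweets["tweet_id"].to_numpy())
    vec.to_csv(outdir / "text_vecs.tsv", sep="\t", index=False, header=False)
    with open(outdir / "tweets.jsonl", "w") as fh:
        for row, v in zip(ds.tweets.itertuples(index=False), ds.text_vecs):
            fh.write(
                json.dumps(
                    {
                        "tweet_id": int(row.tweet_id),
                        "user_id": int(row.user_id),
                        "timestamp": pd.Timestamp(row.timestamp).isoformat(),
                        "region": row.region,
                        "label": row.label,
                        "text_vec": [round(float(x), 6) for x in v],
                    }
                )
                + "\n"
            )
    rep = ds.replies.copy()
    rep["timestamp"] = rep["timestamp"].map(lambda t: pd.Timestamp(t).isoformat())
    rep.to_csv(outdir / "replies.tsv", sep="\t", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(ds.config), fh, indent=1)


def read_dataset(outdir: str | Path) -> SimDataset:
    """Re-load a dataset written by :func:`write_dataset`."""
    outdir = Path(outdir)
    with open(outdir / "config.json") as fh:
        raw = json.load(fh)
    for key in ("time_span", "attitude_probs", "region_probs"):
        raw[key] = tuple(raw[key])
    config = SimConfig(**raw)
    users = pd.read_csv(outdir / "users.csv")
    tweets = pd.read_csv(outdir / "tweets.csv", parse_dates=["timestamp"])
    vec = pd.read_csv(outdir / "text_vecs.tsv", sep="\t", header=None)
    text_vecs = vec.iloc[:, 1:].to_numpy(dtype=float)
    replies = pd.read_csv(outdir / "replies.tsv", sep="\t", parse_dates=["timestamp"])
    truth = users.set_index("user_id")["latent_attitude"].rename("truth")
    return SimDataset(
        config=config,
        users=users,
        tweets=tweets,
        text_vecs=text_vecs,
        replies=replies,
        truth=truth,
    )
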