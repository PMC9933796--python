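"""The four per-tweet modality blocks and their leakage-safe assembly.

Blocks, in fixed concatenation order:

* ``text`` — the tweet's text-embedding vector (synthetic vectors pass
  through unchanged; a real encoder backend can be registered);
* ``history`` — (min, max, mean, population sd) of the binary labels of the
  same user's strictly earlier labeled tweets, neutral fill (0.5, 0.5, 0.5,
  0) when there is no history;
* ``net_stats`` — followers, friends, posts, likes, indegree, outdegree,
  core number, PageRank;
* ``raw_network`` — the user's node-embedding row (zeros when pruned).

The three auxiliary blocks are standardized column-wise with means/sds
fitted on training rows only; the text block passes through unscaled.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .node_embedding import EmbeddingMatrix

NET_STATS_COLUMNS = (
    "followers", "friends", "posts", "likes",
    "indegree", "outdegree", "core_number", "pagerank",
)
HISTORY_FILL = np.array([0.5, 0.5, 0.5, 0.0])

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+|\bt\.co/\S+)")
_MENTION_RE = re.compile(r"@\w+")
_HASHTAG_RE = re.compile(r"#(\w+)")


def _emoji_words(ch: str) -> str:
    try:
        return unicodedata.name(ch).lower()
    except ValueError:
        return ""


def clean_text(raw: str) -> str:
    """Normalize raw tweet text.

    Removes URLs and @mentions, strips '#' from hashtags keeping the tag
    word, replaces each emoji/symbol codepoint by its lower-cased Unicode
    short-name words, and collapses whitespace.
    """
    s = _URL_RE.sub(" ", raw)
    s = _MENTION_RE.sub(" ", s)
    s = _HASHTAG_RE.sub(r"\1", s)
    out = []
    for ch in s:
        if unicodedata.category(ch) in ("So", "Sk") and ord(ch) >= 0x2190:
            words = _emoji_words(ch)
            out.append(f" {words} " if words else " ")
        else:
            out.append(ch)
    return " ".join("".join(out).split())


_ENCODERS: dict[str, object] = {}


def register_text_encoder(name: str, backend) -> None:
    """Register a text-encoder backend (callable: str -> 1-D vector)."""
    _ENCODERS[name] = backend


def encode_text(cleaned: str, backend=None, stored_vec=None) -> np.ndarray:
    """Encode a cleaned tweet; a stored synthetic vector passes through.

    ``backend`` may be a registered encoder name or a callable.  Raises when
    neither a backend nor a stored vector is available.
    """
    if stored_vec is not None:
        return np.asarray(stored_vec, dtype=float)
    if backend is None:
        raise ValueError("no text-encoder backend and no stored vector")
    fn = _ENCODERS[backend] if isinstance(backend, str) else backend
    vec = np.asarray(fn(cleaned), dtype=float)
    if vec.ndim != 1:
        raise ValueError("text encoder must return a 1-D vector")
    return vec


# ---------------------------------------------------------------------------
# user history


def user_history_features(past_labels) -> np.ndarray:
    """(min, max, mean, population sd) of past binary labels; neutral fill."""
    arr = np.asarray(list(past_labels), dtype=float)
    if arr.size == 0:
        return HISTORY_FILL.copy()
    return np.array([arr.min(), arr.max(), arr.mean(), arr.std(ddof=0)])


def history_block(
    user_ids, timestamps, y: np.ndarray, train_mask: np.ndarray | None = None
) -> np.ndarray:
    """History features for every labeled tweet (rows in input order).

    For tweet i the history is the binary labels of the same user's tweets
    with strictly earlier timestamps.  When ``train_mask`` is given, only
    training-period tweets contribute history (the stricter protocol); by
    default every strictly earlier labeled tweet counts.
    """
    user_ids = np.asarray(user_ids)
    ts = np.asarray(timestamps)
    y = np.asarray(y, dtype=float)
    n = len(y)
    out = np.tile(HISTORY_FILL, (n, 1))
    usable = np.ones(n, dtype=bool) if train_mask is None else np.asarray(train_mask)
    for uid in pd.unique(user_ids):
        rows = np.flatnonzero(user_ids == uid)
        src = rows[usable[rows]]
        order = src[np.argsort(ts[src], kind="stable")]
        ts_sorted = ts[order]
        y_sorted = y[order]
        if len(order):
            csum = np.cumsum(y_sorted)
            csq = np.cumsum(y_sorted**2)
            cmin = np.minimum.accumulate(y_sorted)
            cmax = np.maximum.accumulate(y_sorted)
        for i in rows:
            k = int(np.searchsorted(ts_sorted, ts[i], side="left"))
            if k == 0:
                continue
            mean = csum[k - 1] / k
            var = max(csq[k - 1] / k - mean**2, 0.0)
            out[i] = (cmin[k - 1], cmax[k - 1], mean, np.sqrt(var))
    return out


# ---------------------------------------------------------------------------
# network blocks


def net_stats_features(user_id, node_stats: pd.DataFrame, profiles: pd.DataFrame | None = None) -> np.ndarray:
    """8-vector of profile counts and centralities for one user.

    Centrality entries are 0 for users pruned from the graph; profile counts
    then come from the profile table (0 when absent there too).
    """
    if user_id in node_stats.index:
        return node_stats.loc[user_id, list(NET_STATS_COLUMNS)].to_numpy(dtype=float)
    vec = np.zeros(len(NET_STATS_COLUMNS))
    if profiles is not None:
        prof = profiles.set_index("user_id") if "user_id" in profiles.columns else profiles
        if user_id in prof.index:
            for j, col in enumerate(NET_STATS_COLUMNS[:4]):
                if col in prof.columns:
                    vec[j] = float(prof.loc[user_id, col])
    return vec


def net_stats_block(user_ids, node_stats: pd.DataFrame, profiles: pd.DataFrame | None = None) -> np.ndarray:
    return np.stack([net_stats_features(u, node_stats, profiles) for u in np.asarray(user_ids)])


def raw_network_features(user_id, embedding: EmbeddingMatrix) -> np.ndarray:
    """The user's embedding row; an all-zeros row when the user was pruned."""
    row = embedding.row(user_id)
    return np.zeros(embedding.dim) if row is None else np.asarray(row, dtype=float)


def raw_network_block(user_ids, embedding: EmbeddingMatrix) -> np.ndarray:
    return np.stack([raw_network_features(u, embedding) for u in np.asarray(user_ids)])


# ---------------------------------------------------------------------------
# assembly


@dataclass(frozen=True)
class ModalityToggles:
    """Which of the four modality blocks enter the classifier."""

    use_text: bool = True
    use_history: bool = False
    use_net_stats: bool = False
    use_raw_network: bool = False

    def __post_init__(self) -> None:
        if not (self.use_text or self.use_history or self.use_net_stats or self.use_raw_network):
            raise ValueError("at least one modality must be enabled")

    @property
    def enabled(self) -> tuple[str, ...]:
        names = []
        for name, flag in (
            ("text", self.use_text),
            ("history", self.use_history),
            ("net_stats", self.use_net_stats),
            ("raw_network", self.use_raw_network),
        ):
            if flag:
                names.append(name)
        return tuple(names)

    @classmethod
    def from_names(cls, names) -> "ModalityToggles":
        names = {n.replace("-", "_") for n in names}
        known = {"text", "history", "net_stats", "raw_network"}
        unknown = names - known
        if unknown:
            raise ValueError(f"unknown modalities: {sorted(unknown)}")
        return cls(
            use_text="text" in names,
            use_history="history" in names,
            use_net_stats="net_stats" in names,
            use_raw_network="raw_network" in names,
        )


#: blocks that are standardized (text passes through on the encoder's scale)
SCALED_BLOCKS = ("history", "net_stats", "raw_network")
BLOCK_ORDER = ("text", "history", "net_stats", "raw_network")


@dataclass
class FeatureMatrix:
    """Concatenated, block-standardized per-tweet features."""

    tweet_ids: np.ndarray
    X: np.ndarray
    block_spec: list[dict]  # per block: name, offset, width
    scaler_params: dict  # block name -> (mean, sd) fitted on train rows

    @property
    def width(self) -> int:
        return self.X.shape[1]


def assemble(
    tweet_ids,
    blocks: dict[str, np.ndarray],
    toggles: ModalityToggles,
    train_mask,
) -> FeatureMatrix:
    """Standardize and concatenate the enabled blocks in fixed order.

    Scaler means/sds are fitted on training rows only; columns with zero
    training sd are set to 0 everywhere.  Raises if any enabled block is
    missing or any assembled value is non-finite.
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    parts, spec, scalers = [], [], {}
    offset = 0
    for name in BLOCK_ORDER:
        if name not in toggles.enabled:
            continue
        if name not in blocks:
            raise ValueError(f"enabled block {name!r} not provided")
        mat = np.asarray(blocks[name], dtype=float)
        if mat.ndim != 2 or mat.shape[0] != len(train_mask):
            raise ValueError(f"block {name!r} has wrong shape {mat.shape}")
        if name in SCALED_BLOCKS:
            mean = mat[train_mask].mean(axis=0)
            sd = mat[train_mask].std(axis=0, ddof=0)
            scaled = np.where(sd > 0, (mat - mean) / np.where(sd > 0, sd, 1.0), 0.0)
            scalers[name] = (mean, sd)
            parts.append(scaled)
        else:
            parts.append(mat)
        spec.append({"name": name, "offset": offset, "width": mat.shape[1]})
        offset += mat.shape[1]
    X = np.concatenate(parts, axis=1)
    if not np.isfinite(X).all():
        raise ValueError("assembled feature matrix contains non-finite values")
    return FeatureMatrix(
        tweet_ids=np.asarray(tweet_ids), X=X, block_spec=spec, scaler_params=scalers
    )
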