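"""Synthetic tweet-like corpora with planted topics, emotions and trends.

Every pipeline stage is testable without any platform access: the
generator plants K_true topic-word distributions (Dirichlet base with
boosted anchor words), draws one dominant topic per document, injects
1-3 words from disjoint per-emotion lexicons according to a per-day
emotion mixture schedule (stationary or linearly drifting), and stamps
each document uniformly within its day.  Ground truth (per-document
topic / emotion / polarity, the true topic-word matrix, the mixture
schedule) is returned alongside the corpus and everything is fully
deterministic under the seed.

The module also provides the deterministic *toy embedder*: a
5-dimensional vector counting each emotion lexicon's words in the text
(L2-normalized), whose anchor embeddings are exactly the unit basis
vectors.  It stands in for a sentence-embedding model wherever an exact,
analytically tractable zero-shot classifier is wanted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta, timezone
from pathlib import Path

import numpy as np

from .corpus_io import TweetCollection, TweetRecord
from .sentiment import EMOTION_LABELS, EMOTIONS, register_embedder

__all__ = [
    "EMOTION_LEXICONS",
    "SyntheticConfig",
    "GroundTruth",
    "generate_corpus",
    "toy_embedder",
    "presets",
    "get_preset",
]

#: Disjoint per-emotion word sets, mirrored (with valences) in the bundled
#: mini sentiment lexicon so polarity and emotion recovery are exact.
EMOTION_LEXICONS: dict[str, tuple[str, ...]] = {
    "anger": (
        "anger", "angry", "furious", "outraged", "rage", "disgusted",
        "resent", "infuriating", "hateful",
    ),
    "fear": (
        "fear", "scared", "afraid", "worried", "terrified", "anxious",
        "panic", "frightening",
    ),
    "sadness": (
        "sadness", "sad", "grief", "heartbroken", "mourning", "tragic",
        "crying", "sorrow", "devastated",
    ),
    "joy": (
        "joy", "happy", "delighted", "wonderful", "great", "awesome",
        "thrilled", "celebrate",
    ),
    "hopefulness": (
        "hopefulness", "hopeful", "hope", "optimistic", "encouraging",
        "promising", "reassuring", "confident", "uplifting",
    ),
}

_all_words = [w for ws in EMOTION_LEXICONS.values() for w in ws]
assert len(_all_words) == len(set(_all_words)), "emotion lexicons must be disjoint"

_TOKEN = re.compile(r"[a-z']+")
_LEX_INDEX = {
    w: i for i, e in enumerate(EMOTIONS) for w in EMOTION_LEXICONS[e]
}


def toy_embedder(text: str) -> np.ndarray:
    """5-dim emotion-lexicon count vector, L2-normalized when nonzero.

    Axis order follows :data:`trendmine.sentiment.EMOTIONS`; the bare
    emotion word of axis i maps exactly to the unit vector e_i.
    """
    vec = np.zeros(len(EMOTIONS))
    for tok in _TOKEN.findall(text.lower()):
        i = _LEX_INDEX.get(tok)
        if i is not None:
            vec[i] += 1.0
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec


register_embedder("toy", toy_embedder)

#: Trend spec per label: ("stationary", p) or ("drift", p0, p1).
TrendSpec = tuple


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped corpus: 60 days of keyword-filterable short texts with
    one dominant topic per document and a planted daily emotion mixture."""

    k_true: int = 5
    vocab_size: int = 200
    anchors_per_topic: int = 10
    doc_len_mean: float = 12.0
    n_docs: int = 2000
    start_date: date = date(2020, 12, 16)
    n_days: int = 60
    topic_mixture: tuple[float, ...] | None = None  # None -> uniform
    emotion_trends: dict[str, TrendSpec] = field(
        default_factory=lambda: {
            "anger": ("stationary", 0.10),
            "fear": ("stationary", 0.30),
            "sadness": ("stationary", 0.10),
            "joy": ("stationary", 0.25),
            "hopefulness": ("stationary", 0.10),
            "neutral": ("stationary", 0.15),
        }
    )
    anchor_mass: float = 0.6
    keyword_prob: float = 0.9
    keyword: str = "vaccine"
    seed: int = 0

    def validate(self) -> None:
        if self.k_true < 1 or self.vocab_size < self.k_true * self.anchors_per_topic:
            raise ValueError("vocab must accommodate k_true * anchors_per_topic")
        if self.n_docs < 1 or self.n_days < 1:
            raise ValueError("n_docs and n_days must be >= 1")
        if self.topic_mixture is not None:
            pi = np.asarray(self.topic_mixture)
            if pi.shape != (self.k_true,) or abs(pi.sum() - 1.0) > 1e-9 or pi.min() < 0:
                raise ValueError("topic_mixture must be a length-k_true simplex point")
        if set(self.emotion_trends) != set(EMOTION_LABELS):
            raise ValueError(f"emotion_trends must cover exactly {EMOTION_LABELS}")
        for label, spec in self.emotion_trends.items():
            ps = spec[1:]
            if spec[0] not in ("stationary", "drift") or not all(
                0.0 <= p <= 1.0 for p in ps
            ):
                raise ValueError(f"bad trend spec for {label}: {spec}")
        if not 0.0 <= self.keyword_prob <= 1.0:
            raise ValueError("keyword_prob must be in [0, 1]")
        if not 0.0 < self.anchor_mass < 1.0:
            raise ValueError("anchor_mass must be in (0, 1)")


@dataclass
class GroundTruth:
    """Planted per-document labels and generative parameters."""

    doc_ids: list[str]
    topics: np.ndarray  # planted topic per doc
    emotions: list[str]  # planted emotion label per doc
    polarities: list[str]  # implied polarity per doc
    topic_word: np.ndarray  # k_true x vocab_size, rows sum to 1
    vocab: list[str]
    anchor_words: list[list[str]]
    emotion_schedule: np.ndarray  # n_days x 6, rows sum to 1
    config: SyntheticConfig

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with (directory / "ground_truth_docs.tsv").open("w") as fh:
            fh.write("doc_id\ttopic\temotion\tpolarity\n")
            for i, d in enumerate(self.doc_ids):
                fh.write(
                    f"{d}\t{self.topics[i]}\t{self.emotions[i]}\t{self.polarities[i]}\n"
                )
        with (directory / "ground_truth_schedule.tsv").open("w") as fh:
            fh.write("day\t" + "\t".join(EMOTION_LABELS) + "\n")
            for t in range(self.emotion_schedule.shape[0]):
                vals = "\t".join(f"{v:.6f}" for v in self.emotion_schedule[t])
                fh.write(f"{t}\t{vals}\n")
        np.savetxt(
            directory / "ground_truth_topic_word.tsv",
            self.topic_word,
            delimiter="\t",
            header="\t".join(self.vocab),
            comments="# ",
        )


_POLARITY_OF = {
    "anger": "negative",
    "fear": "negative",
    "sadness": "negative",
    "joy": "positive",
    "hopefulness": "positive",
    "neutral": "neutral",
}


def _schedule(config: SyntheticConfig) -> np.ndarray:
    """Daily emotion mixture: raw trend values, renormalized per day."""
    sched = np.zeros((config.n_days, len(EMOTION_LABELS)))
    denom = max(config.n_days - 1, 1)
    for i, label in enumerate(EMOTION_LABELS):
        spec = config.emotion_trends[label]
        if spec[0] == "stationary":
            sched[:, i] = spec[1]
        else:
            p0, p1 = spec[1], spec[2]
            sched[:, i] = p0 + (p1 - p0) * np.arange(config.n_days) / denom
    totals = sched.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("emotion mixture sums to zero on some day")
    return sched / totals


def generate_corpus(config: SyntheticConfig) -> tuple[TweetCollection, GroundTruth]:
    """Draw a corpus and its ground truth; deterministic under the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    vocab = [f"w{i:03d}" for i in range(config.vocab_size)]
    k = config.k_true
    pi = (
        np.full(k, 1.0 / k)
        if config.topic_mixture is None
        else np.asarray(config.topic_mixture, dtype=float)
    )

    # planted topic-word distributions: diffuse Dirichlet base plus
    # concentrated mass on disjoint anchor blocks
    topic_word = np.zeros((k, config.vocab_size))
    anchor_words: list[list[str]] = []
    a = config.anchors_per_topic
    for t in range(k):
        base = rng.dirichlet(np.full(config.vocab_size, 0.1))
        dist = (1.0 - config.anchor_mass) * base
        anchors = np.arange(t * a, (t + 1) * a)
        dist[anchors] += config.anchor_mass / a
        topic_word[t] = dist / dist.sum()
        anchor_words.append([vocab[i] for i in anchors])

    sched = _schedule(config)
    day0 = datetime.combine(config.start_date, datetime.min.time(), timezone.utc)

    records: list[TweetRecord] = []
    topics = np.zeros(config.n_docs, dtype=np.int64)
    emotions: list[str] = []
    polarities: list[str] = []
    doc_ids = [f"t{j:06d}" for j in range(config.n_docs)]

    for j in range(config.n_docs):
        day = int(rng.integers(config.n_days))
        topic = int(rng.choice(k, p=pi))
        length = max(3, int(rng.poisson(config.doc_len_mean)))
        words = list(rng.choice(vocab, size=length, p=topic_word[topic]))
        emotion = EMOTION_LABELS[int(rng.choice(len(EMOTION_LABELS), p=sched[day]))]
        if emotion != "neutral":
            n_inject = int(rng.integers(1, 4))
            words.extend(rng.choice(EMOTION_LEXICONS[emotion], size=n_inject))
        if rng.random() < config.keyword_prob:
            words.append(config.keyword)
        rng.shuffle(words)
        ts = day0 + timedelta(days=day, seconds=float(rng.uniform(0, 86400.0 - 1)))
        records.append(
            TweetRecord(
                id=doc_ids[j], created_at=ts, text=" ".join(words), lang="en"
            )
        )
        topics[j] = topic
        emotions.append(emotion)
        polarities.append(_POLARITY_OF[emotion])

    truth = GroundTruth(
        doc_ids=doc_ids,
        topics=topics,
        emotions=emotions,
        polarities=polarities,
        topic_word=topic_word,
        vocab=vocab,
        anchor_words=anchor_words,
        emotion_schedule=sched,
        config=config,
    )
    return TweetCollection(records), truth


_PRESETS: dict[str, SyntheticConfig] = {
    # recovery benchmark: 5 well-anchored topics, modest vocabulary
    "easy": SyntheticConfig(),
    # constant daily emotion mixes at higher daily volume, for ADF power
    "stationary": SyntheticConfig(n_docs=6000),
    # sadness share ramps linearly across the window, everything else flat
    "drift": SyntheticConfig(
        n_docs=6000,
        emotion_trends={
            "anger": ("stationary", 0.10),
            "fear": ("stationary", 0.30),
            "sadness": ("drift", 0.05, 0.35),
            "joy": ("stationary", 0.20),
            "hopefulness": ("stationary", 0.10),
            "neutral": ("stationary", 0.15),
        },
    ),
}


def presets() -> dict[str, SyntheticConfig]:
    """Named study-condition presets (fresh copies)."""
    return {name: replace(cfg) for name, cfg in _PRESETS.items()}


def get_preset(name: str, seed: int | None = None) -> SyntheticConfig:
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    cfg = replace(_PRESETS[name])
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg
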