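"""Two-step sentiment: rule-based polarity, then polarity-gated emotions.

Step 1 scores each text with a social-media-style rule-based lexicon
scorer: matched token valences (with optional negation flips and
booster increments) are summed and squashed to a compound score in
[-1, 1] via ``s / sqrt(s^2 + 15)``.  Compounds at or beyond +/-0.05 are
labeled positive/negative; the band in between is neutral.

Step 2 assigns one of five emotions zero-shot, by cosine similarity
between the text embedding and embeddings of the bare emotion words
(anger, fear, sadness, joy, hopefulness).  In the default *gated* mode
the candidate set is restricted by polarity -- positive texts choose
between joy and hopefulness, negative ones between anger, fear and
sadness, neutral texts stay neutral.  A *global* mode instead takes the
argmax over all five cosines together with the compound score occupying
the neutral slot.

Embedders are pluggable (name -> text-to-vector callable); the package
registers the deterministic lexicon-count toy embedder under ``"toy"``
and any sentence-embedding model can be registered at run time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable

import numpy as np

from .corpus_io import TweetCollection

__all__ = [
    "EMOTIONS",
    "NEGATIVE_EMOTIONS",
    "POSITIVE_EMOTIONS",
    "EMOTION_LABELS",
    "SentimentLexicon",
    "default_lexicon",
    "load_lexicon",
    "polarity_compound",
    "polarity_label",
    "register_embedder",
    "embed",
    "cosine",
    "emotion_anchors",
    "classify_emotion",
    "EmotionMatrix",
    "emotion_matrix",
]

logger = logging.getLogger(__name__)

#: Fixed emotion order; doubles as the argmax tie-break order.
EMOTIONS = ("anger", "fear", "sadness", "joy", "hopefulness")
NEGATIVE_EMOTIONS = ("anger", "fear", "sadness")
POSITIVE_EMOTIONS = ("joy", "hopefulness")
#: Row order of the emotion matrix: five emotions plus the neutral slot.
EMOTION_LABELS = EMOTIONS + ("neutral",)

_WORD = re.compile(r"[#@\w'-]+")
_NORM_ALPHA = 15.0  # normalization constant of the compound squash
_NEGATION_SCALE = -0.74  # sign flip with damping, standard rule-based value
_DEFAULT_NEGATIONS = frozenset(
    {"not", "no", "never", "none", "neither", "nobody", "cannot", "n't", "without"}
)
_DEFAULT_BOOSTERS = {
    "very": 0.293,
    "extremely": 0.293,
    "really": 0.293,
    "so": 0.293,
    "absolutely": 0.293,
    "incredibly": 0.293,
    "totally": 0.293,
    "slightly": -0.293,
    "somewhat": -0.293,
    "barely": -0.293,
}


@dataclass(frozen=True)
class SentimentLexicon:
    """token -> valence map plus negation and booster rules."""

    valences: dict[str, float]
    negations: frozenset[str] = _DEFAULT_NEGATIONS
    boosters: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BOOSTERS))

    def __post_init__(self) -> None:
        for tok, v in self.valences.items():
            if tok != tok.lower():
                raise ValueError(f"lexicon token {tok!r} is not lowercase")
            if not np.isfinite(v):
                raise ValueError(f"lexicon valence for {tok!r} is not finite")


def load_lexicon(path: str | Path) -> SentimentLexicon:
    """Load a TSV (token <TAB> valence) lexicon."""
    valences: dict[str, float] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        tok, val = line.split("\t")
        valences[tok.strip().lower()] = float(val)
    return SentimentLexicon(valences)


def default_lexicon() -> SentimentLexicon:
    """The bundled mini-lexicon (covers the synthetic emotion vocabularies)."""
    with resources.as_file(
        resources.files("trendmine.data").joinpath("mini_lexicon.tsv")
    ) as p:
        return load_lexicon(p)


def polarity_compound(text: str, lexicon: SentimentLexicon | None = None) -> float:
    """Compound polarity in [-1, 1]; 0.0 when nothing matches.

    A negation within the two tokens before a matched word flips and
    damps its valence; a booster immediately before it shifts the
    magnitude by the booster increment.
    """
    if lexicon is None:
        lexicon = default_lexicon()
    tokens = _WORD.findall(text.lower())
    s = 0.0
    for i, tok in enumerate(tokens):
        v = lexicon.valences.get(tok)
        if v is None:
            continue
        prev = tokens[max(0, i - 2) : i]
        if prev and prev[-1] in lexicon.boosters:
            v += np.sign(v) * lexicon.boosters[prev[-1]]
        if any(p in lexicon.negations for p in prev):
            v *= _NEGATION_SCALE
        s += v
    if s == 0.0:
        return 0.0
    compound = s / np.sqrt(s * s + _NORM_ALPHA)
    return float(np.clip(compound, -1.0, 1.0))


def polarity_label(compound: float) -> str:
    """Threshold the compound at +/-0.05 (both boundaries inclusive)."""
    if compound <= -0.05:
        return "negative"
    if compound >= 0.05:
        return "positive"
    return "neutral"


# ---------------------------------------------------------------------------
# Embedding adapter and zero-shot emotion assignment
# ---------------------------------------------------------------------------

_EMBEDDERS: dict[str, Callable[[str], np.ndarray]] = {}


def register_embedder(name: str, fn: Callable[[str], np.ndarray]) -> None:
    """Register a text -> fixed-length-vector embedder under ``name``."""
    _EMBEDDERS[name] = fn


def _resolve(embedder: str | Callable[[str], np.ndarray]) -> Callable[[str], np.ndarray]:
    if callable(embedder):
        return embedder
    if embedder == "toy" and "toy" not in _EMBEDDERS:
        from . import synthetic_data  # registers "toy" on import

        _ = synthetic_data
    if embedder not in _EMBEDDERS:
        raise KeyError(
            f"unknown embedder {embedder!r}; registered: {sorted(_EMBEDDERS)}"
        )
    return _EMBEDDERS[embedder]


def embed(text: str, embedder: str | Callable[[str], np.ndarray] = "toy") -> np.ndarray:
    """Embed a text with a registered (or directly supplied) embedder."""
    vec = np.asarray(_resolve(embedder)(text), dtype=float)
    if vec.ndim != 1:
        raise ValueError("embedder must return a 1-D vector")
    return vec


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; zero vectors map to 0.0 by convention."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def emotion_anchors(
    embedder: str | Callable[[str], np.ndarray] = "toy",
    template: str | None = None,
) -> dict[str, np.ndarray]:
    """Embeddings of the five emotion words (optionally via a prompt
    template containing ``{emotion}``)."""
    fn = _resolve(embedder)
    out = {}
    for e in EMOTIONS:
        text = template.format(emotion=e) if template else e
        out[e] = np.asarray(fn(text), dtype=float)
    return out


def classify_emotion(
    text: str,
    polarity: str,
    embedder: str | Callable[[str], np.ndarray] = "toy",
    mode: str = "gated",
    anchors: dict[str, np.ndarray] | None = None,
    compound: float | None = None,
) -> str:
    """Assign one emotion label to a text.

    Gated mode restricts candidates by polarity; global mode takes the
    argmax over all five cosines plus the compound score in the neutral
    slot (``compound`` required).  Ties resolve in the fixed order
    anger, fear, sadness, joy, hopefulness.
    """
    if mode not in ("gated", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "gated" and polarity == "neutral":
        return "neutral"
    if anchors is None:
        anchors = emotion_anchors(embedder)
    vec = embed(text, embedder)
    if not np.any(vec):
        logger.warning("zero embedding for text %r; labeling neutral", text[:40])
        return "neutral"

    sims = {e: cosine(vec, anchors[e]) for e in EMOTIONS}
    if mode == "gated":
        cands = POSITIVE_EMOTIONS if polarity == "positive" else NEGATIVE_EMOTIONS
        return max(cands, key=lambda e: (sims[e], -EMOTIONS.index(e)))
    if compound is None:
        raise ValueError("global mode requires the compound score")
    scores = dict(sims)
    scores["neutral"] = compound
    return max(EMOTION_LABELS, key=lambda e: (scores[e], -EMOTION_LABELS.index(e)))


@dataclass
class EmotionMatrix:
    """X is C x N (five cosine rows + the neutral compound row); ``x_rep``
    holds the representative label per document."""

    X: np.ndarray
    x_rep: list[str]
    doc_ids: list[str]
    compounds: np.ndarray
    polarities: list[str]

    @property
    def labels(self) -> tuple[str, ...]:
        return EMOTION_LABELS


def emotion_matrix(
    col: TweetCollection,
    lexicon: SentimentLexicon | None = None,
    embedder: str | Callable[[str], np.ndarray] = "toy",
    mode: str = "gated",
) -> EmotionMatrix:
    """Run the full two-step classifier over a collection."""
    if len(col) == 0:
        raise ValueError("cannot classify an empty collection")
    if lexicon is None:
        lexicon = default_lexicon()
    anchors = emotion_anchors(embedder)

    n = len(col)
    X = np.zeros((len(EMOTION_LABELS), n))
    x_rep: list[str] = []
    compounds = np.zeros(n)
    polarities: list[str] = []
    for j, rec in enumerate(col):
        comp = polarity_compound(rec.text, lexicon)
        pol = polarity_label(comp)
        vec = embed(rec.text, embedder)
        for i, e in enumerate(EMOTIONS):
            X[i, j] = cosine(vec, anchors[e])
        X[-1, j] = comp
        compounds[j] = comp
        polarities.append(pol)
        x_rep.append(
            classify_emotion(
                rec.text, pol, embedder, mode=mode, anchors=anchors, compound=comp
            )
        )
    return EmotionMatrix(
        X=X, x_rep=x_rep, doc_ids=col.doc_ids, compounds=compounds,
        polarities=polarities,
    )
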