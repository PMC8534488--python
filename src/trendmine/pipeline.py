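"""Stage orchestration: raw corpus -> filtered corpus -> tf-idf -> topics
-> sentiment -> trends -> report, with fixed artifact names under a
working directory.

Every stage is idempotent given identical inputs and seed, logs its
input/output counts, and stamps a short hash of the full configuration
into each artifact header so mixed-config artifacts are detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite

from . import corpus_io, onmf, preprocess, sentiment, synthetic_data, trends

__all__ = ["PipelineConfig", "run_stage", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("generate", "ingest", "preprocess", "topics", "sentiment", "trends", "report")

_ARTIFACTS = {
    "generate": ("corpus.jsonl",),
    "ingest": ("filtered.jsonl", "provenance.tsv"),
    "preprocess": ("vocab.tsv", "V.mtx", "doc_ids.txt"),
    "topics": ("W.mtx", "topics.tsv", "ratios.tsv", "top_words.tsv"),
    "sentiment": ("sentiment.tsv",),
    "trends": ("trends.tsv", "adf.tsv"),
    "report": ("report.md",),
}

_UPSTREAM = {
    "ingest": "generate",
    "preprocess": "ingest",
    "topics": "preprocess",
    "sentiment": "ingest",
    "trends": "sentiment",
    "report": "trends",
}


@dataclass
class PipelineConfig:
    """Defaults mirror the production study settings: 50 topics, batch
    size 2000, +/-0.05 polarity thresholds, alpha=0.05, the shipped
    keyword list and a 60-day window."""

    workdir: str = "workdir"
    input_path: str | None = None  # None -> workdir/corpus.jsonl
    preset: str = "easy"
    window_start: str | None = "2020-12-16"
    window_end: str | None = "2021-02-13"
    language: str | None = "en"
    drop_missing_lang: bool = False
    apply_keyword_filter: bool = True
    min_df: int = 2
    max_df_frac: float = 0.95
    smooth_idf: bool = False
    l2_normalize: bool = False
    n_topics: int = 50
    batch_size: int = 2000
    inner_iters: int = 60
    n_passes: int = 1
    embedder: str = "toy"
    emotion_mode: str = "gated"
    lexicon_path: str | None = None  # None -> bundled mini lexicon
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so runs in
        different directories with the same settings hash alike)."""
        d = dataclasses.asdict(self)
        for key in ("workdir", "input_path", "lexicon_path"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @property
    def wd(self) -> Path:
        return Path(self.workdir)


def _require(config: PipelineConfig, stage: str) -> None:
    upstream = _UPSTREAM.get(stage)
    if upstream is None:
        return
    missing = [
        a for a in _ARTIFACTS[upstream] if not (config.wd / a).exists()
    ]
    # the generate stage is optional when an external corpus is supplied
    if upstream == "generate" and config.input_path:
        return
    if missing:
        raise FileNotFoundError(
            f"stage {stage!r} needs artifacts {missing} from stage {upstream!r}; "
            f"run {upstream!r} first"
        )


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _seed_for(config: PipelineConfig, stage: str) -> int:
    h = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_stage(stage: str, config: PipelineConfig) -> list[Path]:
    """Run one pipeline stage; returns the artifact paths it wrote."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; stages: {STAGES}")
    _require(config, stage)
    wd = config.wd
    wd.mkdir(parents=True, exist_ok=True)
    out = [wd / a for a in _ARTIFACTS[stage]]
    fn = globals()[f"_stage_{stage}"]
    fn(config)
    logger.info("stage %s complete: %s", stage, [p.name for p in out])
    return out


def _stage_generate(config: PipelineConfig) -> None:
    cfg = synthetic_data.get_preset(config.preset, seed=_seed_for(config, "generate"))
    col, truth = synthetic_data.generate_corpus(cfg)
    corpus_io.write_tweets(col, config.wd / "corpus.jsonl")
    truth.save(config.wd)
    logger.info("generated %d synthetic records (preset %s)", len(col), config.preset)


def _stage_ingest(config: PipelineConfig) -> None:
    src = Path(config.input_path) if config.input_path else config.wd / "corpus.jsonl"
    col = corpus_io.read_tweets(src)
    n_in = len(col)
    if config.apply_keyword_filter:
        col = corpus_io.filter_by_keywords(col)
    if config.window_start and config.window_end:
        col = corpus_io.filter_window(
            col,
            date.fromisoformat(config.window_start),
            date.fromisoformat(config.window_end),
        )
    if config.language:
        col = corpus_io.filter_language(
            col, config.language, drop_missing=config.drop_missing_lang
        )
    col = corpus_io.deduplicate(col)
    corpus_io.write_tweets(col, config.wd / "filtered.jsonl")
    prov = pd.DataFrame(col.provenance, columns=["filter", "removed"])
    _write_tsv(prov, config.wd / "provenance.tsv", config)
    logger.info("ingest: %d -> %d records", n_in, len(col))


def _stage_preprocess(config: PipelineConfig) -> None:
    col = corpus_io.read_tweets(config.wd / "filtered.jsonl")
    stop = preprocess.default_stopwords()
    docs = [preprocess.tokenize(t, stop) for t in col.texts()]
    vocab = preprocess.build_vocabulary(docs, config.min_df, config.max_df_frac)
    mat = preprocess.tfidf_matrix(
        docs, vocab, col.doc_ids, smooth=config.smooth_idf,
        l2_normalize=config.l2_normalize,
    )
    preprocess.save_vocabulary(
        vocab, config.wd / "vocab.tsv", header=f"config_hash={config.config_hash()}"
    )
    preprocess.save_matrix(mat, config.wd / "V.mtx", config.wd / "doc_ids.txt")
    logger.info("preprocess: %d docs, %d vocabulary words", len(docs), len(vocab))


def _stage_topics(config: PipelineConfig) -> None:
    vocab = preprocess.load_vocabulary(config.wd / "vocab.tsv")
    mat = preprocess.load_matrix(
        config.wd / "V.mtx", config.wd / "doc_ids.txt", vocab
    )
    ocfg = onmf.OnmfConfig(
        n_topics=config.n_topics,
        batch_size=config.batch_size,
        inner_iters=config.inner_iters,
        n_passes=config.n_passes,
        seed=_seed_for(config, "topics"),
    )
    model = onmf.fit_onmf(mat, ocfg)
    load = onmf.infer_loadings(model, mat)
    assign = onmf.assign_topics(load)
    ratio = onmf.topic_ratios(assign)
    retained = onmf.filter_topics(ratio)

    mmwrite(str(config.wd / "W.mtx"), sp.csr_matrix(model.W))
    _write_tsv(
        pd.DataFrame({"doc_id": assign.doc_ids, "topic": assign.topics}),
        config.wd / "topics.tsv",
        config,
    )
    _write_tsv(
        pd.DataFrame(
            {
                "topic": np.arange(ocfg.n_topics),
                "ratio": ratio.ratios,
                "retained": [int(k in retained) for k in range(ocfg.n_topics)],
            }
        ),
        config.wd / "ratios.tsv",
        config,
    )
    rows = [
        {"topic": k, "rank": r, "word": w, "weight": v}
        for k in retained
        for r, (w, v) in enumerate(onmf.top_words(model, k, 10))
    ]
    _write_tsv(pd.DataFrame(rows), config.wd / "top_words.tsv", config)
    logger.info("topics: %d/%d retained", len(retained), ocfg.n_topics)


def _stage_sentiment(config: PipelineConfig) -> None:
    col = corpus_io.read_tweets(config.wd / "filtered.jsonl")
    lex = (
        sentiment.load_lexicon(config.lexicon_path)
        if config.lexicon_path
        else sentiment.default_lexicon()
    )
    em = sentiment.emotion_matrix(
        col, lexicon=lex, embedder=config.embedder, mode=config.emotion_mode
    )
    _write_tsv(
        pd.DataFrame(
            {
                "doc_id": em.doc_ids,
                "compound": em.compounds,
                "polarity": em.polarities,
                "emotion": em.x_rep,
            }
        ),
        config.wd / "sentiment.tsv",
        config,
    )
    logger.info("sentiment: %d records classified", len(em.doc_ids))


def _stage_trends(config: PipelineConfig) -> None:
    col = corpus_io.read_tweets(config.wd / "filtered.jsonl")
    tdf = _read_tsv(config.wd / "topics.tsv")
    sdf = _read_tsv(config.wd / "sentiment.tsv")
    rdf = _read_tsv(config.wd / "ratios.tsv")
    retained = rdf[rdf["retained"] == 1]["topic"].tolist()

    assign = onmf.TopicAssignment(
        topics=tdf["topic"].to_numpy(np.int64),
        doc_ids=tdf["doc_id"].astype(str).tolist(),
        n_topics=int(rdf.shape[0]),
    )
    em = sentiment.EmotionMatrix(
        X=np.zeros((len(sentiment.EMOTION_LABELS), len(sdf))),
        x_rep=sdf["emotion"].tolist(),
        doc_ids=sdf["doc_id"].astype(str).tolist(),
        compounds=sdf["compound"].to_numpy(),
        polarities=sdf["polarity"].tolist(),
    )
    table = trends.merge_topic_emotion(assign, em, col)

    named: dict[tuple[str, str], trends.TimeSeries] = {}
    for k in retained:
        ts = trends.daily_topic_series(table, int(k))
        named[("overall", f"topic_{k}")] = ts
        named[("overall", f"topic_{k}_weekly")] = trends.weekly_smooth(ts)
    for scope in [None] + [int(k) for k in retained]:
        tag = "overall" if scope is None else f"topic_{scope}"
        for emo, ts in trends.daily_emotion_series(table, scope).items():
            named[(tag, f"emotion_{emo}")] = ts

    adf_results: dict[str, trends.AdfResult] = {}
    for emo, ts in trends.daily_emotion_series(table, None).items():
        try:
            adf_results[emo] = trends.adf_stationarity(ts, alpha=config.alpha)
        except ValueError as exc:
            logger.warning("ADF skipped for %s: %s", emo, exc)

    _write_tsv(trends.trends_to_frame(named), config.wd / "trends.tsv", config)
    _write_tsv(trends.adf_report(adf_results), config.wd / "adf.tsv", config)
    logger.info("trends: %d series, %d ADF tests", len(named), len(adf_results))


def _stage_report(config: PipelineConfig) -> None:
    prov = _read_tsv(config.wd / "provenance.tsv")
    rdf = _read_tsv(config.wd / "ratios.tsv")
    sdf = _read_tsv(config.wd / "sentiment.tsv")
    adf = _read_tsv(config.wd / "adf.tsv")
    retained = rdf[rdf["retained"] == 1]

    shares = sdf["emotion"].value_counts(normalize=True).rename("share")
    lines = [
        "# Trend analysis report",
        "",
        f"config_hash: `{config.config_hash()}`",
        "",
        "## Corpus filtering",
        "",
        "```",
        prov.to_string(index=False),
        "```",
        "",
        f"## Topics retained ({len(retained)} of {rdf.shape[0]})",
        "",
        "```",
        retained[["topic", "ratio"]].to_string(index=False),
        "```",
        "",
        "## Emotion shares",
        "",
        "```",
        shares.to_string(),
        "```",
        "",
        "## Stationarity (augmented Dickey-Fuller)",
        "",
        "```",
        adf.to_string(index=False),
        "```",
        "",
    ]
    (config.wd / "report.md").write_text("\n".join(lines), encoding="utf-8")
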