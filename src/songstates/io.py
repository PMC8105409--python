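"""Configuration, pair-table readers, and the end-to-end pipeline.

The pipeline runs the stages in order on a corpus directory of WAV
files plus a pairing table: feature extraction -> state partition fit
and assignment -> per-bird diversity -> similarity/influence scoring ->
syllable segmentation -> balanced-imitation statistics. Intermediate
feature tables are cached (keyed by a config hash) and all randomness
is seeded from the config, so a rerun writes byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .audio import read_wav
from .features import FeatureConfig, FeatureTrack, compute_features
from .similarity import NullModel, build_null, influence, score
from .states import (PartitionConfig, StatePartition, abundance_table,
                     assign_states, fit_partition, shannon_diversity,
                     state_abundances)
from .syllables import SegmentConfig, cluster_types, segment
from . import stats as _stats

log = logging.getLogger("songstates")

__all__ = ["PipelineConfig", "read_pairs_table", "run_pipeline"]

REQUIRED_COLUMNS = ("tutor_id", "pupil_id")
OPTIONAL_COLUMNS = ("relation", "clutch_id", "lineage_id")


@dataclass(frozen=True)
class SimilarityOptions:
    alpha: float = 0.05
    repeats: int = 5
    null_pairs: int = 50000
    null_min_tracks: int = 20
    window_ms: float = 70.0
    hop_ms: float = 3.0


@dataclass(frozen=True)
class StatsOptions:
    bias_threshold: float = 0.2
    gain_bin_width: float = 0.1
    n_shuffles: int = 1000


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline, serializable to YAML/JSON."""

    features: FeatureConfig = field(default_factory=FeatureConfig)
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    similarity: SimilarityOptions = field(default_factory=SimilarityOptions)
    segmentation: SegmentConfig = field(default_factory=SegmentConfig)
    stats: StatsOptions = field(default_factory=StatsOptions)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        def build(klass, sub):
            fields = {f.name for f in dataclasses.fields(klass)}
            kwargs = {k: v for k, v in (sub or {}).items() if k in fields}
            if klass is PartitionConfig and "states_per_region" in kwargs:
                kwargs["states_per_region"] = tuple(kwargs["states_per_region"])
            return klass(**kwargs)

        return cls(
            features=build(FeatureConfig, doc.get("features")),
            partition=build(PartitionConfig, doc.get("partition")),
            similarity=build(SimilarityOptions, doc.get("similarity")),
            segmentation=build(SegmentConfig, doc.get("segmentation")),
            stats=build(StatsOptions, doc.get("stats")),
            seed=int(doc.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(doc or {})

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def read_pairs_table(path) -> pd.DataFrame:
    """Read and validate a tutor-pupil pairing table (CSV or TSV).

    Required columns: ``tutor_id``, ``pupil_id``. Optional columns
    (``relation``, ``clutch_id``, ``lineage_id``) are filled with
    defaults when absent; unknown columns pass through untouched.
    Duplicate (tutor, pupil) rows raise an error.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    table = pd.read_csv(path, sep=sep, dtype=str)
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"pairs table missing required column {col!r}")
    dup = table.duplicated(subset=["tutor_id", "pupil_id"])
    if dup.any():
        rows = (table.index[dup] + 2).tolist()
        raise ValueError(f"duplicate (tutor_id, pupil_id) rows at lines {rows}")
    defaults = {"relation": "biological", "clutch_id": "", "lineage_id": ""}
    for col, val in defaults.items():
        if col not in table.columns:
            table[col] = val
    bad = table["relation"].isin(["biological", "foster"])
    if not bad.all():
        rows = (table.index[~bad] + 2).tolist()
        raise ValueError(f"invalid relation value at lines {rows}")
    return table


def _float_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.6g")


def _load_or_compute_track(wav: Path, cache_dir: Path, cfg: PipelineConfig,
                           bird_id: str) -> FeatureTrack:
    key = cfg.features.__dict__
    tag = hashlib.sha256(json.dumps(key, sort_keys=True).encode()).hexdigest()[:12]
    cache = cache_dir / f"features_{bird_id}_{tag}.csv"
    if cache.exists():
        return FeatureTrack.from_frame(pd.read_csv(cache), cfg.features, bird_id)
    track = compute_features(read_wav(wav), cfg.features, bird_id=bird_id)
    _float_csv(track.to_frame(), cache)
    return track


def run_pipeline(corpus_dir, pairs_path, config: PipelineConfig | None = None,
                 out_dir="songstates_report") -> Path:
    """Run every stage on a corpus directory and write a report directory.

    ``corpus_dir`` must contain one ``<bird_id>.wav`` per bird named in
    the pairs table. Outputs: per-bird ``diversity.csv``, per-pair
    ``pair_scores.csv``, ``syllables.csv``, the fitted ``partition.json``
    and ``null_model.json``, statistics CSVs, and ``summary.json``.
    """
    cfg = config or PipelineConfig()
    corpus = Path(corpus_dir)
    out = Path(out_dir)
    cache = out / "cache"
    cache.mkdir(parents=True, exist_ok=True)
    pairs = read_pairs_table(pairs_path)

    birds = sorted(set(pairs["tutor_id"]) | set(pairs["pupil_id"]))
    missing = [b for b in birds if not (corpus / f"{b}.wav").exists()]
    if missing:
        raise FileNotFoundError(
            "missing audio for ids: " + ", ".join(missing))

    log.info("pipeline start: %d birds, %d pairs, config %s",
             len(birds), len(pairs), cfg.content_hash())

    tracks = {b: _load_or_compute_track(corpus / f"{b}.wav", cache, cfg, b)
              for b in birds}

    partition = fit_partition(tracks.values(), cfg.partition)
    partition.to_json(out / "partition.json")

    vectors = {}
    for b, tr in tracks.items():
        vectors[b] = state_abundances(assign_states(tr, partition))
    div = abundance_table(vectors)
    _float_csv(div, out / "diversity.csv")

    null = build_null(
        [tracks[b] for b in sorted(set(pairs["tutor_id"]))],
        seed=cfg.seed, n_pairs=cfg.similarity.null_pairs,
        window_ms=cfg.similarity.window_ms, hop_ms=cfg.similarity.hop_ms,
        min_tracks=cfg.similarity.null_min_tracks)
    null.to_json(out / "null_model.json")

    score_rows = []
    for k, row in pairs.iterrows():
        t, p = tracks[row["tutor_id"]], tracks[row["pupil_id"]]
        pair_seed = cfg.seed * 100003 + k
        sim = score(t, p, null, alpha=cfg.similarity.alpha,
                    repeats=cfg.similarity.repeats, seed=pair_seed)
        infl = influence(t, p, null, alpha=cfg.similarity.alpha,
                         repeats=cfg.similarity.repeats, seed=pair_seed)
        rec = dict(row)
        rec.update({
            "similarity_pct": sim.similarity_pct,
            "influence_pct": infl.similarity_pct,
            "tutor_diversity_bits": shannon_diversity(vectors[row["tutor_id"]]),
            "pupil_diversity_bits": shannon_diversity(vectors[row["pupil_id"]]),
            "tutor_n_windows": vectors[row["tutor_id"]].n_windows,
            "pupil_n_windows": vectors[row["pupil_id"]].n_windows,
        })
        for i in range(10):
            rec[f"tutor_p{i + 1}"] = vectors[row["tutor_id"]].p[i]
            rec[f"pupil_p{i + 1}"] = vectors[row["pupil_id"]].p[i]
        score_rows.append(rec)
    scored = pd.DataFrame(score_rows)
    _float_csv(scored, out / "pair_scores.csv")

    syl_rows = []
    for b, tr in tracks.items():
        tab = cluster_types(segment(tr, cfg.segmentation), cfg.segmentation)
        tab.insert(0, "bird_id", b)
        syl_rows.append(tab)
    _float_csv(pd.concat(syl_rows, ignore_index=True), out / "syllables.csv")

    summary: dict = {"config_hash": cfg.content_hash(), "seed": cfg.seed,
                     "n_birds": len(birds), "n_pairs": len(pairs)}
    gc = _stats.gain_curve(scored, bin_width=cfg.stats.gain_bin_width)
    _float_csv(gc.to_frame(), out / "gain_curve.csv")
    try:
        sh = _stats.direction_shuffle_test(
            scored, threshold=cfg.stats.bias_threshold,
            n_shuffles=cfg.stats.n_shuffles, seed=cfg.seed)
        summary["diagonal_bias"] = {
            "observed": sh.observed_bias, "reverse": sh.reverse_bias,
            "statistic": sh.statistic, "p_value": sh.p_value,
            "n_shuffles": sh.n_shuffles}
    except ValueError as exc:
        summary["diagonal_bias"] = {"skipped": str(exc)}
    try:
        slope, r2 = _stats.abundance_regression(scored)
        summary["abundance_regression"] = {"slope": slope, "residual_r2": r2}
    except ValueError as exc:
        summary["abundance_regression"] = {"skipped": str(exc)}
    _float_csv(_stats.reversal_table(scored), out / "reversals.csv")
    try:
        fam, across = _stats.family_cv_analysis(scored)
        _float_csv(fam, out / "family_cv.csv")
        summary["family_cv_across"] = across
    except ValueError as exc:
        summary["family_cv"] = {"skipped": str(exc)}
    summary["median_diversity_bits"] = float(div["diversity_bits"].median())
    summary["mean_similarity_pct"] = float(scored["similarity_pct"].mean())
    summary["mean_influence_pct"] = float(scored["influence_pct"].mean())
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    log.info("pipeline done: report in %s", out)
    return out
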