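"""Syllable segmentation, typing, diversity, and recombination.

Syllables are continuous voiced segments bounded by amplitude-threshold
crossings. Per syllable the mean acoustic features are tabulated; within
a bird, syllables are clustered into *types* by single-linkage
(nearest-neighbor) agglomerative clustering on z-scored features, and
the Shannon entropy of the type frequencies gives syllable-type
diversity. Song-syntax (bigram) entropy applies the same measure to
ordered pairs of consecutive syllable types within a bout.

Recombination detection compares tutor and pupil syllable boundaries
inside significantly similar (copied) regions: one pupil syllable
spanning two or more disjoint tutor syllables is a *merge*; one tutor
syllable mapping into two or more disjoint pupil syllables is a
*split*. Only tutor syllables whose duration is covered at least 80% by
similarity sections are considered, an operationalization of restricting
the analysis to clearly and fully imitated syllables; counts are a lower
bound on recombination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import entropy as _scipy_entropy

from .features import FeatureTrack, voiced_segments
from .similarity import NullModel, score

__all__ = ["SegmentConfig", "RecombinationEvent", "segment",
           "cluster_types", "type_diversity", "syntax_entropy",
           "detect_recombination"]

SYLLABLE_COLUMNS = ["onset_s", "offset_s", "duration_ms", "mean_pitch_hz",
                    "mean_fm_deg", "mean_wiener_entropy", "mean_continuity",
                    "type_label", "bout_id"]


@dataclass(frozen=True)
class SegmentConfig:
    min_dur_ms: float = 15.0
    min_gap_ms: float = 5.0
    cluster_cutoff: float = 1.5  # z-units, single-linkage distance
    min_section_coverage: float = 0.8


def segment(track: FeatureTrack,
            config: SegmentConfig | None = None,
            bout_id: int = 0) -> pd.DataFrame:
    """Amplitude-threshold syllable table of one bout.

    Columns: onset/offset (s), duration (ms), mean pitch / FM (signed) /
    Wiener entropy / continuity over the syllable's voiced windows,
    ``type_label`` (unassigned = -1) and ``bout_id``.
    """
    cfg = config or SegmentConfig()
    rows = []
    for onset, offset in voiced_segments(track, min_gap_ms=cfg.min_gap_ms,
                                         min_dur_ms=cfg.min_dur_ms):
        m = (track.time_s >= onset) & (track.time_s < offset) & track.voiced
        rows.append({
            "onset_s": onset, "offset_s": offset,
            "duration_ms": (offset - onset) * 1000.0,
            "mean_pitch_hz": float(np.nanmean(track.pitch_hz[m])),
            "mean_fm_deg": float(np.mean(track.fm_signed[m])),
            "mean_wiener_entropy": float(np.mean(track.wiener_entropy[m])),
            "mean_continuity": float(np.mean(track.spectral_continuity[m])),
            "type_label": -1, "bout_id": bout_id,
        })
    return pd.DataFrame(rows, columns=SYLLABLE_COLUMNS)


_CLUSTER_FEATURES = ["duration_ms", "mean_pitch_hz", "mean_fm_deg",
                     "mean_wiener_entropy", "mean_continuity"]
# floor on each feature's z-scale: roughly the measurement resolution of
# the extractor, so near-constant features do not amplify pure noise
_SCALE_FLOORS = np.array([10.0, 50.0, 5.0, 0.2, 0.02])


def cluster_types(table: pd.DataFrame,
                  config: SegmentConfig | None = None) -> pd.DataFrame:
    """Assign syllable-type labels by nearest-neighbor clustering.

    Features are z-scored; single-linkage trees are cut at
    ``config.cluster_cutoff`` (z-units). Labels are renumbered 1..k in
    order of first temporal occurrence, so the labeling is invariant to
    row order. A table with fewer than 2 syllables gets a single type.
    """
    cfg = config or SegmentConfig()
    out = table.sort_values(["bout_id", "onset_s"]).reset_index(drop=True)
    n = len(out)
    if n == 0:
        return out
    if n == 1:
        out.loc[:, "type_label"] = 1
        return out
    X = out[_CLUSTER_FEATURES].to_numpy(float)
    mu = X.mean(axis=0)
    sd = np.maximum(X.std(axis=0), _SCALE_FLOORS)
    Z = (X - mu) / sd
    raw = fcluster(linkage(Z, method="single"), t=cfg.cluster_cutoff,
                   criterion="distance")
    # canonical labels by first occurrence
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[i] = remap[r]
    out.loc[:, "type_label"] = labels
    return out


def type_diversity(table: pd.DataFrame) -> float:
    """Shannon entropy (bits) of syllable-type relative frequencies."""
    if len(table) == 0:
        raise ValueError("empty syllable table")
    if (table["type_label"] < 0).any():
        raise ValueError("type labels not assigned; run cluster_types first")
    freqs = table["type_label"].value_counts().to_numpy(float)
    return float(_scipy_entropy(freqs / freqs.sum(), base=2))


def syntax_entropy(table: pd.DataFrame) -> float:
    """Shannon entropy (bits) of ordered type bigrams within bouts."""
    if len(table) < 2:
        raise ValueError("need at least 2 syllables for syntax entropy")
    if (table["type_label"] < 0).any():
        raise ValueError("type labels not assigned; run cluster_types first")
    bigrams: dict[tuple[int, int], int] = {}
    for _, bout in table.sort_values("onset_s").groupby("bout_id"):
        lab = bout["type_label"].to_numpy(int)
        for a, b in zip(lab[:-1], lab[1:]):
            bigrams[(a, b)] = bigrams.get((a, b), 0) + 1
    if not bigrams:
        raise ValueError("no within-bout transitions")
    counts = np.array(list(bigrams.values()), dtype=float)
    return float(_scipy_entropy(counts / counts.sum(), base=2))


@dataclass
class RecombinationEvent:
    """One boundary-recombination event between tutor and pupil songs."""

    kind: str  # "merge" | "split"
    tutor_intervals: list[tuple[float, float]]
    pupil_intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.kind == "merge":
            assert len(self.tutor_intervals) >= 2 and len(self.pupil_intervals) == 1
        elif self.kind == "split":
            assert len(self.tutor_intervals) == 1 and len(self.pupil_intervals) >= 2
        else:
            raise ValueError(f"unknown recombination kind {self.kind!r}")


def _overlap(iv: tuple[float, float], jv: tuple[float, float]) -> float:
    return max(0.0, min(iv[1], jv[1]) - max(iv[0], jv[0]))


def detect_recombination(tutor: FeatureTrack, pupil: FeatureTrack,
                         tutor_sylls: pd.DataFrame,
                         pupil_sylls: pd.DataFrame,
                         null: NullModel, alpha: float = 0.05,
                         config: SegmentConfig | None = None
                         ) -> list[RecombinationEvent]:
    """Merge/split events between tutor and pupil syllable boundaries.

    Similarity sections (tutor as reference) are intersected with the
    two syllable tables. Swapping the roles of tutor and pupil swaps
    merge and split labels for the same underlying construction.
    """
    cfg = config or SegmentConfig()
    res = score(tutor, pupil, null, alpha=alpha, repeats=1, seed=0)
    if not res.sections:
        return []
    t_iv = list(zip(tutor_sylls["onset_s"], tutor_sylls["offset_s"]))
    p_iv = list(zip(pupil_sylls["onset_s"], pupil_sylls["offset_s"]))

    # coverage of each tutor syllable by all sections
    cov = np.zeros(len(t_iv))
    for k, iv in enumerate(t_iv):
        tot = sum(_overlap(iv, s.ref_interval) for s in res.sections)
        cov[k] = tot / max(iv[1] - iv[0], 1e-9)
    well_covered = cov >= cfg.min_section_coverage

    # map: which pupil syllable does each (tutor syllable, section) land in
    links: list[tuple[int, int]] = []  # (tutor idx, pupil idx)
    for s in res.sections:
        for ti, iv in enumerate(t_iv):
            if not well_covered[ti]:
                continue
            if _overlap(iv, s.ref_interval) < 0.5 * min(
                    iv[1] - iv[0], s.ref_interval[1] - s.ref_interval[0]):
                continue
            for pi, jv in enumerate(p_iv):
                olap = _overlap(jv, s.target_interval)
                if olap >= 0.5 * min(jv[1] - jv[0],
                                     s.target_interval[1] - s.target_interval[0]):
                    links.append((ti, pi))
    links = sorted(set(links))

    def _consecutive_runs(idx: list[int]) -> list[list[int]]:
        runs, cur = [], [idx[0]]
        for k in idx[1:]:
            if k == cur[-1] + 1:
                cur.append(k)
            else:
                runs.append(cur)
                cur = [k]
        runs.append(cur)
        return [r for r in runs if len(r) >= 2]

    # repeated motifs produce one copy of each event per repeat; collapse
    # events whose interval durations coincide (within 20 ms)
    seen: list[tuple] = []

    def _signature(kind: str, tivs, pivs) -> tuple:
        return (kind, tuple(b - a for a, b in tivs),
                tuple(b - a for a, b in pivs))

    def _is_dup(sig: tuple) -> bool:
        for kind, tdur, pdur in seen:
            if (kind == sig[0] and len(tdur) == len(sig[1])
                    and len(pdur) == len(sig[2])
                    and all(abs(a - b) < 0.02 for a, b in zip(tdur, sig[1]))
                    and all(abs(a - b) < 0.02 for a, b in zip(pdur, sig[2]))):
                return True
        return False

    events: list[RecombinationEvent] = []
    # merge: >= 2 *consecutive* tutor syllables linked into one pupil
    # syllable (consecutiveness rules out matches across motif repeats)
    by_pupil: dict[int, list[int]] = {}
    for ti, pi in links:
        by_pupil.setdefault(pi, []).append(ti)
    for pi, tis in sorted(by_pupil.items()):
        for run in _consecutive_runs(sorted(set(tis))):
            sig = _signature("merge", [t_iv[t] for t in run], [p_iv[pi]])
            if _is_dup(sig):
                continue
            seen.append(sig)
            events.append(RecombinationEvent(
                kind="merge", tutor_intervals=[t_iv[t] for t in run],
                pupil_intervals=[p_iv[pi]]))
    # split: one tutor syllable linked into >= 2 consecutive pupil syllables
    by_tutor: dict[int, list[int]] = {}
    for ti, pi in links:
        by_tutor.setdefault(ti, []).append(pi)
    for ti, pis in sorted(by_tutor.items()):
        for run in _consecutive_runs(sorted(set(pis))):
            sig = _signature("split", [t_iv[ti]], [p_iv[p] for p in run])
            if _is_dup(sig):
                continue
            seen.append(sig)
            events.append(RecombinationEvent(
                kind="split", tutor_intervals=[t_iv[ti]],
                pupil_intervals=[p_iv[p] for p in run]))
    return events


def recombination_table(events: list[RecombinationEvent]) -> pd.DataFrame:
    """Flatten events for CSV export."""
    rows = []
    for e in events:
        rows.append({
            "kind": e.kind,
            "tutor_intervals": ";".join(f"{a:.3f}-{b:.3f}"
                                        for a, b in e.tutor_intervals),
            "pupil_intervals": ";".join(f"{a:.3f}-{b:.3f}"
                                        for a, b in e.pupil_intervals),
        })
    return pd.DataFrame(rows, columns=["kind", "tutor_intervals",
                                       "pupil_intervals"])
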