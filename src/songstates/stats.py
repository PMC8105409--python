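"""Balanced-imitation statistics over tutor-pupil pair tables.

The central question: when a pupil copies a tutor's song, are the
relative abundances of the ten vocal states copied faithfully, or are
common states attenuated and rare states amplified ("balanced
imitation")? The operations here quantify that bias on a table of
tutor-pupil pairs carrying abundance vectors and similarity scores:

* quartile partition by imitation similarity,
* detrended tutor/pupil abundance regressions (overall state-abundance
  trends removed so shuffled pairings correlate at zero),
* the diagonal-bias statistic at a 20% abundance threshold, with a
  direction-shuffle null that swaps tutor/pupil roles within pairs,
* abundance gain curves (median pupil abundance per 0.1-wide tutor
  abundance bin over the bin center),
* pooled-diversity contrasts, per-tutor diversity reversals, mean song
  feature ranges by influence quartile, and family-level variance of
  imitation.

The pair table is a pandas DataFrame with columns ``tutor_id``,
``pupil_id``, ``relation``, ``clutch_id``, ``lineage_id``,
``similarity_pct``, ``influence_pct``, ``tutor_diversity_bits``,
``pupil_diversity_bits`` and abundance columns ``tutor_p1..p10`` /
``pupil_p1..p10`` (optionally ``{tutor,pupil}_n_windows``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureTrack
from .states import AbundanceVector, N_STATES, pooled_diversity, shannon_diversity

__all__ = [
    "PairRecord", "GainCurve", "BiasResult", "records_to_frame",
    "quartile_partition", "detrend_abundances", "abundance_regression",
    "diagonal_bias", "direction_shuffle_test", "gain_curve",
    "pooled_quartile_diversity", "mean_song_features",
    "influence_feature_ranges", "reversal_table", "family_cv_analysis",
    "bonferroni",
]

TUTOR_P = [f"tutor_p{i}" for i in range(1, N_STATES + 1)]
PUPIL_P = [f"pupil_p{i}" for i in range(1, N_STATES + 1)]


@dataclass
class PairRecord:
    """One tutor-pupil pair with scores, diversities, and abundances."""

    tutor_id: str
    pupil_id: str
    relation: str = "biological"
    clutch_id: str = ""
    lineage_id: str = ""
    similarity_pct: float = np.nan
    influence_pct: float = np.nan
    tutor_diversity_bits: float = np.nan
    pupil_diversity_bits: float = np.nan
    tutor_p: AbundanceVector | None = None
    pupil_p: AbundanceVector | None = None

    def __post_init__(self) -> None:
        if not self.tutor_id or not self.pupil_id:
            raise ValueError("tutor_id and pupil_id must be non-empty")
        for pct in (self.similarity_pct, self.influence_pct):
            if np.isfinite(pct) and not (0.0 <= pct <= 100.0):
                raise ValueError("percentages must lie in [0, 100]")
        for d in (self.tutor_diversity_bits, self.pupil_diversity_bits):
            if np.isfinite(d) and not (0.0 <= d <= np.log2(N_STATES) + 1e-9):
                raise ValueError("diversities must lie in [0, 3.322] bits")


def records_to_frame(records: list[PairRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "tutor_id": r.tutor_id, "pupil_id": r.pupil_id,
            "relation": r.relation, "clutch_id": r.clutch_id,
            "lineage_id": r.lineage_id, "similarity_pct": r.similarity_pct,
            "influence_pct": r.influence_pct,
            "tutor_diversity_bits": r.tutor_diversity_bits,
            "pupil_diversity_bits": r.pupil_diversity_bits,
        }
        if r.tutor_p is not None:
            row.update({c: r.tutor_p.p[i] for i, c in enumerate(TUTOR_P)})
            row["tutor_n_windows"] = r.tutor_p.n_windows
        if r.pupil_p is not None:
            row.update({c: r.pupil_p.p[i] for i, c in enumerate(PUPIL_P)})
            row["pupil_n_windows"] = r.pupil_p.n_windows
        rows.append(row)
    return pd.DataFrame(rows)


def quartile_partition(pairs: pd.DataFrame,
                       by: str = "similarity_pct") -> pd.Series:
    """Quartile labels Q1..Q4 by ``by``; Q1 is the highest quartile.

    Ties and group sizes are resolved by stable sorting in input order;
    requires at least 4 pairs.
    """
    n = len(pairs)
    if n < 4:
        raise ValueError("need at least 4 pairs for quartiles")
    order = np.argsort(-pairs[by].to_numpy(), kind="stable")
    labels = np.empty(n, dtype=object)
    for q, chunk in enumerate(np.array_split(order, 4)):
        labels[chunk] = f"Q{q + 1}"
    return pd.Series(labels, index=pairs.index, name="quartile")


def detrend_abundances(pairs: pd.DataFrame) -> pd.DataFrame:
    """Center each vocal state's abundance on its population mean.

    Tutor and pupil columns are centered on their own means, making
    every state equally abundant on average; after detrending, shuffled
    tutor-pupil pairings correlate at zero in expectation.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to detrend")
    out = pairs.copy()
    out[TUTOR_P] = pairs[TUTOR_P] - pairs[TUTOR_P].mean()
    out[PUPIL_P] = pairs[PUPIL_P] - pairs[PUPIL_P].mean()
    return out


def _stacked_xy(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = pairs[TUTOR_P].to_numpy(float).ravel()
    y = pairs[PUPIL_P].to_numpy(float).ravel()
    tutors = np.repeat(pairs["tutor_id"].to_numpy(), N_STATES)
    return x, y, tutors


def abundance_regression(pairs: pd.DataFrame,
                         quartile: str | None = None,
                         detrended: bool = False,
                         cluster_by_tutor: bool = False):
    """Regress detrended pupil abundances on detrended tutor abundances.

    Ten points per pair are stacked; returns ``(slope, residual_R2)``.
    With ``cluster_by_tutor`` the slope's standard error is cluster
    robust (repeated tutors), via statsmodels.
    """
    import statsmodels.api as sm

    sub = pairs
    if quartile is not None:
        q = quartile_partition(pairs)
        sub = pairs[q == quartile]
    if len(sub) < 2:
        raise ValueError("need at least 2 pairs in the group")
    if not detrended:
        sub = detrend_abundances(sub)
    x, y, tutors = _stacked_xy(sub)
    if np.var(x) < 1e-18 or np.var(y) < 1e-18:
        raise ValueError("degenerate abundances: zero variance")
    X = sm.add_constant(x)
    if cluster_by_tutor:
        fit = sm.OLS(y, X).fit(cov_type="cluster",
                               cov_kwds={"groups": pd.factorize(tutors)[0]})
    else:
        fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.rsquared)


@dataclass
class BiasResult:
    """Diagonal bias of tutor-vs-pupil state abundances.

    ``observed_bias``: of the points with tutor abundance above the
    threshold, the fraction whose pupil abundance falls below the
    diagonal (imitation attenuates an already-common state).
    ``reverse_bias``: the same with tutor and pupil roles swapped.
    ``statistic`` is their difference; positive values mean deviations
    preferentially flatten the pupil's song.
    """

    observed_bias: float
    reverse_bias: float
    statistic: float
    threshold: float
    n_points: int
    p_value: float | None = None
    n_shuffles: int = 0
    seed: int | None = None
    per_pair: pd.DataFrame | None = field(default=None, repr=False)


def _bias_counts(pairs: pd.DataFrame, threshold: float):
    """Per-pair counts feeding the bias statistic."""
    t = pairs[TUTOR_P].to_numpy(float)
    p = pairs[PUPIL_P].to_numpy(float)
    above_t = t > threshold
    above_p = p > threshold
    a = (above_t & (p < t)).sum(axis=1)   # tutor-common, pupil attenuates
    A = above_t.sum(axis=1)
    b = (above_p & (t < p)).sum(axis=1)   # pupil-common, tutor below
    B = above_p.sum(axis=1)
    return a, A, b, B


def diagonal_bias(pairs: pd.DataFrame, threshold: float = 0.2) -> BiasResult:
    """Asymmetry of above-threshold abundances around the diagonal.

    Counts are computed per pair and pooled: the observed bias is the
    fraction of above-threshold tutor states that the pupil produces at
    lower abundance, the reverse bias swaps the roles, and the statistic
    is their difference.
    """
    a, A, b, B = _bias_counts(pairs, threshold)
    if A.sum() == 0 and B.sum() == 0:
        raise ValueError("bias undefined: no abundance above threshold")
    obs = a.sum() / max(A.sum(), 1)
    rev = b.sum() / max(B.sum(), 1)
    per_pair = pd.DataFrame({"tutor_id": pairs["tutor_id"],
                             "pupil_id": pairs["pupil_id"],
                             "n_tutor_above": A, "n_pupil_attenuated": a,
                             "n_pupil_above": B, "n_tutor_below": b})
    return BiasResult(observed_bias=float(obs), reverse_bias=float(rev),
                      statistic=float(obs - rev), threshold=threshold,
                      n_points=int(A.sum() + B.sum()), per_pair=per_pair)


def direction_shuffle_test(pairs: pd.DataFrame, threshold: float = 0.2,
                           n_shuffles: int = 1000,
                           seed: int = 0) -> BiasResult:
    """Direction-shuffle null for the diagonal bias.

    Each shuffle independently swaps the tutor->pupil direction within
    each pair with probability 1/2 (pairs are never broken) and the
    statistic is recomputed; the direct p-value is
    ``(1 + #{shuffled >= observed}) / (1 + n_shuffles)``.
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles")
    base = diagonal_bias(pairs, threshold)
    a, A, b, B = _bias_counts(pairs, threshold)
    rng = np.random.default_rng(seed)
    flips = rng.random((n_shuffles, len(pairs))) < 0.5
    keep = ~flips
    a_s = keep @ a + flips @ b
    A_s = keep @ A + flips @ B
    b_s = keep @ b + flips @ a
    B_s = keep @ B + flips @ A
    stat_s = a_s / np.maximum(A_s, 1) - b_s / np.maximum(B_s, 1)
    p = (1.0 + (stat_s >= base.statistic).sum()) / (1.0 + n_shuffles)
    return BiasResult(observed_bias=base.observed_bias,
                      reverse_bias=base.reverse_bias,
                      statistic=base.statistic, threshold=threshold,
                      n_points=base.n_points, p_value=float(p),
                      n_shuffles=n_shuffles, seed=seed,
                      per_pair=base.per_pair)


@dataclass
class GainCurve:
    """Median imitation gain per tutor-abundance bin.

    Bins of width 0.1 are centered at 0.1, 0.2, ...; the gain of a bin
    is the median pupil abundance of points falling in the bin divided
    by the bin center. A gain of 1 means abundances are copied
    faithfully; >1 amplification; <1 attenuation.
    """

    bin_centers: np.ndarray
    medians: np.ndarray
    gains: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers,
                             "median_pupil_abundance": self.medians,
                             "gain": self.gains, "n": self.counts})


def gain_curve(pairs: pd.DataFrame, bin_width: float = 0.1) -> GainCurve:
    """Gain curve over all (tutor, pupil) state-abundance points.

    Bin k covers [center - width/2, center + width/2) around center
    k*width; unpopulated bins (and the zero-centered bin, whose gain is
    undefined) are omitted.
    """
    if len(pairs) < 1:
        raise ValueError("need at least 1 pair")
    t = pairs[TUTOR_P].to_numpy(float).ravel()
    p = pairs[PUPIL_P].to_numpy(float).ravel()
    idx = np.round(t / bin_width).astype(int)
    centers, medians, gains, counts = [], [], [], []
    for k in sorted(set(idx)):
        if k == 0:
            continue
        center = k * bin_width
        m = idx == k
        if not m.any():
            continue
        med = float(np.median(p[m]))
        centers.append(center)
        medians.append(med)
        gains.append(med / center)
        counts.append(int(m.sum()))
    return GainCurve(bin_centers=np.array(centers),
                     medians=np.array(medians), gains=np.array(gains),
                     counts=np.array(counts, dtype=int))


def pooled_quartile_diversity(pairs: pd.DataFrame,
                              by: str = "tutor_diversity_bits"):
    """Pooled vs mean diversity for bottom and top quartiles of ``by``.

    Tutor songs are pooled (count-weighted when ``tutor_n_windows`` is
    present) within the bottom and top quartile of the ranking column;
    returns a dict with pooled and mean per-bird diversities.
    """
    if len(pairs) < 8:
        raise ValueError("need at least 8 pairs")
    q = quartile_partition(pairs, by=by)  # Q1 = highest

    def _pool(sub: pd.DataFrame):
        dedup = sub.drop_duplicates("tutor_id")
        n = dedup["tutor_n_windows"].to_numpy(int) if "tutor_n_windows" in dedup \
            else np.full(len(dedup), 1000)
        vecs = [AbundanceVector(p=row, n_windows=int(nw))
                for row, nw in zip(dedup[TUTOR_P].to_numpy(float), n)]
        return (pooled_diversity(vecs),
                float(np.mean([shannon_diversity(v) for v in vecs])))

    bottom_pooled, bottom_mean = _pool(pairs[q == "Q4"])
    top_pooled, top_mean = _pool(pairs[q == "Q1"])
    return {"bottom_pooled_bits": bottom_pooled,
            "bottom_mean_bits": bottom_mean,
            "top_pooled_bits": top_pooled,
            "top_mean_bits": top_mean}


def mean_song_features(track: FeatureTrack) -> tuple[float, float, float]:
    """Voiced-window means of pitch (Hz), FM (deg) and Wiener entropy."""
    v = track.voiced
    if not v.any():
        raise ValueError("silent recording")
    return (float(np.nanmean(track.pitch_hz[v])),
            float(np.mean(track.fm_deg[v])),
            float(np.mean(track.wiener_entropy[v])))


def influence_feature_ranges(pairs: pd.DataFrame,
                             tutor_features: pd.DataFrame) -> pd.DataFrame:
    """Min-max tutor mean-feature intervals for influence quartiles.

    ``tutor_features`` is indexed by ``tutor_id`` with columns
    ``mean_pitch_hz``, ``mean_fm_deg``, ``mean_wiener_entropy``. Returns
    one row per (feature, quartile in {top, bottom}).
    """
    q = quartile_partition(pairs, by="influence_pct")
    rows = []
    for name, label in (("top", "Q1"), ("bottom", "Q4")):
        ids = pairs.loc[q == label, "tutor_id"].unique()
        feats = tutor_features.loc[tutor_features.index.intersection(ids)]
        for col in feats.columns:
            rows.append({"feature": col, "quartile": name,
                         "low": float(feats[col].min()),
                         "high": float(feats[col].max())})
    return pd.DataFrame(rows)


def reversal_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per tutor: own diversity, mean pupil diversity, and direction.

    ``direction`` is "increase" when pupils average above the tutor,
    "decrease" below, "tie" at (near) equality.
    """
    rows = []
    for tutor, grp in pairs.groupby("tutor_id", sort=True):
        td = float(grp["tutor_diversity_bits"].iloc[0])
        pdiv = float(grp["pupil_diversity_bits"].mean())
        delta = pdiv - td
        direction = "tie" if abs(delta) < 1e-12 else (
            "increase" if delta > 0 else "decrease")
        rows.append({"tutor_id": tutor, "tutor_diversity_bits": td,
                     "mean_pupil_diversity_bits": pdiv,
                     "n_pupils": len(grp), "direction": direction})
    return pd.DataFrame(rows)


def family_cv_analysis(pairs: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Within- vs across-family variability of imitation similarity.

    Similarity is first averaged within each clutch; per family
    (lineage) with >= 2 clutches, the coefficient of variation across
    its clutch means is computed. The across-family CV is the CV of the
    family means. Raises when no family has multiple clutches.
    """
    rows = []
    family_means = []
    for fam, grp in pairs.groupby("lineage_id", sort=True):
        clutch_means = grp.groupby("clutch_id")["similarity_pct"].mean()
        if len(clutch_means) < 2:
            continue
        mu = float(clutch_means.mean())
        cv = float(clutch_means.std(ddof=0) / mu) if mu else np.nan
        rows.append({"lineage_id": fam, "n_clutches": len(clutch_means),
                     "mean_similarity": mu, "within_cv": cv})
        family_means.append(mu)
    if not rows:
        raise ValueError("no family with at least 2 clutches")
    fm = np.array(family_means)
    across_cv = float(fm.std(ddof=0) / fm.mean()) if fm.mean() else np.nan
    return pd.DataFrame(rows), across_cv


def bonferroni(p_values, alpha: float = 0.01):
    """Bonferroni-adjusted p-values and significance calls."""
    p = np.asarray(list(p_values), dtype=float)
    adj = np.minimum(p * p.size, 1.0)
    return adj, adj < alpha
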