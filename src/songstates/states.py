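"""The 10-state partition of acoustic space and song diversity.

The population's voiced windows are partitioned into ten *vocal states*:
the pooled pitch density is cut at the three deepest minima between its
four main modes (very low / low / medium / high pitch regions), and
within each region states are defined around density peaks in the
(signed frequency modulation, Wiener entropy) plane. Every voiced window
is then assigned to exactly one state — no residuals — by nearest center
within its pitch region.

Song diversity is the Shannon entropy (bits) of a bird's vocal-state
abundance vector: at most log2(10) = 3.32 bits when all ten states are
equally abundant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d, maximum_filter
from scipy.signal import find_peaks
from scipy.stats import entropy as _scipy_entropy

from .features import FeatureTrack

__all__ = [
    "PartitionConfig", "StatePartition", "VocalStateSequence",
    "AbundanceVector", "fit_partition", "assign_states",
    "state_abundances", "shannon_diversity", "pooled_diversity",
]

N_STATES = 10


@dataclass(frozen=True)
class PartitionConfig:
    """Settings for fitting the population-level state partition."""

    n_regions: int = 4
    states_per_region: tuple[int, ...] = (2, 3, 3, 2)
    min_windows: int = 10000
    pitch_bins: int = 256
    plane_bins: int = 64
    smooth_scale: float | None = None  # None = Silverman-style default
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.states_per_region) != self.n_regions:
            raise ValueError("states_per_region length must equal n_regions")
        if sum(self.states_per_region) != N_STATES:
            raise ValueError("state counts must sum to 10")


@dataclass
class AbundanceVector:
    """Proportions of a bird's sounds in each of the 10 vocal states."""

    p: np.ndarray
    n_windows: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (N_STATES,):
            raise ValueError("abundance vector must have 10 entries")
        if (p < -1e-12).any():
            raise ValueError("abundances must be non-negative")
        if self.n_windows > 0 and abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        self.p = np.clip(p, 0.0, None)


@dataclass
class VocalStateSequence:
    """Per-voiced-window state labels (1..10) of one song bout."""

    states: np.ndarray
    bird_id: str | None = None
    times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=int)
        if s.size and (s.min() < 1 or s.max() > N_STATES):
            raise ValueError("states must lie in 1..10")
        self.states = s

    def __len__(self) -> int:
        return self.states.size


@dataclass
class StatePartition:
    """The population-level rule mapping any voiced window to a state.

    ``pitch_edges`` are the three increasing pitch thresholds (Hz)
    separating the four regions. Per region, ``centers[r]`` is an
    ``(k_r, 2)`` array of cluster centers in the (signed FM in degrees,
    Wiener entropy) plane, and assignment is nearest center after
    dividing each axis by ``scale``; ties go to the lower state label.
    ``state_offsets[r]`` is the first (1-based) label of region r.
    """

    pitch_edges: np.ndarray
    centers: list[np.ndarray]
    scale: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pitch_edges = np.asarray(self.pitch_edges, dtype=float)
        if self.pitch_edges.size != len(self.centers) - 1:
            raise ValueError("need one fewer edge than regions")
        if not np.all(np.diff(self.pitch_edges) > 0):
            raise ValueError("pitch_edges must be strictly increasing")
        if sum(len(c) for c in self.centers) != N_STATES:
            raise ValueError("partition must define exactly 10 states")

    @property
    def state_offsets(self) -> list[int]:
        offs, k = [], 1
        for c in self.centers:
            offs.append(k)
            k += len(c)
        return offs

    def assign(self, pitch_hz: np.ndarray, fm_signed_deg: np.ndarray,
               wiener_entropy: np.ndarray) -> np.ndarray:
        """Map feature triples to state labels 1..10 (vectorized)."""
        pitch = np.asarray(pitch_hz, float)
        region = np.searchsorted(self.pitch_edges, pitch)
        labels = np.empty(pitch.size, dtype=int)
        pts = np.column_stack([np.asarray(fm_signed_deg, float),
                               np.asarray(wiener_entropy, float)]) / self.scale
        offsets = self.state_offsets
        for r, centers in enumerate(self.centers):
            m = region == r
            if not m.any():
                continue
            sc = centers / self.scale
            d2 = ((pts[m, None, :] - sc[None, :, :]) ** 2).sum(axis=2)
            # round distances so numerically equidistant centers tie,
            # then argmin picks the lower label
            labels[m] = offsets[r] + np.argmin(np.round(d2, 9), axis=1)
        return labels

    def to_json(self, path=None) -> str:
        doc = {
            "schema": "songstates.partition/1",
            "pitch_edges": self.pitch_edges.tolist(),
            "centers": [c.tolist() for c in self.centers],
            "scale": self.scale.tolist(),
            "meta": self.meta,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "StatePartition":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(pitch_edges=np.array(doc["pitch_edges"]),
                   centers=[np.array(c) for c in doc["centers"]],
                   scale=np.array(doc["scale"]),
                   meta=doc.get("meta", {}))


def _pooled_voiced(tracks) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pitch, fm, went = [], [], []
    for tr in tracks:
        v = tr.voiced
        pitch.append(tr.pitch_hz[v])
        fm.append(tr.fm_signed[v])
        went.append(tr.wiener_entropy[v])
    return (np.concatenate(pitch), np.concatenate(fm), np.concatenate(went))


def _density_modes_edges(values: np.ndarray, n_regions: int, bins: int,
                         smooth_scale: float | None):
    """Mode peaks and between-mode minima of a smoothed 1-D density."""
    hist, edges = np.histogram(values, bins=bins)
    binw = edges[1] - edges[0]
    if smooth_scale is None:
        iqr = np.subtract(*np.percentile(values, [75, 25]))
        sd = min(values.std(), iqr / 1.349) or values.std()
        bw = 0.9 * sd * values.size ** (-0.2)
        sigma = max(bw / binw, 1.0)
    else:
        sigma = max(smooth_scale / binw, 1.0)
    dens = gaussian_filter1d(hist.astype(float), sigma, mode="nearest")
    # zero-pad so modes at the range edges are detected too
    padded = np.concatenate(([0.0], dens, [0.0]))
    peaks, props = find_peaks(padded, prominence=0.0)
    peaks = peaks - 1
    if peaks.size < n_regions:
        raise ValueError("degenerate pitch distribution: "
                         f"found {peaks.size} modes, need {n_regions}")
    top = peaks[np.argsort(props["prominences"])[::-1][:n_regions]]
    top = np.sort(top)
    cuts = []
    for a, b in zip(top[:-1], top[1:]):
        j = a + int(np.argmin(dens[a:b + 1]))
        cuts.append(0.5 * (edges[j] + edges[j + 1]))
    return np.array(cuts), float(sigma * binw)


def _plane_peaks(x: np.ndarray, y: np.ndarray, k: int, bins: int,
                 scale: np.ndarray, min_sep_fm: float = 0.8,
                 min_sep_entropy: float = 2.0) -> np.ndarray:
    """Top-k density peaks in the (x, y) = (signed FM, entropy) plane.

    Greedy selection treats two maxima as one cluster unless they are
    separated along FM (by ``min_sep_fm`` FM standard deviations) or,
    failing that, far apart in entropy (``min_sep_entropy`` standard
    deviations): within-cluster entropy fluctuations are comparable to
    between-cluster differences, so entropy alone rarely distinguishes
    states, while the up/flat/down modulation classes always do. If
    fewer separated maxima exist than states, remaining centers go on
    the populated bin farthest (scaled max-min distance) from every
    chosen center, so sparse but real clusters still get a center of
    their own.
    """
    xr = np.percentile(x, [1, 99])
    yr = np.percentile(y, [1, 99])
    xr = (xr[0] - 1e-6, xr[1] + 1e-6)
    yr = (yr[0] - 1e-6, yr[1] + 1e-6)
    hist, xe, ye = np.histogram2d(x, y, bins=bins, range=(xr, yr))
    dens = gaussian_filter(hist, sigma=bins / 24.0, mode="nearest")
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])

    def scaled_dist(i, j, ci, cj):
        return np.hypot((xc[i] - xc[ci]) / scale[0],
                        (yc[j] - yc[cj]) / scale[1])

    def distinct(i, j, ci, cj):
        return (abs(xc[i] - xc[ci]) / scale[0] >= min_sep_fm
                or abs(yc[j] - yc[cj]) / scale[1] >= min_sep_entropy)

    local_max = (maximum_filter(dens, size=5, mode="nearest") == dens) & (dens > 0)
    ii, jj = np.nonzero(local_max)
    order = np.argsort(dens[ii, jj])[::-1]
    chosen: list[tuple[int, int]] = []
    for o in order:
        i, j = int(ii[o]), int(jj[o])
        if all(distinct(i, j, ci, cj) for ci, cj in chosen):
            chosen.append((i, j))
        if len(chosen) == k:
            break
    occupied = np.argwhere(dens >= 0.02 * dens.max())
    while len(chosen) < k and occupied.size:
        dmin = np.full(len(occupied), np.inf)
        for ci, cj in chosen:
            dd = scaled_dist(occupied[:, 0], occupied[:, 1], ci, cj)
            dmin = np.minimum(dmin, dd)
        best = int(np.argmax(dmin)) if chosen else int(
            np.argmax(dens[occupied[:, 0], occupied[:, 1]]))
        chosen.append((int(occupied[best, 0]), int(occupied[best, 1])))
    return np.array([(xc[i], yc[j]) for i, j in chosen])


def fit_partition(tracks, config: PartitionConfig | None = None) -> StatePartition:
    """Fit the population 10-state partition from pooled feature tracks.

    Raises ``ValueError`` when fewer than ``config.min_windows`` voiced
    windows are pooled, or when the pooled pitch density has fewer modes
    than regions ("degenerate pitch distribution").
    """
    cfg = config or PartitionConfig()
    pitch, fm, went = _pooled_voiced(tracks)
    if pitch.size < cfg.min_windows:
        raise ValueError(
            f"too few voiced windows: {pitch.size} < {cfg.min_windows}")
    edges, bw = _density_modes_edges(pitch, cfg.n_regions, cfg.pitch_bins,
                                     cfg.smooth_scale)
    scale = np.array([max(fm.std(), 1e-6), max(went.std(), 1e-6)])
    region = np.searchsorted(edges, pitch)
    centers = []
    for r, k in enumerate(cfg.states_per_region):
        m = region == r
        if m.sum() < k:
            raise ValueError(f"pitch region {r} has too few windows")
        c = _plane_peaks(fm[m], went[m], k, cfg.plane_bins, scale)
        # canonical labels: ascending signed FM, then entropy
        c = c[np.lexsort((c[:, 1], c[:, 0]))]
        centers.append(c)
    meta = {"n_windows": int(pitch.size), "pitch_bandwidth_hz": bw,
            "states_per_region": list(cfg.states_per_region),
            "min_windows": cfg.min_windows}
    return StatePartition(pitch_edges=edges, centers=centers, scale=scale,
                          meta=meta)


def assign_states(track: FeatureTrack,
                  partition: StatePartition) -> VocalStateSequence:
    """Assign every voiced window of a track to a vocal state."""
    v = track.voiced
    if not v.any():
        raise ValueError("silent recording: no voiced windows")
    labels = partition.assign(track.pitch_hz[v], track.fm_signed[v],
                              track.wiener_entropy[v])
    return VocalStateSequence(states=labels, bird_id=track.bird_id,
                              times_s=track.time_s[v])


def state_abundances(seq: VocalStateSequence) -> AbundanceVector:
    """Relative abundance of each vocal state in a state sequence."""
    if len(seq) == 0:
        raise ValueError("empty state sequence")
    counts = np.bincount(seq.states, minlength=N_STATES + 1)[1:]
    return AbundanceVector(p=counts / counts.sum(), n_windows=int(len(seq)))


def shannon_diversity(vec: AbundanceVector | np.ndarray) -> float:
    """Song diversity: Shannon entropy of the abundance vector, in bits."""
    p = vec.p if isinstance(vec, AbundanceVector) else np.asarray(vec, float)
    return float(_scipy_entropy(p, base=2))


def pooled_diversity(vectors) -> float:
    """Diversity of the count-weighted pooled abundance vector."""
    vectors = list(vectors)
    if not vectors:
        raise ValueError("empty collection of abundance vectors")
    weights = np.array([max(v.n_windows, 1) for v in vectors], dtype=float)
    pooled = (np.stack([v.p for v in vectors]) * weights[:, None]).sum(axis=0)
    return shannon_diversity(pooled / pooled.sum())


def abundance_table(vectors: dict[str, AbundanceVector]) -> pd.DataFrame:
    """Tabulate per-bird abundances and diversities (CSV-ready)."""
    rows = []
    for bird, vec in vectors.items():
        row = {"bird_id": bird, "n_windows": vec.n_windows,
               "diversity_bits": shannon_diversity(vec)}
        row.update({f"p{i + 1}": vec.p[i] for i in range(N_STATES)})
        rows.append(row)
    return pd.DataFrame(rows)
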