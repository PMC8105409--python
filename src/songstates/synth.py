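"""Synthetic zebra-finch-like songs and tutor-pupil colonies.

Songs are rendered as sequences of syllables, each syllable a run of one
to three contiguous *notes*. A note is a harmonic stack (sum of sinusoids
at multiples of a linearly swept fundamental) mixed with band-limited
noise, so its windows land in a predictable region of the (pitch,
frequency modulation, Wiener entropy) feature space. Ten note archetypes
emulate the ten vocal states of zebra finch song: four fundamental
frequency regions, with down-modulated / unmodulated / up-modulated and
clean / noisy variants inside them.

Colonies of tutor-pupil pairs are generated with known ground truth:
per-bird vocal-state abundance vectors, syllable boundaries, which pupil
syllables were copied, and a one-parameter *balancing* transform
``p -> normalize(p**beta)`` that flattens abundant states and boosts rare
ones (beta = 1 reproduces faithful copying of abundances).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .audio import AudioClip

__all__ = [
    "SyllableSpec", "SongSpec", "ColonySpec", "ColonyData",
    "ARCHETYPES", "archetype_note", "synth_song", "simulate_pupil",
    "simulate_colony",
]

DEFAULT_SAMPLE_RATE = 22050
N_STATES = 10


@dataclass(frozen=True)
class SyllableSpec:
    """One note: a harmonic stack with a linear fundamental sweep."""

    duration_ms: float
    f0_start_hz: float
    f0_end_hz: float
    n_harmonics: int = 3
    noise_fraction: float = 0.1
    amplitude_db: float = 62.0
    state: int | None = None  # generating vocal-state label, if any

    def __post_init__(self) -> None:
        if self.duration_ms < 20:
            raise ValueError("note duration must be >= 20 ms")
        for f in (self.f0_start_hz, self.f0_end_hz):
            if not (300.0 <= f <= 3000.0):
                raise ValueError("fundamental must lie in 300-3000 Hz")
        if not (0.0 <= self.noise_fraction <= 1.0):
            raise ValueError("noise_fraction must be in [0, 1]")


Syllable = tuple  # tuple of SyllableSpec notes rendered contiguously


def _as_syllable(s) -> tuple:
    if isinstance(s, SyllableSpec):
        return (s,)
    return tuple(s)


@dataclass(frozen=True)
class SongSpec:
    """Generative description of one song bout.

    ``motif`` is an ordered list of syllables; each syllable is either a
    single :class:`SyllableSpec` or a sequence of them (multi-note
    syllable). The motif is repeated ``n_motif_repeats`` times with
    ``gap_ms`` silences between syllables.
    """

    motif: tuple
    gap_ms: float = 40.0
    n_motif_repeats: int = 2
    seed: int = 0
    sample_rate: int = DEFAULT_SAMPLE_RATE
    crossfade_ms: float = 10.0  # frequency glide between notes of a syllable

    def __post_init__(self) -> None:
        if len(self.motif) == 0:
            raise ValueError("motif must be non-empty")
        object.__setattr__(self, "motif",
                           tuple(_as_syllable(s) for s in self.motif))
        if self.total_duration_s > 10.0:
            raise ValueError("song longer than 10 s")

    @property
    def notes(self) -> list[SyllableSpec]:
        return [n for syl in self.motif for n in syl]

    @property
    def total_duration_s(self) -> float:
        syl_ms = sum(sum(n.duration_ms for n in syl) for syl in self.motif)
        gaps = (len(self.motif) * self.n_motif_repeats) * self.gap_ms
        return (syl_ms * self.n_motif_repeats + gaps) / 1000.0

    def state_abundance(self) -> np.ndarray:
        """Duration-weighted ground-truth vocal-state proportions.

        Notes adjacent to a within-syllable junction lose half the
        crossfade each, matching what the renderer produces.
        """
        d = np.zeros(N_STATES)
        half_fade = self.crossfade_ms / 2.0
        for syl in self.motif:
            for i, n in enumerate(syl):
                if n.state is None:
                    continue
                dur = n.duration_ms
                if i > 0:
                    dur -= half_fade
                if i < len(syl) - 1:
                    dur -= half_fade
                d[n.state - 1] += max(dur, 0.0)
        total = d.sum()
        if total == 0:
            raise ValueError("song has no state-labelled notes")
        return d / total


# ten note archetypes: (f0 center Hz, relative sweep, harmonics, noise)
# regions: very low ~480, low ~850, medium ~1500, high ~2600 Hz;
# within regions: down-modulated / unmodulated / up-modulated variants,
# the medium modulated ones noisier (wide-spectrum sounds)
ARCHETYPES: dict[int, dict] = {
    1: dict(f0=480.0, sweep=-0.50, harmonics=3, noise=0.08),
    2: dict(f0=480.0, sweep=+0.50, harmonics=3, noise=0.08),
    3: dict(f0=850.0, sweep=-0.40, harmonics=3, noise=0.08),
    4: dict(f0=850.0, sweep=0.0, harmonics=5, noise=0.02),
    5: dict(f0=850.0, sweep=+0.40, harmonics=3, noise=0.08),
    6: dict(f0=1500.0, sweep=-0.35, harmonics=2, noise=0.12),
    7: dict(f0=1500.0, sweep=0.0, harmonics=4, noise=0.02),
    8: dict(f0=1500.0, sweep=+0.35, harmonics=2, noise=0.12),
    9: dict(f0=2600.0, sweep=-0.20, harmonics=2, noise=0.08),
    10: dict(f0=2600.0, sweep=+0.20, harmonics=2, noise=0.08),
}


def archetype_note(state: int, rng: np.random.Generator,
                   jitter: float = 0.12,
                   duration_ms: float | None = None) -> SyllableSpec:
    """Draw one note instance of a vocal-state archetype.

    ``jitter`` sets the relative spread of the fundamental and sweep
    between instances, so different birds' renditions of the same vocal
    state are individually distinguishable, as real birds' syllables
    are. Copies between tutor and pupil jitter an existing instance far
    less (see ``jitter_note``).
    """
    a = ARCHETYPES[state]
    f0 = a["f0"] * (1.0 + rng.uniform(-jitter, jitter))
    sweep = a["sweep"] * (1.0 + rng.uniform(-2 * jitter, 2 * jitter))
    dur = duration_ms if duration_ms is not None else rng.uniform(55.0, 90.0)
    half = f0 * sweep / 2.0
    lo, hi = 310.0, 2990.0
    start = float(np.clip(f0 - half, lo, hi))
    end = float(np.clip(f0 + half, lo, hi))
    noise = float(np.clip(a["noise"] + rng.uniform(-0.03, 0.03), 0.02, 1.0))
    return SyllableSpec(duration_ms=float(dur), f0_start_hz=start,
                        f0_end_hz=end, n_harmonics=a["harmonics"],
                        noise_fraction=noise, state=state)


def jitter_note(note: SyllableSpec, rng: np.random.Generator,
                amount: float = 0.015) -> SyllableSpec:
    """Slightly perturb a note (pupil copy of a tutor note)."""
    g = 1.0 + rng.uniform(-amount, amount)
    return SyllableSpec(
        duration_ms=max(20.0, note.duration_ms * (1.0 + rng.uniform(-amount, amount))),
        f0_start_hz=float(np.clip(note.f0_start_hz * g, 300, 3000)),
        f0_end_hz=float(np.clip(note.f0_end_hz * g, 300, 3000)),
        n_harmonics=note.n_harmonics,
        noise_fraction=note.noise_fraction,
        amplitude_db=note.amplitude_db,
        state=note.state,
    )


def _render_note(note: SyllableSpec, fs: int, rng: np.random.Generator,
                 baseline_db: float = 70.0) -> np.ndarray:
    n = int(round(note.duration_ms * fs / 1000.0))
    t = np.arange(n) / fs
    f0 = np.linspace(note.f0_start_hz, note.f0_end_hz, n)
    phase = 2 * np.pi * np.cumsum(f0) / fs
    sig = np.zeros(n)
    nyq = fs / 2.0
    for k in range(1, note.n_harmonics + 1):
        if note.f0_start_hz * k >= nyq or note.f0_end_hz * k >= nyq:
            break
        sig += np.sin(k * phase) / k
    rms = np.sqrt(np.mean(sig**2))
    if rms > 0:
        sig /= rms
    noise = rng.standard_normal(n)
    # band-limit the noise to the song band so its spectrum is flat there
    spec = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < 300) | (freqs > 8600)] = 0.0
    noise = np.fft.irfft(spec, n=n)
    nrms = np.sqrt(np.mean(noise**2))
    if nrms > 0:
        noise /= nrms
    mix = np.sqrt(1 - note.noise_fraction) * sig + np.sqrt(note.noise_fraction) * noise
    target_rms = 10 ** ((note.amplitude_db - baseline_db) / 20.0)
    mix *= target_rms
    return mix


def synth_song(spec: SongSpec, return_truth: bool = False):
    """Render a song spec into audio.

    Deterministic given ``spec.seed``. With ``return_truth=True`` also
    returns the ground-truth syllable boundary list ``(onset_s,
    offset_s)`` and per-note ``(onset_s, offset_s, state)`` records.
    """
    fs = spec.sample_rate
    rng = np.random.default_rng(spec.seed)
    gap = np.zeros(int(round(spec.gap_ms * fs / 1000.0)))
    pieces = [gap]
    boundaries = []
    note_records = []
    cursor = gap.size
    ramp_n = int(round(0.004 * fs))
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp_n)))
    xfade = max(2, int(round(spec.crossfade_ms / 1000.0 * fs)))
    xf_out = 0.5 * (1 + np.cos(np.linspace(0, np.pi, xfade)))
    for _ in range(spec.n_motif_repeats):
        for syl in spec.motif:
            onset = cursor
            syl_audio = None
            for note in syl:
                piece = _render_note(note, fs, rng)
                if syl_audio is None:
                    start = 0
                    syl_audio = piece
                else:
                    # overlap-add crossfade removes the junction click
                    start = syl_audio.size - xfade
                    syl_audio[-xfade:] *= xf_out
                    syl_audio = np.concatenate([syl_audio, piece[xfade:]])
                    syl_audio[start:start + xfade] += piece[:xfade] * xf_out[::-1]
                note_records.append(((onset + start) / fs,
                                     (onset + start + piece.size) / fs,
                                     note.state))
            cursor = onset + syl_audio.size
            syl_audio[:ramp_n] *= ramp
            syl_audio[-ramp_n:] *= ramp[::-1]
            pieces.append(syl_audio)
            boundaries.append((onset / fs, cursor / fs))
            pieces.append(gap)
            cursor += gap.size
    samples = np.clip(np.concatenate(pieces), -1.0, 1.0)
    clip = AudioClip(samples, fs)
    if return_truth:
        return clip, {"syllables": boundaries, "notes": note_records}
    return clip


# ---------------------------------------------------------------------------
# colonies


@dataclass(frozen=True)
class ColonySpec:
    """Generative settings for a tutor-pupil colony.

    ``balancing_exponent`` (beta) applies the transform
    ``normalize(p**beta)`` to the tutor's state-abundance vector to obtain
    the pupil's target vector: beta = 1 is faithful copying, smaller
    values flatten the distribution toward uniform. ``copy_fidelity`` is
    the mean fraction of tutor syllables each pupil copies; per-pair
    fidelities get a family-level random effect so that imitation quality
    runs in families, as observed in real colonies.
    """

    n_pairs: int = 100
    balancing_exponent: float = 0.85
    copy_fidelity: float = 0.7
    lineage_depth: int = 2
    seed: int = 0
    clutches_per_family: int = 2
    family_sd: float = 0.12
    within_family_sd: float = 0.05
    improvisation_scale: float = 0.5
    n_windows_per_bird: int = 3000
    motif_voiced_ms: float = 1300.0

    def __post_init__(self) -> None:
        if not (0.0 < self.balancing_exponent <= 1.0):
            raise ValueError("balancing_exponent must be in (0, 1]")
        if not (0.0 <= self.copy_fidelity <= 1.0):
            raise ValueError("copy_fidelity must be in [0, 1]")
        if self.n_pairs < 0 or self.lineage_depth < 1:
            raise ValueError("n_pairs >= 0 and lineage_depth >= 1 required")


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _vector_with_entropy(target_bits: float, rng: np.random.Generator,
                         tol: float = 1e-4) -> np.ndarray:
    """An abundance vector over 10 states with the requested entropy.

    A random direction is exponentially tilted; the tilt strength is
    solved by bisection (0 = uniform = 3.32 bits; large = concentrated).
    """
    g = rng.standard_normal(N_STATES)
    g -= g.mean()
    g /= np.linalg.norm(g)

    def h(gamma: float) -> float:
        w = np.exp(gamma * g)
        return _entropy_bits(w / w.sum())

    lo, hi = 0.0, 1.0
    while h(hi) > target_bits:
        hi *= 2
        if hi > 1e4:
            break
    for _ in range(80):
        mid = (lo + hi) / 2
        if h(mid) > target_bits:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    gamma = (lo + hi) / 2
    w = np.exp(gamma * g)
    return w / w.sum()


def _notes_for_state_durations(durations_ms: np.ndarray,
                               rng: np.random.Generator,
                               jitter: float = 0.09,
                               min_note_ms: float = 45.0,
                               max_note_ms: float = 90.0) -> list[SyllableSpec]:
    """Split per-state duration budgets into archetype note instances."""
    notes: list[SyllableSpec] = []
    for state in range(1, N_STATES + 1):
        left = float(durations_ms[state - 1])
        while left >= min_note_ms:
            dur = min(left, rng.uniform(55.0, max_note_ms))
            if left - dur < min_note_ms and left <= max_note_ms:
                dur = left
            notes.append(archetype_note(state, rng, jitter=jitter,
                                        duration_ms=dur))
            left -= dur
    return notes


def _notes_to_motif(notes: list[SyllableSpec], rng: np.random.Generator,
                    notes_per_syllable: int = 2) -> list[tuple]:
    order = rng.permutation(len(notes))
    shuffled = [notes[i] for i in order]
    motif = []
    for i in range(0, len(shuffled), notes_per_syllable):
        motif.append(tuple(shuffled[i:i + notes_per_syllable]))
    return motif


def _song_from_abundance(p: np.ndarray, rng: np.random.Generator,
                         colony: ColonySpec, seed: int) -> SongSpec:
    durations = p * colony.motif_voiced_ms
    notes = _notes_for_state_durations(durations, rng)
    motif = _notes_to_motif(notes, rng)
    return SongSpec(motif=tuple(motif), seed=seed)


def simulate_pupil(tutor: SongSpec, colony: ColonySpec, seed: int,
                   copy_fidelity: float | None = None) -> tuple[SongSpec, dict]:
    """Generate a pupil song from a tutor song.

    The pupil copies ``copy_fidelity`` of the tutor's syllables (with
    small parameter jitter) and improvises additional syllables drawn
    from the archetype pool so that its overall state-abundance vector
    approaches ``normalize(tutor_p ** beta)``. Returns the pupil spec and
    a ground-truth dict with copied flags and target abundances.
    """
    rng = np.random.default_rng(seed)
    fid = colony.copy_fidelity if copy_fidelity is None else copy_fidelity
    beta = colony.balancing_exponent

    tutor_p = tutor.state_abundance()
    target = tutor_p ** beta
    target /= target.sum()

    n_syl = len(tutor.motif)
    n_copy = int(round(fid * n_syl))
    copy_idx = np.sort(rng.choice(n_syl, size=n_copy, replace=False))
    copied = [tuple(jitter_note(nt, rng) for nt in tutor.motif[i])
              for i in copy_idx]

    copied_d = np.zeros(N_STATES)
    for syl in copied:
        for nt in syl:
            if nt.state is not None:
                copied_d[nt.state - 1] += nt.duration_ms

    # total pupil voiced duration: at least the tutor's, inflated by an
    # improvisation margin that grows as less is copied (pupils that
    # copy poorly improvise more), and large enough to accommodate the
    # copied material under the target proportions
    tutor_total = sum(n.duration_ms for n in tutor.notes)
    margin = 1.0 + colony.improvisation_scale * (1.0 - fid)
    base_total = max(copied_d.sum(), tutor_total * margin)
    with np.errstate(divide="ignore"):
        need = np.where(copied_d > 0, copied_d / np.maximum(target, 1e-12),
                        0.0)
    total = max(base_total, float(need.max()))
    improv_d = np.maximum(target * total - copied_d, 0.0)
    improv_notes = _notes_for_state_durations(improv_d, rng)
    improv_motif = _notes_to_motif(improv_notes, rng)

    motif = copied + improv_motif
    order = rng.permutation(len(motif))
    motif = [motif[i] for i in order]
    copied_flags = [i < len(copied) for i in order]

    pupil = SongSpec(motif=tuple(motif), gap_ms=tutor.gap_ms,
                     n_motif_repeats=tutor.n_motif_repeats,
                     seed=int(rng.integers(2**31)),
                     sample_rate=tutor.sample_rate)
    realized = pupil.state_abundance()
    truth = {
        "copied_syllable": copied_flags,
        "target_abundance": target,
        "realized_abundance": realized,
        "copied_fraction_of_tutor": copied_d.sum() /
            max(sum(n.duration_ms for n in tutor.notes), 1e-9),
        "copied_fraction_of_pupil": copied_d.sum() /
            max(sum(n.duration_ms for n in pupil.notes), 1e-9),
    }
    return pupil, truth


@dataclass
class ColonyData:
    """A simulated colony: pair table, song specs, and ground truth."""

    spec: ColonySpec
    pairs: pd.DataFrame
    songs: dict[str, SongSpec]
    truth: dict[str, dict]

    def render(self, bird_id: str) -> AudioClip:
        return synth_song(self.songs[bird_id])

    def truth_json(self) -> str:
        def clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer, np.bool_)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj
        return json.dumps(clean(self.truth), indent=2)


def _sample_diversity(rng: np.random.Generator) -> float:
    """Left-tailed tutor song diversity: median ~3.1 bits, tail to ~2.3."""
    x = rng.gamma(2.0, 0.12)
    return float(np.log2(N_STATES) - np.clip(x, 0.0, 1.05))


def simulate_colony(colony: ColonySpec) -> ColonyData:
    """Simulate a colony of tutor-pupil pairs with known ground truth.

    Families are founded until the pair budget is spent: each family has
    one founder tutor with ``clutches_per_family`` first-generation
    clutches, then a chain of one pair per extra generation (the previous
    generation's first pupil becomes the tutor). The pair table carries
    ground-truth similarity/influence proxies (copied duration fractions,
    scaled to percent) and multinomially sampled abundance vectors that
    emulate estimating abundances from a finite window sample.
    """
    spec = colony
    rng = np.random.default_rng(spec.seed)
    rows = []
    songs: dict[str, SongSpec] = {}
    truth: dict[str, dict] = {}

    def bird_abundance(p_realized: np.ndarray) -> tuple[np.ndarray, int]:
        n = spec.n_windows_per_bird
        counts = rng.multinomial(n, p_realized)
        return counts / n, n

    pair_budget = spec.n_pairs
    family = 0
    while pair_budget > 0:
        family += 1
        founder_id = f"F{family:03d}T"
        d_target = _sample_diversity(rng)
        p = _vector_with_entropy(d_target, rng)
        founder = _song_from_abundance(p, rng, spec, seed=int(rng.integers(2**31)))
        songs[founder_id] = founder
        p_founder = founder.state_abundance()
        obs_p, n_obs = bird_abundance(p_founder)
        truth[founder_id] = {"target_abundance": p,
                             "realized_abundance": p_founder,
                             "observed_abundance": obs_p}
        fam_effect = rng.normal(0.0, spec.family_sd)

        def make_pair(tutor_id: str, pupil_id: str, clutch: str,
                      generation: int) -> None:
            tut = songs[tutor_id]
            fid = float(np.clip(spec.copy_fidelity + fam_effect +
                                rng.normal(0.0, spec.within_family_sd),
                                0.05, 1.0))
            pupil, ptruth = simulate_pupil(tut, spec,
                                           seed=int(rng.integers(2**31)),
                                           copy_fidelity=fid)
            songs[pupil_id] = pupil
            p_obs, _ = bird_abundance(ptruth["realized_abundance"])
            ptruth["observed_abundance"] = p_obs
            ptruth["generation"] = generation
            truth[pupil_id] = ptruth
            t_obs = truth[tutor_id]["observed_abundance"]
            row = {
                "tutor_id": tutor_id, "pupil_id": pupil_id,
                "relation": "biological",
                "clutch_id": clutch, "lineage_id": f"F{family:03d}",
                "similarity_pct": float(np.clip(
                    100.0 * ptruth["copied_fraction_of_tutor"], 0, 100)),
                "influence_pct": float(np.clip(
                    100.0 * ptruth["copied_fraction_of_pupil"], 0, 100)),
                "tutor_diversity_bits": _entropy_bits(t_obs),
                "pupil_diversity_bits": _entropy_bits(p_obs),
                "tutor_n_windows": spec.n_windows_per_bird,
                "pupil_n_windows": spec.n_windows_per_bird,
            }
            for i in range(N_STATES):
                row[f"tutor_p{i + 1}"] = t_obs[i]
                row[f"pupil_p{i + 1}"] = p_obs[i]
            rows.append(row)

        # first generation: clutches under the founder
        gen1_first = None
        for c in range(spec.clutches_per_family):
            if pair_budget <= 0:
                break
            pupil_id = f"F{family:03d}G1C{c + 1}"
            make_pair(founder_id, pupil_id, clutch=f"F{family:03d}c{c + 1}",
                      generation=1)
            gen1_first = gen1_first or pupil_id
            pair_budget -= 1
        # deeper generations: chain from the first pupil
        prev = gen1_first
        for g in range(2, spec.lineage_depth + 1):
            if pair_budget <= 0 or prev is None:
                break
            pupil_id = f"F{family:03d}G{g}"
            make_pair(prev, pupil_id, clutch=f"F{family:03d}g{g}",
                      generation=g)
            prev = pupil_id
            pair_budget -= 1

    pairs = pd.DataFrame(rows)
    return ColonyData(spec=spec, pairs=pairs, songs=songs, truth=truth)
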