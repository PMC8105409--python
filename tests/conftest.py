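"""Shared fixtures: synthetic clips, corpora, partitions, null models.

Everything is generated programmatically with fixed seeds; the heavier
objects (feature corpus, fitted partition, null model) are session
scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from songstates.audio import AudioClip
from songstates.features import FeatureConfig, compute_features
from songstates.similarity import build_null
from songstates.states import PartitionConfig, fit_partition
from songstates.synth import SongSpec, archetype_note, synth_song

FS = 22050


def tone_clip(freq_hz: float = 1000.0, dur_s: float = 0.2,
              amp: float = 0.9) -> AudioClip:
    t = np.arange(int(dur_s * FS)) / FS
    return AudioClip(amp * np.sin(2 * np.pi * freq_hz * t), FS)


@pytest.fixture(scope="session")
def tone_track():
    return compute_features(tone_clip())


@pytest.fixture(scope="session")
def noise_track():
    rng = np.random.default_rng(0)
    return compute_features(AudioClip(0.5 * rng.standard_normal(int(0.2 * FS)), FS))


def make_song(states, seed: int, repeats: int = 2, rng_seed: int = 0,
              jitter: float = 0.06) -> SongSpec:
    """A song whose syllables are archetype notes of the given states."""
    rng = np.random.default_rng(rng_seed)
    motif = tuple((archetype_note(int(s), rng, jitter=jitter),) for s in states)
    return SongSpec(motif=motif, seed=seed, n_motif_repeats=repeats)


@pytest.fixture(scope="session")
def corpus_tracks():
    """20 unrelated synthetic songs (one per bird), with ground truth."""
    rng = np.random.default_rng(11)
    out = []
    for b in range(20):
        motif = tuple(archetype_note(int(s) + 1, rng)
                      for s in rng.permutation(10)[:6])
        spec = SongSpec(motif=motif, seed=int(rng.integers(2**31)))
        clip, truth = synth_song(spec, return_truth=True)
        out.append((compute_features(clip, bird_id=f"bird{b}"), truth))
    return out


@pytest.fixture(scope="session")
def null_model(corpus_tracks):
    return build_null([t for t, _ in corpus_tracks], seed=1, n_pairs=30000)


@pytest.fixture(scope="session")
def state_corpus():
    """12 songs covering all 10 archetype states, with note ground truth."""
    rng = np.random.default_rng(7)
    out = []
    for b in range(12):
        motif = tuple(archetype_note(int(s) + 1, rng)
                      for s in rng.permutation(10))
        spec = SongSpec(motif=motif, seed=int(rng.integers(2**31)))
        clip, truth = synth_song(spec, return_truth=True)
        out.append((compute_features(clip, bird_id=f"sb{b}"), truth))
    return out


@pytest.fixture(scope="session")
def partition(state_corpus):
    return fit_partition([t for t, _ in state_corpus],
                         PartitionConfig(min_windows=5000))
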