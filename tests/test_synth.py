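"""Synthetic song generator: determinism, round trips, colonies."""

import numpy as np
import pytest

from songstates.features import compute_features
from songstates.states import shannon_diversity
from songstates.syllables import segment
from songstates.synth import (ColonySpec, SongSpec, SyllableSpec,
                              archetype_note, simulate_colony,
                              simulate_pupil, synth_song)


class TestSynthSong:
    def test_deterministic(self):
        rng = np.random.default_rng(1)
        spec = SongSpec(motif=tuple((archetype_note(s, rng),)
                                    for s in (1, 4, 9)), seed=5)
        a = synth_song(spec)
        b = synth_song(spec)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_constant_f0_round_trip_pitch(self):
        note = SyllableSpec(duration_ms=200, f0_start_hz=1000,
                            f0_end_hz=1000, noise_fraction=0.0)
        clip = synth_song(SongSpec(motif=(note,), seed=0, n_motif_repeats=1))
        tr = compute_features(clip)
        assert np.nanmedian(tr.pitch_hz[tr.voiced]) == pytest.approx(
            1000.0, rel=0.02)

    def test_pure_noise_flat_spectrum(self):
        note = SyllableSpec(duration_ms=200, f0_start_hz=1000,
                            f0_end_hz=1000, noise_fraction=1.0)
        clip = synth_song(SongSpec(motif=(note,), seed=0, n_motif_repeats=1))
        tr = compute_features(clip)
        assert abs(np.median(tr.wiener_entropy[tr.voiced])) < 0.3

    def test_round_trip_syllable_count(self):
        """segment(features(synth)) recovers the generated syllable count
        exactly for gaps of at least 15 ms."""
        rng = np.random.default_rng(6)
        for n_syl, gap in ((3, 20.0), (5, 40.0), (6, 15.0)):
            motif = tuple((archetype_note(int(s) + 1, rng),)
                          for s in rng.permutation(10)[:n_syl])
            spec = SongSpec(motif=motif, gap_ms=gap, seed=int(n_syl),
                            n_motif_repeats=2)
            clip, truth = synth_song(spec, return_truth=True)
            table = segment(compute_features(clip))
            assert len(table) == len(truth["syllables"]) == 2 * n_syl

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyllableSpec(duration_ms=5, f0_start_hz=800, f0_end_hz=800)
        with pytest.raises(ValueError):
            SyllableSpec(duration_ms=50, f0_start_hz=100, f0_end_hz=100)
        with pytest.raises(ValueError):
            SongSpec(motif=())


class TestSimulatePupil:
    @pytest.fixture()
    def tutor(self):
        # full-support tutor: every state contributes
        rng = np.random.default_rng(2)
        motif = tuple((archetype_note(s, rng, duration_ms=70),)
                      for s in range(1, 11))
        return SongSpec(motif=motif, seed=3)

    def test_identity_limit(self, tutor):
        """beta = 1 and full fidelity: pupil abundances match the tutor
        within the copy jitter."""
        colony = ColonySpec(n_pairs=1, balancing_exponent=1.0,
                            copy_fidelity=1.0)
        pupil, truth = simulate_pupil(tutor, colony, seed=4)
        l1 = np.abs(pupil.state_abundance()
                    - tutor.state_abundance()).sum()
        assert l1 < 0.05
        assert all(truth["copied_syllable"])

    def test_flattening_limit_uniform(self, tutor):
        """beta near 0 drives the target abundances to uniform."""
        colony = ColonySpec(n_pairs=1, balancing_exponent=0.01,
                            copy_fidelity=0.5)
        _, truth = simulate_pupil(tutor, colony, seed=5)
        np.testing.assert_allclose(truth["target_abundance"], 0.1, atol=0.01)

    def test_copy_jitter_within_five_percent(self, tutor):
        colony = ColonySpec(n_pairs=1, balancing_exponent=1.0,
                            copy_fidelity=1.0)
        pupil, truth = simulate_pupil(tutor, colony, seed=6)
        copied = [syl for syl, c in zip(pupil.motif,
                                        truth["copied_syllable"]) if c]
        tutor_f0 = sorted(n.f0_start_hz for syl in tutor.motif for n in syl)
        pupil_f0 = sorted(n.f0_start_hz for syl in copied for n in syl)
        rel = np.abs(np.array(pupil_f0) / np.array(tutor_f0) - 1)
        assert rel.max() <= 0.05


class TestSimulateColony:
    def test_empty_colony(self):
        col = simulate_colony(ColonySpec(n_pairs=0))
        assert len(col.pairs) == 0 and col.songs == {}

    def test_lineage_depth_structure(self):
        """With depth 2, every generation-2 tutor is a generation-1
        pupil."""
        col = simulate_colony(ColonySpec(n_pairs=30, lineage_depth=2,
                                         seed=8))
        pupils = set(col.pairs["pupil_id"])
        gen2 = col.pairs[col.pairs["pupil_id"].str.contains("G2")]
        assert len(gen2) > 0
        assert set(gen2["tutor_id"]).issubset(pupils)

    def test_diversity_distribution(self):
        """Tutor song diversities: median near 3.1 bits with a left tail."""
        col = simulate_colony(ColonySpec(n_pairs=100, seed=7))
        d = col.pairs.drop_duplicates("tutor_id")["tutor_diversity_bits"]
        assert abs(d.median() - 3.1) < 0.15
        assert d.min() < 2.8  # left tail
        assert d.max() <= np.log2(10) + 1e-9

    def test_pair_table_schema(self):
        col = simulate_colony(ColonySpec(n_pairs=10, seed=9))
        for col_name in ("tutor_id", "pupil_id", "clutch_id", "lineage_id",
                         "similarity_pct", "influence_pct"):
            assert col_name in col.pairs.columns
        assert col.pairs["similarity_pct"].between(0, 100).all()
        p_cols = [f"pupil_p{i}" for i in range(1, 11)]
        np.testing.assert_allclose(col.pairs[p_cols].sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_deterministic(self):
        a = simulate_colony(ColonySpec(n_pairs=10, seed=10))
        b = simulate_colony(ColonySpec(n_pairs=10, seed=10))
        assert a.pairs.equals(b.pairs)

    def test_ground_truth_abundance_targeting(self, state_corpus,
                                              partition):
        """Measured state abundances of clean single-note songs land
        within L1 0.1 of the generator's duration-weighted ground
        truth (through the fitted partition)."""
        from songstates.states import assign_states, state_abundances
        errs = []
        for track, truth in state_corpus:
            target = np.zeros(10)
            for on, off, state in truth["notes"]:
                target[state - 1] += off - on
            target /= target.sum()
            measured = state_abundances(assign_states(track, partition)).p
            errs.append(np.abs(measured - target).sum())
        assert np.median(errs) < 0.1


class TestEndToEndRecovery:
    def test_full_fidelity_high_scores_and_partial_fidelity_ordering(
            self, null_model):
        """Rendered colony at full fidelity: measured similarity and
        influence above 90% for every pair; at half fidelity the
        measured influence drops below the measured similarity. The
        null comes from an unrelated corpus (a null built from the
        colony itself would contain tutor-pupil copies)."""
        from songstates.similarity import influence, score

        def run(fid, seed):
            col = simulate_colony(ColonySpec(
                n_pairs=3, lineage_depth=1, copy_fidelity=fid,
                balancing_exponent=1.0, family_sd=0.0,
                within_family_sd=0.0, seed=seed))
            tracks = {b: compute_features(col.render(b), bird_id=b)
                      for b in col.songs}
            out = []
            for _, row in col.pairs.iterrows():
                t, p = tracks[row.tutor_id], tracks[row.pupil_id]
                out.append((score(t, p, null_model, repeats=2,
                                  seed=2).similarity_pct,
                            influence(t, p, null_model, repeats=2,
                                      seed=2).similarity_pct))
            return out

        full = run(1.0, seed=31)
        assert all(s > 90 and i > 90 for s, i in full)
        half = run(0.5, seed=31)
        assert all(i < s for s, i in half)
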