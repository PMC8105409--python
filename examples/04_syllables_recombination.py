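"""Syllable segmentation, typing, and merge detection.

A tutor sings three syllables; the pupil fuses the first two into one
(the silent gap between them is dropped), a *merge* recombination. The
example segments both songs by amplitude threshold, clusters syllable
types within each bird, computes syllable-type and syntax (bigram)
entropies, and detects the boundary recombination.
"""

import numpy as np

from songstates import build_null, compute_features
from songstates.syllables import (cluster_types, detect_recombination,
                                  segment, syntax_entropy, type_diversity)
from songstates.synth import SongSpec, archetype_note, synth_song

rng = np.random.default_rng(11)
corpus = []
for _ in range(20):
    motif = tuple(archetype_note(int(s) + 1, rng)
                  for s in rng.permutation(10)[:6])
    corpus.append(compute_features(
        synth_song(SongSpec(motif=motif, seed=int(rng.integers(2**31))))))
null = build_null(corpus, seed=1, n_pairs=30000)

note_rng = np.random.default_rng(8)
n1 = archetype_note(3, note_rng)
n2 = archetype_note(7, note_rng)
n3 = archetype_note(9, note_rng)
tutor = SongSpec(motif=((n1,), (n2,), (n3,)), seed=5, n_motif_repeats=2)
pupil = SongSpec(motif=((n1, n2), (n3,)), seed=6, n_motif_repeats=2)

t = compute_features(synth_song(tutor), bird_id="tutor")
p = compute_features(synth_song(pupil), bird_id="pupil")
t_syl = cluster_types(segment(t))
p_syl = cluster_types(segment(p))

print(f"tutor: {len(t_syl)} syllables, "
      f"type diversity {type_diversity(t_syl):.2f} bits, "
      f"syntax entropy {syntax_entropy(t_syl):.2f} bits")
print(f"pupil: {len(p_syl)} syllables, "
      f"type diversity {type_diversity(p_syl):.2f} bits")

events = detect_recombination(t, p, t_syl, p_syl, null)
for e in events:
    print(f"recombination: {e.kind} — {len(e.tutor_intervals)} tutor "
          f"interval(s) -> {len(e.pupil_intervals)} pupil interval(s)")
print("(the pupil merged tutor syllables 1 and 2 into one unit)")
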