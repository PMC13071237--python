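"""Phrase-structured symbolic melodies.

A melody is a gapless monophonic sequence of notes tiling a series of
phrases. Phrase lengths are expressed in beats at a nominal tempo
(74.4 bpm by default, so one beat = 60/74.4 s and the quaver rate is
2.48 Hz). Regular melodies use 8-beat phrases throughout (one boundary
every ~6.5 s); irregular melodies draw phrase lengths from 3-30 beats
(mean ~9.5). Phrase endings carry salient cues -- a lengthened final
note and an enlarged melodic interval into it -- but no inserted
silence, and similar cues occasionally appear inside phrases so a
boundary is not perfectly predictable from local events alone.
Shuffled controls permute the note material on the half-beat grid while
keeping the original boundary times as pseudo-boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

DEFAULT_TEMPO_BPM = 74.4
#: phrase lengths (beats) classified as regular
REGULAR_LENGTHS = (4, 8, 12)
#: default duration alphabet, in beats (quaver granularity keeps the
#: half-beat shuffle exact)
DURATION_ALPHABET = (0.5, 1.0, 2.0, 4.0)
#: C-major scale degrees over a two-octave melody range (MIDI numbers)
DEFAULT_SCALE = tuple(
    o + pc for o in (48, 60, 72) for pc in (0, 2, 4, 5, 7, 9, 11) if 55 <= o + pc <= 79
)

CONDITIONS = ("regular", "irregular", "shuffled")


@dataclass(frozen=True)
class NoteEvent:
    """A single note: onset and duration in beats, pitch in semitones."""

    onset_beats: float
    duration_beats: float
    pitch: float

    def __post_init__(self) -> None:
        if self.duration_beats <= 0:
            raise ValueError(f"duration_beats must be positive, got {self.duration_beats}")
        if self.onset_beats < 0:
            raise ValueError(f"onset_beats must be nonnegative, got {self.onset_beats}")

    @property
    def offset_beats(self) -> float:
        return self.onset_beats + self.duration_beats


@dataclass(frozen=True)
class PhraseStructure:
    """Sequence of phrase lengths (beats) with tempo and condition label."""

    phrase_lengths: tuple
    tempo_bpm: float = DEFAULT_TEMPO_BPM
    condition: str = "regular"

    def __post_init__(self) -> None:
        object.__setattr__(self, "phrase_lengths", tuple(self.phrase_lengths))
        if self.tempo_bpm <= 0:
            raise ValueError(f"tempo_bpm must be positive, got {self.tempo_bpm}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if not self.phrase_lengths:
            raise ValueError("phrase_lengths must be non-empty")
        if any(l <= 0 for l in self.phrase_lengths):
            raise ValueError("phrase lengths must be positive")
        if self.condition == "regular" and any(l != 8 for l in self.phrase_lengths):
            raise ValueError("regular structures must use 8-beat phrases")
        if self.condition == "irregular":
            if any(not (3 <= l <= 30) for l in self.phrase_lengths):
                raise ValueError("irregular phrase lengths must lie in [3, 30] beats")

    @property
    def boundary_beats(self) -> np.ndarray:
        """Beat positions of phrase ends (cumulative phrase lengths)."""
        return np.cumsum(np.asarray(self.phrase_lengths, dtype=float))

    @property
    def total_beats(self) -> float:
        return float(sum(self.phrase_lengths))

    @property
    def beat_s(self) -> float:
        """Duration of one beat in seconds."""
        return 60.0 / self.tempo_bpm


@dataclass(frozen=True)
class NoteSequence:
    """Notes plus the phrase structure and boundary annotations they realize."""

    notes: tuple
    structure: Optional[PhraseStructure]
    boundaries_beats: tuple
    pseudo_boundaries: bool = False
    melody_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "notes", tuple(self.notes))
        object.__setattr__(self, "boundaries_beats", tuple(float(b) for b in self.boundaries_beats))

    def validate(self) -> None:
        """Check tiling/annotation invariants; raise ValueError on breach."""
        if not self.notes:
            raise ValueError("empty note sequence")
        onsets = np.array([n.onset_beats for n in self.notes])
        if np.any(np.diff(onsets) < 0):
            raise ValueError("note onsets must be non-decreasing")
        for a, b in zip(self.notes[:-1], self.notes[1:]):
            if abs(a.offset_beats - b.onset_beats) > 1e-9:
                raise ValueError(
                    f"gap or overlap at beat {a.offset_beats:g}: next onset {b.onset_beats:g}"
                )
        offsets = {round(n.offset_beats * 2) / 2 for n in self.notes}
        for bb in self.boundaries_beats:
            if round(bb * 2) / 2 not in offsets:
                raise ValueError(f"boundary at beat {bb:g} does not coincide with a note offset")
        if self.structure is not None:
            expect = self.structure.boundary_beats
            if len(expect) != len(self.boundaries_beats) or np.max(
                np.abs(expect - np.array(self.boundaries_beats))
            ) > 1e-9:
                raise ValueError("boundaries_beats must equal cumulative phrase lengths")

    @property
    def total_beats(self) -> float:
        return float(self.notes[-1].offset_beats) if self.notes else 0.0

    @property
    def boundaries_s(self) -> np.ndarray:
        tempo = self.structure.tempo_bpm if self.structure is not None else DEFAULT_TEMPO_BPM
        return np.asarray(self.boundaries_beats) * 60.0 / tempo

    @property
    def duration_s(self) -> float:
        tempo = self.structure.tempo_bpm if self.structure is not None else DEFAULT_TEMPO_BPM
        return self.total_beats * 60.0 / tempo


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_phrase_structure(
    condition: str,
    n_phrases: int,
    tempo_bpm: float = DEFAULT_TEMPO_BPM,
    seed=None,
    mean_window: tuple = (8.5, 10.5),
) -> PhraseStructure:
    """Draw a phrase-length sequence for one melody.

    Regular melodies are 8 beats per phrase throughout. Irregular
    melodies draw lengths from 3-30 beats excluding the regular lengths
    {4, 8, 12} (so the conditions are disjoint by construction) and are
    resampled until the mean length falls in ``mean_window``, targeting
    the ~9.5-beat average of the stimulus material.
    """
    if n_phrases < 1:
        raise ValueError(f"n_phrases must be >= 1, got {n_phrases}")
    if condition == "regular":
        return PhraseStructure((8,) * n_phrases, tempo_bpm, "regular")
    if condition != "irregular":
        raise ValueError(f"unknown condition {condition!r}; expected 'regular' or 'irregular'")
    rng = _as_rng(seed)
    candidates = np.array([l for l in range(3, 31) if l not in REGULAR_LENGTHS])
    lo, hi = mean_window
    for _ in range(100_000):
        lengths = rng.choice(candidates, size=n_phrases)
        if not lo <= lengths.mean() <= hi:
            continue
        if n_phrases > 1 and len(set(lengths.tolist())) == 1:
            continue
        return PhraseStructure(tuple(int(l) for l in lengths), tempo_bpm, "irregular")
    raise RuntimeError("failed to sample an irregular structure in the mean window")


def boundary_times(structure: PhraseStructure) -> np.ndarray:
    """Phrase-boundary times in seconds from melody onset."""
    if structure.tempo_bpm <= 0:
        raise ValueError("tempo must be positive")
    return structure.boundary_beats * 60.0 / structure.tempo_bpm


def _fill_interior(rng: np.random.Generator, beats: float, distractor_rate: float) -> list:
    """Tile `beats` with durations from the alphabet; occasional long notes."""
    out: list = []
    remaining = round(beats * 2)  # work in half-beat integer units
    while remaining > 0:
        if remaining >= 4 and rng.random() < distractor_rate:
            dur = 4 if remaining < 8 or rng.random() < 0.8 else 8
        else:
            dur = 1 if remaining == 1 else int(rng.choice([1, 2]))
        out.append(dur / 2.0)
        remaining -= dur
    rng.shuffle(out)
    return out


def render_melody(
    structure: PhraseStructure,
    cue_duration_factor: float = 2.0,
    cue_interval_semitones: float = 5.0,
    distractor_rate: float = 0.15,
    scale: Sequence[int] = DEFAULT_SCALE,
    seed=None,
    melody_id: str = "",
) -> NoteSequence:
    """Realize a phrase structure as notes with boundary cues.

    Each phrase is tiled exactly by durations from {0.5, 1, 2, 4} beats.
    The final note of every phrase is lengthened to at least
    ``cue_duration_factor`` times the median interior duration and is
    approached by a melodic leap of at least ``cue_interval_semitones``.
    Interior notes occasionally carry long durations or leaps too
    (``distractor_rate``), so boundaries are not locally determined.
    """
    if cue_duration_factor > 8:
        raise ValueError("cue_duration_factor > 8 cannot be met with a 4-beat final note")
    rng = _as_rng(seed)
    scale = sorted(int(p) for p in scale)
    final_dur = 4.0 if cue_duration_factor > 4 else 2.0
    for L in structure.phrase_lengths:
        if L < final_dur + 0.5:
            raise ValueError(
                f"phrase of {L} beats is shorter than the minimal tiling "
                f"(final note {final_dur} beats + one interior note)"
            )

    notes: list = []
    onset = 0.0
    pitch = int(scale[len(scale) // 2])
    for L in structure.phrase_lengths:
        interior = _fill_interior(rng, L - final_dur, distractor_rate)
        # enforce the duration cue: halve the longest interior notes until
        # the final note is >= cue_duration_factor x the interior median
        while final_dur < cue_duration_factor * float(np.median(interior)) - 1e-9:
            i = int(np.argmax(interior))
            d = interior.pop(i)
            interior[i:i] = [d / 2, d / 2]
        for k, dur in enumerate(interior):
            jump = rng.random() < distractor_rate
            lo_iv, hi_iv = (cue_interval_semitones, 12.0) if jump else (0.0, 4.0)
            cand = [p for p in scale if lo_iv <= abs(p - pitch) <= hi_iv]
            if not cand:
                cand = [p for p in scale if p != pitch]
            pitch = int(rng.choice(cand))
            notes.append(NoteEvent(onset, dur, pitch))
            onset += dur
        # boundary cues: enlarged interval into a lengthened final note
        cand = [p for p in scale if abs(p - pitch) >= cue_interval_semitones]
        pitch = int(rng.choice(cand))
        notes.append(NoteEvent(onset, final_dur, pitch))
        onset += final_dur

    seq = NoteSequence(
        tuple(notes), structure, tuple(structure.boundary_beats), melody_id=melody_id
    )
    seq.validate()
    return seq


def shuffle_melody(seq: NoteSequence, chunk_beats: float = 0.5, seed=None) -> NoteSequence:
    """Half-beat-grid shuffle destroying phrase structure.

    The note material (a sequence of units on the ``chunk_beats`` grid)
    is permuted and reassembled contiguously, preserving the duration
    histogram and pitch multiset exactly. The returned sequence carries
    the ORIGINAL boundary positions as pseudo-boundaries, which serve as
    the chance-level ground truth for the shuffled condition.
    """
    rng = _as_rng(seed)
    for n in seq.notes:
        ratio = n.duration_beats / chunk_beats
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"note duration {n.duration_beats} beats is not a multiple of "
                f"chunk_beats={chunk_beats}"
            )
    perm = rng.permutation(len(seq.notes))
    onset = 0.0
    shuffled = []
    for i in perm:
        n = seq.notes[i]
        shuffled.append(NoteEvent(onset, n.duration_beats, n.pitch))
        onset += n.duration_beats
    structure = (
        replace(seq.structure, condition="shuffled") if seq.structure is not None else None
    )
    return NoteSequence(
        tuple(shuffled),
        structure,
        seq.boundaries_beats,
        pseudo_boundaries=True,
        melody_id=(seq.melody_id + "-shuf") if seq.melody_id else "",
    )


def note_table(seq: NoteSequence) -> "np.ndarray":
    """(n_notes, 3) array of onset, duration, pitch in beats/semitones."""
    return np.array([[n.onset_beats, n.duration_beats, n.pitch] for n in seq.notes])
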