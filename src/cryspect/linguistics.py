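"""Cry-to-language segmentation on the 100 ms VU trace.

The cry is read as a language: a word is one voiced expiration (a maximal
run of cry-active meter frames), a sentence is a cry burst (words
separated only by short inhalation gaps), and a phrase is a group of
bursts separated by longer pauses.  Segmentation operates on the VU trace
rather than raw audio — the 100 ms meters are the native representation
of the measurement app — so all boundaries are resolved to 100 ms.

Coordinates are seconds, intervals half-open, frame indices 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .features import (
    MeterTrace,
    Waveform,
    compute_vu,
    default_activity_threshold,
)


@dataclass
class SegmentationConfig:
    """Thresholds of the silence-based segmenter.

    ``activity_threshold`` (U) separates cry from background; ``None``
    derives max(50 U, 5% of trace max) per recording.  A silence longer
    than ``sentence_gap_ms`` ends a sentence; longer than
    ``phrase_gap_ms`` ends a phrase.  Runs shorter than ``min_word_ms``
    are discarded as clicks.
    """

    activity_threshold: float | None = None
    min_word_ms: float = 200.0
    sentence_gap_ms: float = 1000.0
    phrase_gap_ms: float = 3000.0

    def __post_init__(self) -> None:
        if self.min_word_ms <= 0:
            raise ValueError("min_word_ms must be positive")
        if not 0 < self.sentence_gap_ms < self.phrase_gap_ms:
            raise ValueError("need 0 < sentence_gap_ms < phrase_gap_ms")
        if self.activity_threshold is not None and self.activity_threshold < 0:
            raise ValueError("activity_threshold must be >= 0")


class Word(NamedTuple):
    onset: float  # s
    duration: float  # s


@dataclass
class CryStructure:
    """Hierarchical segmentation: phrases > sentences > words."""

    phrases: list[list[list[Word]]]  # phrases -> sentences -> words
    frame_ms: float = 100.0

    @property
    def sentences(self) -> list[list[Word]]:
        return [s for p in self.phrases for s in p]

    @property
    def words(self) -> list[Word]:
        return [w for s in self.sentences for w in s]

    @property
    def n_phrases(self) -> int:
        return len(self.phrases)

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    @property
    def n_words(self) -> int:
        return len(self.words)


@dataclass
class StructureStats:
    """Per-recording structural statistics of a segmented cry."""

    sentence_durations: list[float]
    words_per_sentence: list[int]
    first_word_duration: float | None
    phrase_count: int
    sentence_count: int
    word_count: int
    total_cry_time: float  # summed word (expiration) time, s


def detect_words(vu: MeterTrace, cfg: SegmentationConfig | None = None) -> list[Word]:
    """Words = maximal runs of frames above the activity threshold.

    Runs shorter than ``min_word_ms`` are discarded.  Onset/duration are
    reported in seconds from 0-based frame indices (half-open).
    """
    cfg = cfg or SegmentationConfig()
    if vu.kind != "VU":
        raise ValueError("segmentation expects a VU trace")
    thr = cfg.activity_threshold
    if thr is None:
        thr = default_activity_threshold(vu.values)
    active = vu.values > thr
    frame_s = vu.frame_s
    words: list[Word] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], active.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if (stop - start) * vu.frame_ms >= cfg.min_word_ms:
            words.append(Word(onset=float(start * frame_s),
                              duration=float((stop - start) * frame_s)))
    return words


def group_structure(words: list[Word], cfg: SegmentationConfig | None = None) -> CryStructure:
    """Group time-ordered words into sentences and phrases by gap length."""
    cfg = cfg or SegmentationConfig()
    phrases: list[list[list[Word]]] = []
    if not words:
        return CryStructure(phrases=phrases)
    onsets = [w.onset for w in words]
    if onsets != sorted(onsets):
        raise ValueError("words must be time-ordered")
    sentence_gap = cfg.sentence_gap_ms / 1000.0
    phrase_gap = cfg.phrase_gap_ms / 1000.0
    phrases.append([[words[0]]])
    for prev, cur in zip(words, words[1:]):
        gap = cur.onset - (prev.onset + prev.duration)
        if gap < -1e-9:
            raise ValueError("words must not overlap")
        if gap > phrase_gap:
            phrases.append([[cur]])
        elif gap > sentence_gap:
            phrases[-1].append([cur])
        else:
            phrases[-1][-1].append(cur)
    return CryStructure(phrases=phrases)


def structure_stats(s: CryStructure) -> StructureStats:
    """Sentence durations, words/sentence, first-word duration and counts.

    A sentence's duration runs from its first word's onset to its last
    word's end (inhalation gaps included).
    """
    sentences = s.sentences
    durations = [sent[-1].onset + sent[-1].duration - sent[0].onset for sent in sentences]
    counts = [len(sent) for sent in sentences]
    words = s.words
    return StructureStats(
        sentence_durations=durations,
        words_per_sentence=counts,
        first_word_duration=words[0].duration if words else None,
        phrase_count=s.n_phrases,
        sentence_count=s.n_sentences,
        word_count=len(words),
        total_cry_time=float(sum(w.duration for w in words)),
    )


def segment_waveform(
    w: Waveform, cfg: SegmentationConfig | None = None, frame_ms: float = 100.0
) -> CryStructure:
    """Convenience: VU trace -> words -> structure."""
    vu = compute_vu(w, frame_ms)
    return group_structure(detect_words(vu, cfg), cfg)


def voiced_frame_mask(
    structure: CryStructure, n_frames: int, frame_ms: float = 100.0
) -> np.ndarray:
    """Boolean mask of frames lying inside any detected word."""
    mask = np.zeros(n_frames, dtype=bool)
    frame_s = frame_ms / 1000.0
    for w in structure.words:
        i0 = int(round(w.onset / frame_s))
        i1 = int(round((w.onset + w.duration) / frame_s))
        mask[max(i0, 0): min(i1, n_frames)] = True
    return mask
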