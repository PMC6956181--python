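"""Synthetic neonatal cry generator with scripted ground truth.

A cry recording is modeled as a language-like hierarchy: a *word* is one
voiced expiration, a *sentence* is a burst of words separated by short
inhalation gaps, and a *phrase* is a group of sentences separated by
longer pauses.  :func:`plan_cry` lays out this structure as a
:class:`CryScript` (the ground truth used by round-trip tests), and
:func:`render_cry` realizes it as audio: each word is a harmonic stack at
its fundamental frequency with a 1/k amplitude roll-off and an
attack-sustain-decay envelope, embedded in Gaussian background noise.

Two cohort presets emulate the study groups: the control group ("M") and
the tight-nuchal-cord group ("C"), whose words-per-sentence distributions
(mean/SD/range), first-word duration, typical and minimum intensity
levels, and healthy-newborn F0 band (250-450 Hz) follow the published
group parameters.  Intensity levels are specified in the meter unit "U"
(16-bit PCM magnitude, peak-reading): a word with peak level ``a`` U
reaches a maximum sample magnitude of ``a / 32767``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .features import FULL_SCALE_U, Waveform
from .metadata import RecordingMetadata


class SpecValidationError(ValueError):
    """A synthesis spec violates one of its invariants."""


class ScriptWord(NamedTuple):
    phrase: int
    sentence: int
    word: int
    onset: float
    duration: float
    peak_amplitude: float  # normalized, in [0, 1]
    f0: float  # Hz


@dataclass
class SynthSpec:
    """Parameters of the cry generator; defaults follow the control group."""

    sample_rate: int = 22050
    # voicing
    f0_mean: float = 350.0
    f0_jitter: float = 0.05  # relative SD of per-word F0
    n_harmonics: int = 8
    # structure
    words_per_sentence_mean: float = 9.45
    words_per_sentence_sd: float = 3.381
    words_per_sentence_range: tuple[int, int] = (4, 18)
    sentences_per_phrase_range: tuple[int, int] = (2, 3)
    word_duration_mean: float = 1.0
    word_duration_sd: float = 0.3
    word_duration_range: tuple[float, float] = (0.5, 2.0)
    first_word_duration_mean: float = 1.21
    first_word_duration_sd: float = 0.5
    first_word_duration_range: tuple[float, float] = (0.5, 2.9)
    # pauses (strictly ordered so segmentation is well-posed)
    intra_sentence_gap: float = 0.3  # inhalation pause between words, s
    inter_sentence_pause: float = 1.5
    inter_phrase_pause: float = 4.0
    # intensity, in peak-reading U (16-bit magnitude)
    amplitude_mean: float = 1659.973
    amplitude_min_mean: float = 343.0  # quietest word per recording targets this
    amplitude_cv: float = 0.5  # free dispersion parameter (no published SD)
    amplitude_max_factor: float = 3.0  # per-word peaks clipped at this x mean
    noise_rms: float = 0.001
    total_duration_range: tuple[float, float] = (30.0, 90.0)
    seed: int = 0

    def validate(self) -> None:
        def _range_ok(name: str, rng: tuple[float, float]) -> None:
            if rng[0] > rng[1]:
                raise SpecValidationError(f"{name}: min must be <= max, got {rng}")

        if self.sample_rate <= 0:
            raise SpecValidationError("sample_rate must be a positive integer")
        if self.n_harmonics < 1:
            raise SpecValidationError("n_harmonics must be >= 1")
        if not 150.0 <= self.f0_mean <= 800.0:
            raise SpecValidationError("f0_mean must lie within [150, 800] Hz")
        if self.f0_jitter < 0:
            raise SpecValidationError("f0_jitter must be >= 0")
        for name in (
            "word_duration_mean",
            "first_word_duration_mean",
            "intra_sentence_gap",
            "inter_sentence_pause",
            "inter_phrase_pause",
        ):
            if getattr(self, name) <= 0:
                raise SpecValidationError(f"{name} must be positive")
        for name in (
            "words_per_sentence_range",
            "sentences_per_phrase_range",
            "word_duration_range",
            "first_word_duration_range",
            "total_duration_range",
        ):
            _range_ok(name, getattr(self, name))
        lo, hi = self.word_duration_range
        if lo < 0.1 or hi > 5.0:
            raise SpecValidationError("word_duration_range must lie within [0.1 s, 5 s]")
        if self.total_duration_range[0] <= 0:
            raise SpecValidationError("total durations must be positive")
        if not self.intra_sentence_gap < self.inter_sentence_pause < self.inter_phrase_pause:
            raise SpecValidationError(
                "pauses must be strictly ordered: "
                "intra_sentence_gap < inter_sentence_pause < inter_phrase_pause"
            )
        if self.amplitude_mean <= 0 or self.amplitude_min_mean <= 0:
            raise SpecValidationError("amplitude levels must be positive")
        if self.amplitude_min_mean > self.amplitude_mean:
            raise SpecValidationError("amplitude_min_mean must not exceed amplitude_mean")
        if self.noise_rms < 0:
            raise SpecValidationError("noise_rms must be >= 0")


@dataclass
class CryScript:
    """Ground-truth word layout of one synthetic recording."""

    words: list[ScriptWord]
    total_duration: float

    @property
    def n_words(self) -> int:
        return len(self.words)

    def sentence_keys(self) -> list[tuple[int, int]]:
        seen: list[tuple[int, int]] = []
        for w in self.words:
            key = (w.phrase, w.sentence)
            if not seen or seen[-1] != key:
                seen.append(key)
        return seen

    @property
    def n_sentences(self) -> int:
        return len(self.sentence_keys())

    @property
    def n_phrases(self) -> int:
        return len({w.phrase for w in self.words})

    def words_per_sentence(self) -> list[int]:
        counts: dict[tuple[int, int], int] = {}
        for w in self.words:
            counts[(w.phrase, w.sentence)] = counts.get((w.phrase, w.sentence), 0) + 1
        return [counts[k] for k in sorted(counts)]


# ---------------------------------------------------------------------------
# presets

#: Control group: words/sentence 9.45 +/- 3.381 in [4, 18]; typical peak level
#: 1659.973 U with per-recording minimum near 343 U (the group PPM statistics).
GROUP_M_PRESET = SynthSpec()

#: Nuchal-cord group: words/sentence 7.65 +/- 2.485 in [4, 14]; louder minima
#: (598 U) and typical level 2189.202 U, with slightly more sentences per
#: phrase than controls.
GROUP_C_PRESET = SynthSpec(
    words_per_sentence_mean=7.65,
    words_per_sentence_sd=2.485,
    words_per_sentence_range=(4, 14),
    sentences_per_phrase_range=(3, 4),
    amplitude_mean=2189.202,
    amplitude_min_mean=598.0,
)


def group_preset(group: str) -> SynthSpec:
    """Return a fresh copy of the preset for study group "M" or "C"."""
    if group == "M":
        return copy.deepcopy(GROUP_M_PRESET)
    if group == "C":
        return copy.deepcopy(GROUP_C_PRESET)
    raise ValueError(f"unknown group: {group!r}")


# ---------------------------------------------------------------------------
# planning


def _draw_words_per_sentence(spec: SynthSpec, rng: np.random.Generator) -> int:
    """Truncated discrete normal: round a normal draw, clip to the range."""
    lo, hi = spec.words_per_sentence_range
    n = int(round(rng.normal(spec.words_per_sentence_mean, spec.words_per_sentence_sd)))
    return int(np.clip(n, lo, hi))


def _draw_duration(
    rng: np.random.Generator, mean: float, sd: float, rng_lim: tuple[float, float]
) -> float:
    return float(np.clip(rng.normal(mean, sd), rng_lim[0], rng_lim[1]))


def plan_cry(spec: SynthSpec, rng_seed: int | None = None) -> CryScript:
    """Lay out the word/sentence/phrase structure of one recording.

    The total duration is drawn uniformly from ``total_duration_range``.
    Whole sentences are appended while they fit the duration budget; the
    first sentence that would overflow ends the plan, so completed
    sentences keep the nominal words-per-sentence distribution.  If not
    even the first word fits, a single word truncated to the budget is
    emitted, so every script holds at least one word.
    """
    spec.validate()
    if rng_seed is None:
        rng_seed = spec.seed
    rng = np.random.default_rng(rng_seed)

    target = float(rng.uniform(*spec.total_duration_range))
    words: list[ScriptWord] = []
    cursor = 0.0
    phrase = sentence = 0
    done = False
    first = True
    while not done:
        n_sent = int(rng.integers(spec.sentences_per_phrase_range[0],
                                  spec.sentences_per_phrase_range[1] + 1))
        for s in range(n_sent):
            n_words = _draw_words_per_sentence(spec, rng)
            durations = []
            for k in range(n_words):
                if first and k == 0:
                    durations.append(_draw_duration(
                        rng, spec.first_word_duration_mean,
                        spec.first_word_duration_sd, spec.first_word_duration_range))
                else:
                    durations.append(_draw_duration(
                        rng, spec.word_duration_mean,
                        spec.word_duration_sd, spec.word_duration_range))
            lead = 0.0
            if words:
                lead = (spec.inter_sentence_pause if s > 0 else spec.inter_phrase_pause)
            span = sum(durations) + spec.intra_sentence_gap * (n_words - 1)
            if cursor + lead + span > target:
                if not words:
                    # budget smaller than one word: emit a single truncated word
                    d = min(durations[0], target)
                    words.append(ScriptWord(0, 0, 0, 0.0, d, 1.0, spec.f0_mean))
                done = True
                break
            t = cursor + lead
            for k, d in enumerate(durations):
                words.append(ScriptWord(phrase, sentence, k, t, d, 1.0, spec.f0_mean))
                t += d + spec.intra_sentence_gap
            cursor = t - spec.intra_sentence_gap
            sentence += 1
            first = False
        else:
            phrase += 1
            sentence = 0
            continue
        break

    words = _assign_levels(words, spec, rng)
    words = _renumber(words)
    return CryScript(words=words, total_duration=target)


def _assign_levels(
    words: list[ScriptWord], spec: SynthSpec, rng: np.random.Generator
) -> list[ScriptWord]:
    """Draw per-word peak amplitudes and F0, forcing one quiet word.

    Peaks are lognormal around ``amplitude_mean`` (CV ``amplitude_cv``),
    clipped between 1.5x the minimum level and ``amplitude_max_factor`` x
    the mean; one randomly chosen word is instead set near
    ``amplitude_min_mean`` so the per-recording minimum intensity sits at
    the group's published level.
    """
    n = len(words)
    mean_norm = spec.amplitude_mean / FULL_SCALE_U
    min_norm = spec.amplitude_min_mean / FULL_SCALE_U
    sigma = float(np.sqrt(np.log1p(spec.amplitude_cv**2)))
    mu = np.log(mean_norm) - sigma**2 / 2
    peaks = np.exp(rng.normal(mu, sigma, size=n))
    lo = min(1.5 * min_norm, mean_norm)
    hi = min(spec.amplitude_max_factor * mean_norm, 0.95)
    peaks = np.clip(peaks, lo, hi)
    quiet = int(rng.integers(n))
    peaks[quiet] = min(min_norm * float(np.exp(rng.normal(0.0, 0.1))), lo * 0.99)

    f0s = np.clip(rng.normal(spec.f0_mean, spec.f0_jitter * spec.f0_mean, size=n),
                  150.0, 800.0)
    return [w._replace(peak_amplitude=float(p), f0=float(f))
            for w, p, f in zip(words, peaks, f0s)]


def _renumber(words: list[ScriptWord]) -> list[ScriptWord]:
    """Make (phrase, sentence) indices contiguous from 0 after truncation."""
    out: list[ScriptWord] = []
    phrase_map: dict[int, int] = {}
    sent_map: dict[tuple[int, int], int] = {}
    for w in words:
        p = phrase_map.setdefault(w.phrase, len(phrase_map))
        key = (w.phrase, w.sentence)
        if key not in sent_map:
            n_in_phrase = sum(1 for k in sent_map if k[0] == w.phrase)
            sent_map[key] = n_in_phrase
        out.append(w._replace(phrase=p, sentence=sent_map[key]))
    return out


# ---------------------------------------------------------------------------
# rendering

_ATTACK_S = 0.1
_DECAY_S = 0.1


def _word_signal(duration: float, f0: float, peak: float,
                 n_harmonics: int, sample_rate: int) -> np.ndarray:
    n = int(round(duration * sample_rate))
    if n == 0:
        return np.zeros(0)
    t = np.arange(n) / sample_rate
    x = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        x += np.sin(2 * np.pi * k * f0 * t) / k
    m = np.max(np.abs(x))
    if m > 0:
        x /= m
    attack = min(_ATTACK_S, 0.3 * duration)
    decay = min(_DECAY_S, 0.3 * duration)
    env = np.ones(n)
    na = int(round(attack * sample_rate))
    nd = int(round(decay * sample_rate))
    if na > 0:
        env[:na] = np.linspace(0.0, 1.0, na, endpoint=False)
    if nd > 0:
        env[n - nd:] = np.linspace(1.0, 0.0, nd)
    return peak * env * x


def render_cry(script: CryScript, spec: SynthSpec,
               rng_seed: int | None = None) -> Waveform:
    """Render a script to audio: harmonic words over Gaussian noise.

    Each word is a harmonic stack at its F0 (1/k roll-off) normalized so
    the attack-sustain-decay envelope reaches exactly ``peak_amplitude``;
    elsewhere only background noise at ``noise_rms``.  Output is clipped
    to [-1, 1] and has ``round(total_duration * sample_rate)`` samples.
    """
    spec.validate()
    if rng_seed is None:
        rng_seed = spec.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0x52454E44]))
    n = int(round(script.total_duration * spec.sample_rate))
    out = (rng.normal(0.0, spec.noise_rms, size=n) if spec.noise_rms > 0
           else np.zeros(n))
    for w in script.words:
        if w.onset > script.total_duration:
            raise ValueError("script word starts beyond total_duration")
        i0 = int(round(w.onset * spec.sample_rate))
        sig = _word_signal(w.duration, w.f0, w.peak_amplitude,
                           spec.n_harmonics, spec.sample_rate)
        i1 = min(i0 + sig.size, n)
        out[i0:i1] += sig[: i1 - i0]
    return Waveform(samples=np.clip(out, -1.0, 1.0), sample_rate=spec.sample_rate)


# ---------------------------------------------------------------------------
# cohorts


class CohortRecord(NamedTuple):
    waveform: Waveform
    metadata: RecordingMetadata
    script: CryScript


def _make_metadata(group: str, ordinal: int, number: int,
                   rng: np.random.Generator) -> RecordingMetadata:
    if group == "M":
        ga = int(rng.integers(38, 43))
        apgar = 10
        other = ""
    else:
        ga = int(rng.integers(38, 43))
        apgar = int(rng.integers(7, 11))
        other = "tight nuchal cord"
    day = int(rng.integers(0, 1065))  # study window, ~May 2009 .. Mar 2012
    date = np.datetime64("2009-05-01") + np.timedelta64(day, "D")
    gesta = int(rng.integers(1, 5))
    return RecordingMetadata(
        first_last_name=f"NB-{group}{ordinal}",
        number=number,
        indicative=f"{group}{ordinal}",
        sex="M" if rng.random() < 0.5 else "F",
        date_of_birth=str(date),
        time_of_birth=f"{int(rng.integers(0, 24)):02d}:{int(rng.integers(0, 60)):02d}",
        weight_g=float(np.clip(rng.normal(3400, 400), 2500, 4500).round()),
        head_circumference_cm=round(float(rng.normal(34.5, 1.2)), 1),
        chest_circumference_cm=round(float(rng.normal(33.0, 1.5)), 1),
        length_cm=round(float(rng.normal(51.0, 2.0)), 1),
        gestational_age_weeks=ga,
        apgar=apgar,
        birth_type="natural" if rng.random() < 0.7 else "caesarian",
        presentation="cephalic" if rng.random() < 0.95 else "pelvic",
        gesta=gesta,
        para=int(rng.integers(1, gesta + 1)),
        group=group,
        other_info=other,
    )


def generate_cohort(spec_m: SynthSpec, spec_c: SynthSpec,
                    n_m: int, n_c: int, seed: int) -> list[CohortRecord]:
    """Generate ``n_m`` group-M then ``n_c`` group-C scripted recordings.

    Per-record seeds are derived deterministically from the master seed,
    so the whole cohort is reproducible bit-for-bit.
    """
    if n_m < 1 or n_c < 1:
        raise ValueError("both cohorts need at least one recording")
    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(3 * (n_m + n_c)).astype(np.int64)
    records: list[CohortRecord] = []
    idx = 0
    for group, spec, count in (("M", spec_m, n_m), ("C", spec_c, n_c)):
        for j in range(count):
            plan_seed, render_seed, meta_seed = state[3 * idx: 3 * idx + 3]
            script = plan_cry(spec, rng_seed=int(plan_seed))
            wave = render_cry(script, spec, rng_seed=int(render_seed))
            meta = _make_metadata(group, j + 1, idx + 1,
                                  np.random.default_rng(int(meta_seed)))
            records.append(CohortRecord(wave, meta, script))
            idx += 1
    return records
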