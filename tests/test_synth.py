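"""Synthetic cry generator: planning, rendering, cohorts."""

import numpy as np
import pytest

from cryspect import (
    SpecValidationError,
    SynthSpec,
    generate_cohort,
    group_preset,
    inclusion_filter,
    plan_cry,
    render_cry,
)

from conftest import short_preset


def rigid_spec(**overrides):
    """Spec with all randomness in durations/counts removed."""
    base = dict(
        words_per_sentence_mean=3, words_per_sentence_sd=0.0,
        words_per_sentence_range=(3, 3),
        sentences_per_phrase_range=(2, 2),
        word_duration_mean=1.0, word_duration_sd=0.0, word_duration_range=(1.0, 1.0),
        first_word_duration_mean=1.0, first_word_duration_sd=0.0,
        first_word_duration_range=(1.0, 1.0),
        total_duration_range=(10.0, 10.0),
        noise_rms=0.0,
    )
    base.update(overrides)
    return SynthSpec(**base)


def test_invalid_spec_names_violated_invariant():
    spec = SynthSpec(intra_sentence_gap=2.0, inter_sentence_pause=1.0)
    with pytest.raises(SpecValidationError, match="intra_sentence_gap"):
        plan_cry(spec, 0)
    with pytest.raises(SpecValidationError, match="f0_mean"):
        plan_cry(SynthSpec(f0_mean=100.0), 0)
    with pytest.raises(SpecValidationError, match="word_duration_range"):
        plan_cry(SynthSpec(word_duration_range=(0.01, 1.0)), 0)


def test_degenerate_ranges_force_exact_structure():
    # one phrase of 2 sentences x 3 words fits a 10 s budget; a second
    # phrase (4 s pause + 3.6 s) would overflow it
    script = plan_cry(rigid_spec(), rng_seed=5)
    assert script.n_words == 6
    assert script.n_sentences == 2
    assert script.n_phrases == 1
    assert script.words_per_sentence() == [3, 3]


def test_sub_word_budget_yields_single_truncated_word():
    script = plan_cry(rigid_spec(total_duration_range=(0.5, 0.5)), rng_seed=5)
    assert script.n_words == 1
    assert script.words[0].duration == pytest.approx(0.5)


def test_script_words_are_ordered_contiguous_and_gapped():
    spec = short_preset("M")
    script = plan_cry(spec, rng_seed=11)
    onsets = [w.onset for w in script.words]
    assert onsets == sorted(onsets)
    for prev, cur in zip(script.words, script.words[1:]):
        assert cur.onset >= prev.onset + prev.duration - 1e-9
        if (cur.phrase, cur.sentence) == (prev.phrase, prev.sentence):
            gap = cur.onset - (prev.onset + prev.duration)
            assert gap == pytest.approx(spec.intra_sentence_gap)
    # (phrase, sentence) pairs contiguous from 0
    keys = script.sentence_keys()
    phrases = sorted({p for p, _ in keys})
    assert phrases == list(range(len(phrases)))
    for p in phrases:
        sents = [s for q, s in keys if q == p]
        assert sents == list(range(len(sents)))


def test_words_per_sentence_sampler_recovers_group_m_parameters():
    """Monte-Carlo: >=1000 planned sentences match the 9.45/3.381 target."""
    spec = group_preset("M")
    counts = []
    seed = 0
    while len(counts) < 1000:
        counts.extend(plan_cry(spec, rng_seed=1000 + seed).words_per_sentence())
        seed += 1
    assert np.mean(counts) == pytest.approx(9.45, abs=0.3)
    lo, hi = spec.words_per_sentence_range
    assert min(counts) >= lo and max(counts) <= hi


def test_render_empty_script_is_silence():
    from cryspect.synth import CryScript

    spec = rigid_spec()
    w = render_cry(CryScript(words=[], total_duration=2.0), spec)
    assert w.samples.size == round(2.0 * spec.sample_rate)
    assert np.all(w.samples == 0.0)


def test_rendered_word_peaks_at_its_f0():
    from cryspect.synth import CryScript, ScriptWord

    spec = rigid_spec()
    script = CryScript(words=[ScriptWord(0, 0, 0, 0.0, 1.0, 0.5, 350.0)],
                       total_duration=1.0)
    w = render_cry(script, spec)
    mags = np.abs(np.fft.rfft(w.samples))
    freqs = np.fft.rfftfreq(w.samples.size, 1 / spec.sample_rate)
    assert freqs[np.argmax(mags)] == pytest.approx(350.0, abs=5.0)
    # envelope reaches the scripted peak amplitude
    assert np.max(np.abs(w.samples)) == pytest.approx(0.5, abs=0.02)
    from cryspect import compute_ppm

    assert compute_ppm(w).values.max() == pytest.approx(0.5 * 32767, abs=50)


def test_no_rendered_sample_exceeds_full_scale():
    for seed in range(5):
        spec = short_preset("M", amplitude_mean=20000.0, amplitude_min_mean=5000.0,
                            noise_rms=0.01)
        w = render_cry(plan_cry(spec, seed), spec, seed)
        assert np.max(np.abs(w.samples)) <= 1.0


def test_cohort_counts_labels_and_inclusion():
    records = generate_cohort(short_preset("M"), short_preset("C"), 2, 3, seed=9)
    assert [r.metadata.group for r in records] == ["M", "M", "C", "C", "C"]
    assert [r.metadata.indicative for r in records] == ["M1", "M2", "C1", "C2", "C3"]
    for r in records:
        assert inclusion_filter(r.metadata).include


def test_cohort_is_bit_identical_under_same_seed():
    a = generate_cohort(short_preset("M"), short_preset("C"), 2, 2, seed=13)
    b = generate_cohort(short_preset("M"), short_preset("C"), 2, 2, seed=13)
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.waveform.samples, rb.waveform.samples)
        assert ra.metadata == rb.metadata
        assert ra.script == rb.script
    c = generate_cohort(short_preset("M"), short_preset("C"), 2, 2, seed=14)
    assert not np.array_equal(a[0].waveform.samples, c[0].waveform.samples)


def test_script_sidecar_round_trip(tmp_path):
    from cryspect.io import read_script_sidecar, write_script_sidecar

    script = plan_cry(short_preset("C"), rng_seed=21)
    path = tmp_path / "script.tsv"
    write_script_sidecar(path, script)
    back = read_script_sidecar(path)
    assert back.total_duration == script.total_duration
    assert back.words == script.words


def test_wav_round_trip(tmp_path):
    from cryspect.io import read_wav, write_wav

    spec = short_preset("M")
    w = render_cry(plan_cry(spec, 2), spec, 2)
    write_wav(tmp_path / "cry.wav", w)
    back = read_wav(tmp_path / "cry.wav")
    assert back.sample_rate == spec.sample_rate
    assert np.max(np.abs(back.samples - w.samples)) < 1.0 / 32767
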