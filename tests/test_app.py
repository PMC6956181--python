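"""Inclusion/quality filters and end-to-end study orchestration."""

import dataclasses

import numpy as np
import pytest

from cryspect import (
    StudyConfig,
    Waveform,
    inclusion_filter,
    plan_cry,
    quality_filter,
    render_cry,
    run_study,
)
from cryspect.metadata import RecordingMetadata

from conftest import short_preset


def meta(group="M", ga=39, apgar=10):
    return RecordingMetadata(
        first_last_name="NB", number=1, indicative=f"{group}1", sex="M",
        date_of_birth="2010-01-01", time_of_birth="08:00", weight_g=3300,
        head_circumference_cm=34.0, chest_circumference_cm=33.0, length_cm=50.0,
        gestational_age_weeks=ga, apgar=apgar, birth_type="natural",
        presentation="cephalic", gesta=1, para=1, group=group)


def test_inclusion_criteria_per_group():
    assert inclusion_filter(meta("M", ga=39, apgar=10)).include
    dec = inclusion_filter(meta("M", ga=39, apgar=9))
    assert not dec.include and "Apgar" in dec.reason
    dec = inclusion_filter(meta("C", ga=37, apgar=8))
    assert not dec.include and "GA" in dec.reason
    assert inclusion_filter(meta("C", ga=38, apgar=7)).include
    assert not inclusion_filter(meta("M", ga=43, apgar=10)).include


def test_quality_filter_clean_cry_included():
    spec = short_preset("M", noise_rms=0.001)
    w = render_cry(plan_cry(spec, 3), spec, 3)
    dec = quality_filter(w)
    assert dec.include
    assert dec.snr_db > 10.0


def test_quality_filter_pure_noise_excluded(rng):
    w = Waveform(samples=rng.normal(0, 0.0005, 22050 * 5), sample_rate=22050)
    dec = quality_filter(w)
    assert not dec.include


def test_quality_inclusion_is_monotone_in_noise():
    spec = short_preset("C")
    script = plan_cry(spec, 8)
    included = []
    for noise in (0.0005, 0.002, 0.02, 0.08):
        noisy_spec = dataclasses.replace(spec, noise_rms=noise)
        w = render_cry(script, noisy_spec, 8)
        included.append(quality_filter(w).include)
    assert included[0]  # clean recording passes
    # once excluded, more noise never re-includes
    for prev, cur in zip(included, included[1:]):
        assert not (cur and not prev)
    assert not included[-1]


def small_config(tmp_path=None, **overrides):
    cfg = StudyConfig(
        spec_m=short_preset("M"), spec_c=short_preset("C"),
        n_m=2, n_c=2, seed=11,
        classifier_kinds=("IB1", "RT"), meters=("VU",),
        out_dir=str(tmp_path) if tmp_path else None,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def test_run_study_produces_expected_artifacts(tmp_path):
    cfg = small_config(tmp_path)
    report = run_study(cfg)
    assert report.n_included == {"M": 2, "C": 2}
    assert report.n_excluded == {"M": 0, "C": 0}
    # one outcome per (meter, kind, protocol), infeasible protocols recorded
    assert len(report.evaluations) == 1 * 2 * 3
    training = [e for e in report.evaluations if e.protocol == "training"]
    assert all(e.report is not None for e in training)
    cv = [e for e in report.evaluations if e.protocol == "cv10"]
    assert all(e.report is None and "10" in e.error for e in cv)  # n=4 < 10

    assert (tmp_path / "cry_vu.arff").exists()
    assert (tmp_path / "metadata.tsv").exists()
    assert (tmp_path / "tables.tsv").exists()
    assert (tmp_path / "classification.tsv").exists()
    bundles = list((tmp_path / "bundles").iterdir())
    assert len(bundles) == 4
    for b in bundles:
        for fname in ("VU.txt", "PPM.txt", "Spectrum.txt"):
            assert (b / fname).exists()
        assert list(b.glob("*.wav"))


def test_run_study_is_deterministic(tmp_path):
    rep1 = run_study(small_config(tmp_path / "a"))
    rep2 = run_study(small_config(tmp_path / "b"))
    assert rep1.config_hash == rep2.config_hash
    assert (tmp_path / "a" / "tables.tsv").read_bytes() == \
        (tmp_path / "b" / "tables.tsv").read_bytes()
    assert (tmp_path / "a" / "classification.tsv").read_bytes() == \
        (tmp_path / "b" / "classification.tsv").read_bytes()
    assert (tmp_path / "a" / "cry_vu.arff").read_bytes() == \
        (tmp_path / "b" / "cry_vu.arff").read_bytes()


def test_run_study_filter_accounting_with_injected_noise():
    cfg = small_config(n_m=4, n_c=4, noisy_fraction=0.5, noisy_rms=0.1)
    report = run_study(cfg)
    for g in ("M", "C"):
        assert report.n_included[g] + report.n_excluded[g] == report.n_generated[g]
    assert sum(report.n_excluded.values()) > 0


def test_study_config_from_toml(tmp_path):
    toml = tmp_path / "study.toml"
    toml.write_text(
        "[study]\nn_m = 3\nn_c = 2\nseed = 42\nmeters = [\"VU\"]\n\n"
        "[spec_m]\ntotal_duration_range = [8.0, 10.0]\n\n"
        "[segmentation]\nmin_word_ms = 300\n")
    cfg = StudyConfig.from_toml(toml)
    assert (cfg.n_m, cfg.n_c, cfg.seed) == (3, 2, 42)
    assert cfg.meters == ("VU",)
    assert cfg.spec_m.total_duration_range == (8.0, 10.0)
    assert cfg.segmentation.min_word_ms == 300
    with pytest.raises(ValueError, match="unknown"):
        bad = tmp_path / "bad.toml"
        bad.write_text("[study]\nnot_a_field = 1\n")
        StudyConfig.from_toml(bad)


def test_metadata_table_round_trip(tmp_path, small_cohort):
    from cryspect.io import read_metadata_table, write_metadata_table

    metas = [r.metadata for r in small_cohort]
    path = tmp_path / "metadata.tsv"
    write_metadata_table(path, metas)
    back = read_metadata_table(path)
    assert len(back) == len(metas)
    assert [m.indicative for m in back] == [m.indicative for m in metas]
    assert [m.apgar for m in back] == [m.apgar for m in metas]


def test_bundle_round_trip(tmp_path):
    from cryspect.io import read_bundle, write_bundle
    from cryspect import compute_vu

    spec = short_preset("M")
    w = render_cry(plan_cry(spec, 4), spec, 4)
    folder = write_bundle(tmp_path / "M1", "M1", w)
    back = read_bundle(folder)
    assert back["VU"].kind == "VU"
    assert back["VU"].n_frames == compute_vu(w).n_frames
    assert np.allclose(back["VU"].values, compute_vu(w).values, atol=0.01)
    assert back["Spectrum"].n_frames == back["PPM"].n_frames
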