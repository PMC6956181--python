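"""End-to-end study orchestration: synthesize, filter, measure, report.

``run_study`` drives the whole pipeline on two synthetic cohorts:
generation (with optional injection of noise-corrupted recordings),
cohort inclusion and recording-quality filtering, 100 ms metering and
spectrum extraction, cry-language segmentation, group descriptive tables
and t-tests, ARFF export, and the classifier evaluation grid.  All
randomness derives from one master seed, and every written artifact is
stamped with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

from . import io as cio
from .classify import (
    CLASSIFIER_KINDS,
    PROTOCOLS,
    EvalReport,
    build_feature_vectors,
    evaluate,
    write_arff,
)
from .features import Waveform, compute_ppm, compute_spectrum, compute_vu
from .linguistics import (
    SegmentationConfig,
    StructureStats,
    detect_words,
    group_structure,
    structure_stats,
)
from .metadata import RecordingMetadata
from .stats import CohortSummary, IntensityTable, intensity_table, summarize_variable
from .synth import CohortRecord, SynthSpec, generate_cohort, group_preset

logger = logging.getLogger("cryspect")


class FilterDecision(NamedTuple):
    include: bool
    reason: str


def inclusion_filter(m: RecordingMetadata) -> FilterDecision:
    """Cohort inclusion criteria.

    Group M (control): gestational age 38-42 weeks and Apgar exactly 10.
    Group C (nuchal cord): gestational age >= 38 weeks and Apgar 7-10.
    The reason string names the first failed criterion.
    """
    if m.group == "M":
        if not 38 <= m.gestational_age_weeks <= 42:
            return FilterDecision(False, "GA: control requires 38-42 weeks")
        if m.apgar != 10:
            return FilterDecision(False, "Apgar: control requires score 10")
        return FilterDecision(True, "ok")
    if m.group == "C":
        if m.gestational_age_weeks < 38:
            return FilterDecision(False, "GA: requires >= 38 weeks")
        if not 7 <= m.apgar <= 10:
            return FilterDecision(False, "Apgar: requires score 7-10")
        return FilterDecision(True, "ok")
    raise ValueError(f"unknown group {m.group!r}")


class QualityDecision(NamedTuple):
    include: bool
    snr_db: float


def quality_filter(
    w: Waveform,
    threshold_db: float = 10.0,
    cfg: SegmentationConfig | None = None,
) -> QualityDecision:
    """Exclude recordings whose cry does not rise above the noise floor.

    The SNR estimate is the ratio (in dB) of the mean VU over voiced
    frames (frames inside detected words) to the mean VU over the
    remaining frames.  Recordings with no detected words are excluded,
    and so are recordings with no unvoiced frames at all (noise so loud
    it saturates the activity detector leaves no usable noise floor).
    A silent background yields an effectively infinite SNR.
    """
    vu = compute_vu(w)
    words = detect_words(vu, cfg)
    if not words:
        return QualityDecision(False, float("-inf"))
    from .linguistics import CryStructure, voiced_frame_mask

    mask = voiced_frame_mask(CryStructure(phrases=[[words]]), vu.n_frames, vu.frame_ms)
    voiced_mean = float(vu.values[mask].mean())
    unvoiced = vu.values[~mask]
    if unvoiced.size == 0:
        return QualityDecision(False, float("nan"))
    unvoiced_mean = float(unvoiced.mean())
    if unvoiced_mean <= 0:
        return QualityDecision(True, float("inf"))
    snr_db = 20.0 * np.log10(voiced_mean / unvoiced_mean)
    return QualityDecision(snr_db >= threshold_db, float(snr_db))


@dataclass
class StudyConfig:
    spec_m: SynthSpec = field(default_factory=lambda: group_preset("M"))
    spec_c: SynthSpec = field(default_factory=lambda: group_preset("C"))
    n_m: int = 101
    n_c: int = 72
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classifier_kinds: tuple[str, ...] = CLASSIFIER_KINDS
    protocols: tuple[str, ...] = PROTOCOLS
    meters: tuple[str, ...] = ("VU", "PPM")
    seed: int = 0
    quality_threshold_db: float = 10.0
    noisy_fraction: float = 0.0  # fraction of recordings corrupted by noise
    noisy_rms: float = 0.08
    out_dir: str | None = None
    write_bundles: bool = True

    def config_hash(self) -> str:
        payload = {k: repr(v) for k, v in dataclasses.asdict(self).items()
                   if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_toml(cls, path) -> "StudyConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        cfg = cls()
        for section, target in (("spec_m", cfg.spec_m), ("spec_c", cfg.spec_c),
                                ("segmentation", cfg.segmentation)):
            for k, v in data.get(section, {}).items():
                if not hasattr(target, k):
                    raise ValueError(f"unknown {section} option {k!r}")
                if isinstance(v, list):
                    v = tuple(v)
                setattr(target, k, v)
        for k, v in data.get("study", {}).items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown study option {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            setattr(cfg, k, v)
        return cfg


@dataclass
class EvalOutcome:
    meter: str
    kind: str
    protocol: str
    report: EvalReport | None
    error: str | None = None


@dataclass
class StudyReport:
    seed: int
    config_hash: str
    n_generated: dict[str, int]
    n_included: dict[str, int]
    n_excluded: dict[str, int]
    sentence_duration: dict[str, CohortSummary]
    words_per_sentence: dict[str, CohortSummary]
    first_word_duration: CohortSummary
    intensity: IntensityTable
    evaluations: list[EvalOutcome]
    recordings: list[CohortRecord] = field(repr=False, default_factory=list)
    structures: dict[str, list] = field(repr=False, default_factory=dict)


def _maybe_corrupt(records: list[CohortRecord], cfg: StudyConfig) -> list[CohortRecord]:
    if cfg.noisy_fraction <= 0:
        return records
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x4E4F4953]))
    out = []
    for rec in records:
        if rng.random() < cfg.noisy_fraction:
            noisy = rec.waveform.samples + rng.normal(
                0.0, cfg.noisy_rms, size=rec.waveform.samples.size)
            out.append(CohortRecord(
                Waveform(np.clip(noisy, -1, 1), rec.waveform.sample_rate),
                rec.metadata, rec.script))
        else:
            out.append(rec)
    return out


def run_study(cfg: StudyConfig) -> StudyReport:
    """Execute the full pipeline and (optionally) write the report bundle."""
    stage = "generate"
    try:
        records = generate_cohort(cfg.spec_m, cfg.spec_c, cfg.n_m, cfg.n_c, cfg.seed)
        records = _maybe_corrupt(records, cfg)
        n_generated = {"M": cfg.n_m, "C": cfg.n_c}

        stage = "filter"
        included: list[CohortRecord] = []
        n_included = {"M": 0, "C": 0}
        for rec in records:
            ok_meta = inclusion_filter(rec.metadata)
            ok_quality = quality_filter(rec.waveform, cfg.quality_threshold_db,
                                        cfg.segmentation)
            if ok_meta.include and ok_quality.include:
                included.append(rec)
                n_included[rec.metadata.group] += 1
            else:
                reason = ok_meta.reason if not ok_meta.include else (
                    f"noise (SNR {ok_quality.snr_db:.1f} dB)")
                logger.info("excluded %s: %s", rec.metadata.indicative, reason)
        n_excluded = {g: n_generated[g] - n_included[g] for g in n_generated}
        logger.info("filter accounting: generated=%s included=%s excluded=%s",
                    n_generated, n_included, n_excluded)
        for g in n_included:
            if n_included[g] == 0:
                raise RuntimeError(f"group {g}: no recordings passed the filters")

        stage = "measure"
        traces: dict[str, list[dict]] = {"M": [], "C": []}
        structures: dict[str, list] = {"M": [], "C": []}
        stats_by_group: dict[str, list[StructureStats]] = {"M": [], "C": []}
        for rec in included:
            g = rec.metadata.group
            vu = compute_vu(rec.waveform)
            ppm = compute_ppm(rec.waveform)
            spec = compute_spectrum(rec.waveform)
            structure = group_structure(detect_words(vu, cfg.segmentation),
                                        cfg.segmentation)
            traces[g].append({"VU": vu, "PPM": ppm, "Spectrum": spec})
            structures[g].append(structure)
            stats_by_group[g].append(structure_stats(structure))

        stage = "summarize"
        sentence_duration = {
            g: summarize_variable(
                [d for st in stats_by_group[g] for d in st.sentence_durations],
                f"sentence duration (s), group {g}")
            for g in ("M", "C")}
        words_per_sentence = {
            g: summarize_variable(
                [c for st in stats_by_group[g] for c in st.words_per_sentence],
                f"words/sentence, group {g}")
            for g in ("M", "C")}
        first_words = [st.first_word_duration
                       for g in ("M", "C") for st in stats_by_group[g]
                       if st.first_word_duration is not None]
        first_word = summarize_variable(first_words, "first word duration (s)")
        intensity = intensity_table(traces, structures)

        stage = "classify"
        evaluations: list[EvalOutcome] = []
        datasets = {}
        for meter in cfg.meters:
            datasets[meter] = build_feature_vectors(included, meter=meter)
            for kind in cfg.classifier_kinds:
                for protocol in cfg.protocols:
                    try:
                        rep = evaluate(kind, datasets[meter], protocol, seed=cfg.seed)
                        evaluations.append(EvalOutcome(meter, kind, protocol, rep))
                    except ValueError as exc:
                        evaluations.append(EvalOutcome(meter, kind, protocol,
                                                       None, error=str(exc)))

        report = StudyReport(
            seed=cfg.seed, config_hash=cfg.config_hash(),
            n_generated=n_generated, n_included=n_included, n_excluded=n_excluded,
            sentence_duration=sentence_duration,
            words_per_sentence=words_per_sentence,
            first_word_duration=first_word,
            intensity=intensity, evaluations=evaluations,
            recordings=included, structures=structures,
        )

        if cfg.out_dir is not None:
            stage = "write"
            _write_outputs(cfg, report, datasets, structures, included)
        return report
    except Exception as exc:
        raise RuntimeError(f"study failed at stage '{stage}': {exc}") from exc


def _fmt_summary(s: CohortSummary) -> str:
    return (f"{s.variable}\tN={s.n}\tmean={s.mean:.3f}\tsd={s.sd:.3f}"
            f"\tmin={s.min:.3f}\tmax={s.max:.3f}")


def _write_outputs(cfg: StudyConfig, report: StudyReport, datasets,
                   structures, included) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"# config={report.config_hash} seed={report.seed}\n"

    cio.write_metadata_table(out / "metadata.tsv", [r.metadata for r in included])
    if cfg.write_bundles:
        for rec in included:
            folder = cio.write_bundle(out / "bundles" / rec.metadata.indicative,
                                      rec.metadata.indicative, rec.waveform)
            cio.write_script_sidecar(folder / "script.tsv", rec.script)
    idx = {g: 0 for g in structures}
    struct_dir = out / "structures"
    struct_dir.mkdir(exist_ok=True)
    for rec in included:
        g = rec.metadata.group
        cio.write_structure_file(
            struct_dir / f"{rec.metadata.indicative}.tsv", structures[g][idx[g]])
        idx[g] += 1

    for meter, dataset in datasets.items():
        write_arff(dataset, out / f"cry_{meter.lower()}.arff")

    with open(out / "tables.tsv", "w") as fh:
        fh.write(stamp)
        for g in ("M", "C"):
            fh.write(_fmt_summary(report.sentence_duration[g]) + "\n")
            fh.write(_fmt_summary(report.words_per_sentence[g]) + "\n")
        fh.write(_fmt_summary(report.first_word_duration) + "\n")
        fh.write("group\tmeter\tmean_U\tmin_U\tmax_U\tmean_minimum_U\tn\n")
        for row in report.intensity.rows:
            fh.write(f"{row.group}\t{row.meter}\t{row.mean:.3f}\t{row.min:.3f}"
                     f"\t{row.max:.3f}\t{row.mean_minimum:.3f}\t{row.n}\n")
        for meter, tt in report.intensity.tests.items():
            fh.write(f"t-test mean-minimum {meter}\tt={tt.t:.4f}\tdf={tt.df:.1f}"
                     f"\tp={tt.p:.4g}\tCI=({tt.ci_low:.2f}, {tt.ci_high:.2f})"
                     f"\tsignificant={tt.significant}\n")

    with open(out / "classification.tsv", "w") as fh:
        fh.write(stamp)
        fh.write("meter\tkind\tprotocol\tcorrect_pct\tincorrect_pct\tMAE\tRMSE"
                 "\tRAE_pct\tRRSE_pct\tconfusion\n")
        for ev in report.evaluations:
            if ev.report is None:
                fh.write(f"{ev.meter}\t{ev.kind}\t{ev.protocol}\tERROR: {ev.error}\n")
            else:
                r = ev.report
                cm = ";".join(",".join(str(c) for c in row)
                              for row in r.confusion_matrix)
                fh.write(f"{ev.meter}\t{ev.kind}\t{ev.protocol}"
                         f"\t{r.correctly_classified_pct:.2f}"
                         f"\t{r.incorrectly_classified_pct:.2f}"
                         f"\t{r.mean_absolute_error:.4f}"
                         f"\t{r.root_mean_squared_error:.4f}"
                         f"\t{r.relative_absolute_error_pct:.2f}"
                         f"\t{r.root_relative_squared_error_pct:.2f}\t{cm}\n")

    with open(out / "filters.txt", "w") as fh:
        fh.write(stamp)
        for g in ("M", "C"):
            fh.write(f"group {g}: generated={report.n_generated[g]} "
                     f"included={report.n_included[g]} "
                     f"excluded={report.n_excluded[g]}\n")
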