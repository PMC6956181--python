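"""File formats: WAV audio, measurement bundles, scripts and structures.

A *measurement bundle* is the per-recording folder dialect of the
recording application: one ``*.wav`` file plus three text traces
(``VU.txt``, ``PPM.txt``, ``Spectrum.txt``).  Each text file starts with
a header line ``# <kind> <frame_ms>`` followed by one frame per line
(spectrum frames are tab-separated bin magnitudes).

Ground-truth scripts and detected structures are tab-separated text with
one word per line.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .features import (
    MeterTrace,
    SpectrumSeries,
    Waveform,
    compute_ppm,
    compute_spectrum,
    compute_vu,
)
from .linguistics import CryStructure, Word
from .metadata import RecordingMetadata
from .synth import CryScript, ScriptWord


def write_wav(path, w: Waveform) -> None:
    """Write mono 16-bit PCM RIFF WAV."""
    pcm = np.rint(np.clip(w.samples, -1.0, 1.0) * 32767).astype(np.int16)
    wavfile.write(str(path), w.sample_rate, pcm)


def read_wav(path) -> Waveform:
    """Read mono WAV; non-16-bit sample formats are normalized to [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data / 32767.0
    elif data.dtype == np.int32:
        samples = data / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 127.0
    else:  # float WAV
        samples = data.astype(np.float64)
    return Waveform(samples=np.clip(samples, -1.0, 1.0), sample_rate=int(rate))


# ---------------------------------------------------------------------------
# meter/spectrum text traces


def write_trace_txt(path, trace: MeterTrace | SpectrumSeries) -> None:
    with open(path, "w") as fh:
        if isinstance(trace, SpectrumSeries):
            fh.write(f"# Spectrum {trace.frame_ms:g}\n")
            for row in trace.magnitudes:
                fh.write("\t".join(f"{v:.2f}" for v in row) + "\n")
        else:
            fh.write(f"# {trace.kind} {trace.frame_ms:g}\n")
            for v in trace.values:
                fh.write(f"{v:.4f}\n")


def read_trace_txt(path, bin_width: float | None = None):
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 3 or header[0] != "#":
            raise ValueError(f"{path}: malformed trace header")
        kind, frame_ms = header[1], float(header[2])
        rows = [line.split("\t") for line in fh if line.strip()]
    if kind == "Spectrum":
        mags = np.array([[float(v) for v in row] for row in rows])
        return SpectrumSeries(magnitudes=mags, frame_ms=frame_ms,
                              bin_width=bin_width if bin_width else 1.0)
    values = np.array([float(row[0]) for row in rows])
    return MeterTrace(kind=kind, values=values, frame_ms=frame_ms)


def write_bundle(folder, name: str, w: Waveform,
                 frame_ms: float = 100.0, fft_size: int = 4096) -> Path:
    """Write the per-recording folder: one WAV and three trace files."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    write_wav(folder / f"{name}.wav", w)
    write_trace_txt(folder / "VU.txt", compute_vu(w, frame_ms))
    write_trace_txt(folder / "PPM.txt", compute_ppm(w, frame_ms))
    write_trace_txt(folder / "Spectrum.txt", compute_spectrum(w, frame_ms, fft_size))
    return folder


def read_bundle(folder) -> dict:
    """Read a bundle folder back into waveform + traces."""
    folder = Path(folder)
    wavs = sorted(folder.glob("*.wav"))
    if not wavs:
        raise FileNotFoundError(f"no wav file in bundle {folder}")
    w = read_wav(wavs[0])
    return {
        "waveform": w,
        "VU": read_trace_txt(folder / "VU.txt"),
        "PPM": read_trace_txt(folder / "PPM.txt"),
        "Spectrum": read_trace_txt(folder / "Spectrum.txt"),
    }


# ---------------------------------------------------------------------------
# ground-truth scripts and detected structures

_SCRIPT_HEADER = "phrase\tsentence\tword\tonset_s\tduration_s\tamplitude\tf0_hz"


def write_script_sidecar(path, script: CryScript) -> None:
    with open(path, "w") as fh:
        fh.write(f"# total_duration_s\t{script.total_duration!r}\n")
        fh.write(_SCRIPT_HEADER + "\n")
        for w in script.words:
            fh.write(f"{w.phrase}\t{w.sentence}\t{w.word}\t{w.onset!r}\t"
                     f"{w.duration!r}\t{w.peak_amplitude!r}\t{w.f0!r}\n")


def read_script_sidecar(path) -> CryScript:
    words = []
    total = 0.0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                total = float(line.split("\t")[1])
                continue
            if line.startswith("phrase"):
                continue
            p, s, k, onset, dur, amp, f0 = line.split("\t")
            words.append(ScriptWord(int(p), int(s), int(k), float(onset),
                                    float(dur), float(amp), float(f0)))
    return CryScript(words=words, total_duration=total)


def write_structure_file(path, structure: CryStructure) -> None:
    with open(path, "w") as fh:
        fh.write("phrase\tsentence\tword\tonset_s\tduration_s\n")
        for pi, phrase in enumerate(structure.phrases):
            for si, sent in enumerate(phrase):
                for wi, w in enumerate(sent):
                    fh.write(f"{pi}\t{si}\t{wi}\t{float(w.onset)!r}"
                             f"\t{float(w.duration)!r}\n")


def read_structure_file(path) -> CryStructure:
    phrases: list[list[list[Word]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("phrase"):
                continue
            p, s, _k, onset, dur = line.split("\t")
            p, s = int(p), int(s)
            while len(phrases) <= p:
                phrases.append([])
            while len(phrases[p]) <= s:
                phrases[p].append([])
            phrases[p][s].append(Word(onset=float(onset), duration=float(dur)))
    return CryStructure(phrases=phrases)


def structure_from_script(script: CryScript) -> CryStructure:
    """Project a ground-truth script onto the detected-structure type."""
    phrases: list[list[list[Word]]] = []
    for w in script.words:
        while len(phrases) <= w.phrase:
            phrases.append([])
        while len(phrases[w.phrase]) <= w.sentence:
            phrases[w.phrase].append([])
        phrases[w.phrase][w.sentence].append(Word(onset=w.onset, duration=w.duration))
    return CryStructure(phrases=phrases)


METADATA_FIELDS = [
    "first_last_name", "number", "indicative", "sex", "date_of_birth",
    "time_of_birth", "weight_g", "head_circumference_cm",
    "chest_circumference_cm", "length_cm", "gestational_age_weeks", "apgar",
    "birth_type", "presentation", "gesta", "para", "group", "other_info",
]


def write_metadata_table(path, metas: list[RecordingMetadata]) -> None:
    import pandas as pd

    rows = [{f: getattr(m, f) for f in METADATA_FIELDS} for m in metas]
    pd.DataFrame(rows, columns=METADATA_FIELDS).to_csv(path, sep="\t", index=False)


def read_metadata_table(path) -> list[RecordingMetadata]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [RecordingMetadata(**{f: row[f] for f in METADATA_FIELDS})
            for _, row in df.iterrows()]
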