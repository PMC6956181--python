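"""Per-recording clinical metadata for a newborn cry recording."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

INDICATIVE_RE = re.compile(r"^[MC][0-9]+$")


@dataclass
class RecordingMetadata:
    """Clinical record attached to one cry recording.

    ``group`` is the study cohort: "M" (control, eventless intrapartum,
    Apgar 10) or "C" (tight nuchal cord, Apgar 7-10).  The ``indicative``
    is the cohort letter plus an ordinal, e.g. ``M10`` or ``C7``.
    """

    first_last_name: str
    number: int
    indicative: str
    sex: str  # "M" or "F"
    date_of_birth: str
    time_of_birth: str
    weight_g: float
    head_circumference_cm: float
    chest_circumference_cm: float
    length_cm: float
    gestational_age_weeks: float
    apgar: int
    birth_type: str  # "natural" or "caesarian"
    presentation: str  # "cephalic", "pelvic" or "transverse"
    gesta: int
    para: int
    group: str  # "M" or "C"
    other_info: str = ""

    def __post_init__(self) -> None:
        if self.group not in ("M", "C"):
            raise ValueError(f"unknown group: {self.group!r}")
        if not INDICATIVE_RE.match(self.indicative):
            raise ValueError(f"indicative must match [MC]<number>: {self.indicative!r}")
        if not 1 <= self.apgar <= 10:
            raise ValueError("apgar must be in [1, 10]")
        if not 20 <= self.gestational_age_weeks <= 45:
            raise ValueError("gestational_age_weeks must be in [20, 45]")
        if self.weight_g <= 0:
            raise ValueError("weight_g must be positive")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F: {self.sex!r}")
        if self.birth_type not in ("natural", "caesarian"):
            raise ValueError(f"unknown birth_type: {self.birth_type!r}")
        if self.presentation not in ("cephalic", "pelvic", "transverse"):
            raise ValueError(f"unknown presentation: {self.presentation!r}")
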