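"""Crossover triglyceride response: ΔTG computation and responder classes.

In the crossover design each participant serves as their own control: the
treatment response ΔTG is the post-supplementation TG minus the post-control
TG, in mmol/l, once per treatment (EPA and DHA). Participants are then placed
into ordered responder classes using a window of normal intra-individual TG
variation of half-width w:

    R  (responder)          ΔTG < -w
    NR (non-responder)      |ΔTG| <= w   (boundary inclusive)
    AR (adverse responder)  ΔTG > +w

The study's window is w = 0.25 mmol/l, the cohort mean of per-participant
standard deviations of four repeated off-treatment TG measurements;
:func:`estimate_window` recomputes that quantity from data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TgProfile",
    "ResponderLabel",
    "TREATMENTS",
    "CLASS_ORDER",
    "DEFAULT_WINDOW",
    "compute_delta",
    "estimate_window",
    "classify",
    "classify_cohort",
    "percent_change",
    "read_phenotypes_csv",
    "write_phenotypes_csv",
    "labels_frame",
]

Treatment = Literal["EPA", "DHA"]
TREATMENTS: tuple[str, str] = ("EPA", "DHA")
#: responder classes in their natural order (most to least favourable)
CLASS_ORDER: tuple[str, str, str] = ("R", "NR", "AR")
#: study window half-width, mmol/l (mean intra-individual TG SD)
DEFAULT_WINDOW = 0.25


@dataclass
class TgProfile:
    """Per-participant phenotype record for one crossover cycle.

    Post-phase TG fields accept a single measurement or a sequence of
    replicate measurements; replicates are averaged when the phase value is
    used (the "mean post-intervention level").
    """

    participant_id: str
    age: float
    sex: str  # category label, e.g. "F"/"M"
    bmi: float
    tg_post_control: float | Sequence[float]
    tg_post_epa: float | Sequence[float]
    tg_post_dha: float | Sequence[float]
    tg_off_treatment: Sequence[float] = field(default_factory=list)

    def phase_mean(self, phase: str) -> float:
        value = {
            "control": self.tg_post_control,
            "EPA": self.tg_post_epa,
            "DHA": self.tg_post_dha,
        }[phase]
        if value is None:
            raise ValueError(
                f"participant {self.participant_id!r}: missing TG for phase {phase!r}"
            )
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 0 or np.isnan(arr).any():
            raise ValueError(
                f"participant {self.participant_id!r}: missing TG for phase {phase!r}"
            )
        if (arr <= 0).any():
            raise ValueError(
                f"participant {self.participant_id!r}: non-positive TG in phase {phase!r}"
            )
        return float(arr.mean())


@dataclass(frozen=True)
class ResponderLabel:
    participant_id: str
    treatment: str
    delta_tg: float
    label: str  # in CLASS_ORDER


def compute_delta(profile: TgProfile, treatment: Treatment) -> float:
    """ΔTG = mean post-treatment TG − mean post-control TG (mmol/l)."""
    if treatment not in TREATMENTS:
        raise ValueError(f"treatment must be one of {TREATMENTS}, got {treatment!r}")
    return profile.phase_mean(treatment) - profile.phase_mean("control")


def estimate_window(profiles: Iterable[TgProfile]) -> float:
    """Cohort mean of per-participant sample SDs of off-treatment TG.

    Each participant needs at least 2 repeated off-treatment measurements
    (the study used 4); the sample SD uses the n−1 denominator.
    """
    sds = []
    for p in profiles:
        values = np.asarray(p.tg_off_treatment, dtype=float)
        if values.size < 2:
            raise ValueError(
                f"participant {p.participant_id!r}: needs >=2 off-treatment "
                f"TG measurements, got {values.size}"
            )
        sds.append(values.std(ddof=1))
    if not sds:
        raise ValueError("no profiles supplied")
    return float(np.mean(sds))


def classify(delta_tg: float, window: float = DEFAULT_WINDOW) -> str:
    """Responder class from ΔTG and window half-width (boundary → NR)."""
    if window < 0:
        raise ValueError(f"window must be non-negative, got {window}")
    if delta_tg < -window:
        return "R"
    if delta_tg > window:
        return "AR"
    return "NR"


def classify_cohort(
    profiles: Iterable[TgProfile],
    window: float = DEFAULT_WINDOW,
    treatments: Sequence[str] = TREATMENTS,
) -> list[ResponderLabel]:
    """Two labels per participant (one per treatment) with their ΔTG."""
    labels = []
    for p in profiles:
        for t in treatments:
            d = compute_delta(p, t)
            labels.append(ResponderLabel(p.participant_id, t, d, classify(d, window)))
    return labels


def percent_change(pre: float, post: float) -> float:
    """TG reduction as a percentage of the pre value, to one decimal.

    Positive values are reductions: 100 × (pre − post) / pre.
    """
    if pre <= 0:
        raise ValueError(f"pre value must be positive, got {pre}")
    return round(100.0 * (pre - post) / pre, 1)


def read_phenotypes_csv(path: str | Path) -> list[TgProfile]:
    """Read per-participant phenotypes from CSV.

    Expected columns: participant_id, age, sex, bmi, tg_post_control,
    tg_post_epa, tg_post_dha, and repeated off-treatment columns
    tg_off_1..tg_off_k.
    """
    df = pd.read_csv(path)
    off_cols = sorted(
        (c for c in df.columns if c.startswith("tg_off_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    profiles = []
    for _, row in df.iterrows():
        off = [row[c] for c in off_cols if pd.notna(row[c])]
        profiles.append(
            TgProfile(
                participant_id=str(row["participant_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                bmi=float(row["bmi"]),
                tg_post_control=float(row["tg_post_control"]),
                tg_post_epa=float(row["tg_post_epa"]),
                tg_post_dha=float(row["tg_post_dha"]),
                tg_off_treatment=off,
            )
        )
    return profiles


def write_phenotypes_csv(profiles: Sequence[TgProfile], path: str | Path) -> None:
    """Write profiles in the CSV layout that :func:`read_phenotypes_csv` reads."""
    k = max((len(p.tg_off_treatment) for p in profiles), default=0)
    rows = []
    for p in profiles:
        row = {
            "participant_id": p.participant_id,
            "age": p.age,
            "sex": p.sex,
            "bmi": p.bmi,
            "tg_post_control": p.phase_mean("control"),
            "tg_post_epa": p.phase_mean("EPA"),
            "tg_post_dha": p.phase_mean("DHA"),
        }
        for i in range(k):
            row[f"tg_off_{i + 1}"] = (
                p.tg_off_treatment[i] if i < len(p.tg_off_treatment) else np.nan
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def labels_frame(labels: list[ResponderLabel], window: float) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.participant_id, l.treatment, l.delta_tg, l.label, window) for l in labels],
        columns=["participant_id", "treatment", "delta_tg", "label", "window_used"],
    )
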