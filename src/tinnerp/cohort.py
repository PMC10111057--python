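"""Synthetic study cohorts and questionnaire scoring.

The study population consists of chronic-tinnitus patients assigned to one of
five sound-based treatments -- placebo music, binaural-beats therapy (BBT),
tinnitus retraining therapy (TRT), enriched-acoustic-environment therapy
(TEAE) and auditory discrimination therapy (ADT) -- plus healthy volunteers
(control) who listen to the same relaxing music as the placebo group.  The
default completed-group sizes are 11/14/15/15/8/8 (71 participants overall,
out of 103 recruits; 32 did not complete the protocol).

Each participant carries an audiogram (per-ear hearing thresholds in dB HL),
a tinnitus profile (pitch, perceived intensity 0-100 dB, laterality L/R/B),
demographics (age, sex, heart rate) and questionnaire scores at the initial
(S0) and final (Sf) monitoring sessions: the Tinnitus Handicap Inventory
(THI, 0-100) and the two Hospital Anxiety and Depression subscales
(HADS-A anxiety, HADS-S stress, each 0-21).

Group assignment follows the clinical rules, applied most-specific first:

1. healthy volunteers -> control;
2. tinnitus pitch below 1 kHz -> BBT (binaural carriers need low pitches);
3. a well-identified tinnitus pitch -> TRT or ADT (random, seeded);
4. otherwise, with no severe hearing loss -> placebo or TEAE (random).

Participants that fall through every rule (poorly identified pitch *and*
severe loss) default to TEAE, whose loss-proportional stimulation is the
only therapy not contraindicated for them; this keeps assignment total.

The simulated marginals are chosen to be clinically plausible rather than
to reproduce the real cohort: tinnitus pitch spans up to 8 kHz, intensity
0-100 dB, hearing levels populate the normal/slight/moderate/severe bands,
and perceived intensity is generated with a built-in positive dependence on
hearing loss so that the downstream correlation screen has a known signal
to recover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import MissingDataError

__all__ = [
    "AUDIOGRAM_FREQS",
    "GROUPS",
    "THERAPY_GROUPS",
    "DEFAULT_COMPLETED",
    "DEFAULT_RECRUITED",
    "THI_CATEGORIES",
    "HADS_CATEGORIES",
    "Audiogram",
    "TinnitusProfile",
    "Participant",
    "EffectLabel",
    "simulate_cohort",
    "assign_group",
    "categorize_thi",
    "categorize_hads",
    "categorize_effect",
    "hearing_level_band",
    "cohort_to_frame",
]

#: Standard octave audiometric test frequencies (Hz).
AUDIOGRAM_FREQS: tuple[float, ...] = (125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0)

GROUPS: tuple[str, ...] = ("placebo", "BBT", "TRT", "TEAE", "ADT", "control")
THERAPY_GROUPS: tuple[str, ...] = ("placebo", "BBT", "TRT", "TEAE", "ADT")

#: Completed-procedure group sizes of the study design.
DEFAULT_COMPLETED: dict[str, int] = {
    "placebo": 11, "BBT": 14, "TRT": 15, "TEAE": 15, "ADT": 8, "control": 8,
}
#: Recruited group sizes (before dropout).
DEFAULT_RECRUITED: dict[str, int] = {
    "placebo": 16, "BBT": 18, "TRT": 18, "TEAE": 18, "ADT": 19, "control": 14,
}

THI_CATEGORIES: tuple[str, ...] = ("light", "mild", "moderate", "severe", "catastrophic")
HADS_CATEGORIES: tuple[str, ...] = ("normal", "borderline", "abnormal")

SESSIONS: tuple[str, ...] = ("S0", "Sf")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Audiogram:
    """Per-ear hearing thresholds (dB HL) over standard octave frequencies."""

    left: dict[float, float]
    right: dict[float, float]

    def __post_init__(self) -> None:
        for ear, mapping in (("left", self.left), ("right", self.right)):
            if not mapping:
                raise ValueError(f"{ear} ear audiogram is empty")
            freqs = list(mapping)
            if any(f2 <= f1 for f1, f2 in zip(freqs, freqs[1:])):
                raise ValueError("audiogram frequencies must be strictly increasing")
            for f, thr in mapping.items():
                if not -10.0 <= thr <= 120.0:
                    raise ValueError(f"threshold {thr} dB HL at {f} Hz outside [-10, 120]")

    def _ear(self, ear: str) -> dict[float, float]:
        if ear not in ("left", "right"):
            raise ValueError("ear must be 'left' or 'right'")
        return self.left if ear == "left" else self.right

    def loss_at(self, freq: float, ear: str = "both") -> float:
        """Hearing loss interpolated at ``freq`` (linear in dB over log-frequency)."""
        if ear == "both":
            return 0.5 * (self.loss_at(freq, "left") + self.loss_at(freq, "right"))
        mapping = self._ear(ear)
        freqs = np.array(list(mapping), dtype=float)
        vals = np.array(list(mapping.values()), dtype=float)
        return float(np.interp(np.log2(freq), np.log2(freqs), vals))

    def pta(self, ear: str) -> float:
        """Pure-tone average over 0.5, 1, 2 and 4 kHz (the clinical summary)."""
        return float(np.mean([self.loss_at(f, ear) for f in (500.0, 1000.0, 2000.0, 4000.0)]))

    def worst_pta(self) -> float:
        return max(self.pta("left"), self.pta("right"))


def hearing_level_band(pta_db: float) -> str:
    """Map a pure-tone average to the five clinical hearing-level bands."""
    if pta_db <= 25.0:
        return "normal"
    if pta_db <= 40.0:
        return "slight"
    if pta_db <= 60.0:
        return "moderate"
    if pta_db <= 80.0:
        return "severe"
    return "profound"


@dataclass
class TinnitusProfile:
    """Perceived tinnitus: pitch (Hz), intensity (0-100 dB), laterality L/R/B."""

    pitch: float
    intensity: float
    laterality: str
    well_identified: bool = True

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("tinnitus pitch must be positive")
        if not 0.0 <= self.intensity <= 100.0:
            raise ValueError("tinnitus intensity must lie in [0, 100] dB")
        if self.laterality not in ("L", "R", "B"):
            raise ValueError("laterality must be one of 'L', 'R', 'B'")


@dataclass
class Participant:
    id: str
    condition: str  # "tinnitus" | "healthy"
    age: float
    sex: str  # "F" | "M"
    heart_rate: float
    audiogram: Audiogram
    tinnitus: TinnitusProfile | None = None
    group: str | None = None
    thi_score: dict[str, int] | None = None       # per session, tinnitus only
    hads_anxiety: dict[str, int] = field(default_factory=dict)
    hads_stress: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in ("tinnitus", "healthy"):
            raise ValueError("condition must be 'tinnitus' or 'healthy'")
        if self.condition == "healthy" and self.tinnitus is not None:
            raise ValueError("healthy participants carry no tinnitus profile")


@dataclass
class EffectLabel:
    """Direction of the questionnaire change between sessions S0 and Sf."""

    instrument: str  # "THI" | "HADS-A" | "HADS-S"
    label: str       # "positive" | "none" | "negative"


# ---------------------------------------------------------------------------
# questionnaire categorization
# ---------------------------------------------------------------------------

def categorize_thi(score: float) -> str:
    """Grade a THI total (0-100) into the five handicap categories.

    Uses the standard grade bounds 0-16 / 18-36 / 38-56 / 58-76 / 78-100,
    linearly extended so odd scores fall into the nearest lower grade.
    """
    if not 0 <= score <= 100:
        raise ValueError(f"THI score {score} outside [0, 100]")
    if score <= 16:
        return "light"
    if score <= 36:
        return "mild"
    if score <= 56:
        return "moderate"
    if score <= 76:
        return "severe"
    return "catastrophic"


def categorize_hads(score: float) -> str:
    """Grade a HADS subscale total (0-21): 0-7 normal, 8-10 borderline, 11-21 abnormal."""
    if not 0 <= score <= 21:
        raise ValueError(f"HADS score {score} outside [0, 21]")
    if score <= 7:
        return "normal"
    if score <= 10:
        return "borderline"
    return "abnormal"


def _category_rank(instrument: str, category: str) -> int:
    scale = THI_CATEGORIES if instrument == "THI" else HADS_CATEGORIES
    if category not in scale:
        raise ValueError(f"category {category!r} is not on the {instrument} scale")
    return scale.index(category)


def categorize_effect(instrument: str, cat_s0: str, cat_sf: str) -> EffectLabel:
    """Label the S0 -> Sf category change: lower = positive, equal = none, higher = negative."""
    if instrument not in ("THI", "HADS-A", "HADS-S"):
        raise ValueError(f"unknown instrument {instrument!r}")
    r0 = _category_rank(instrument, cat_s0)
    rf = _category_rank(instrument, cat_sf)
    label = "positive" if rf < r0 else "negative" if rf > r0 else "none"
    return EffectLabel(instrument=instrument, label=label)


# ---------------------------------------------------------------------------
# group assignment
# ---------------------------------------------------------------------------

#: pure-tone averages at or above this (dB HL) count as severe hearing loss
SEVERE_LOSS_DB = 61.0


def assign_group(p: Participant, rng: np.random.Generator) -> str:
    """Assign a participant to a treatment group by the clinical rules.

    Rule order (most specific first): control for healthy volunteers; BBT for
    tinnitus pitch < 1 kHz; TRT or ADT (random) for a well-identified pitch;
    placebo or TEAE (random) when hearing loss is not severe; TEAE otherwise.
    """
    if p.condition == "healthy":
        return "control"
    if p.tinnitus is None:
        raise MissingDataError(f"participant {p.id} has tinnitus but no profile")
    if p.tinnitus.pitch < 1000.0:
        return "BBT"
    if p.tinnitus.well_identified:
        return str(rng.choice(["TRT", "ADT"]))
    if p.audiogram.worst_pta() < SEVERE_LOSS_DB:
        return str(rng.choice(["placebo", "TEAE"]))
    return "TEAE"


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _simulate_audiogram(rng: np.random.Generator, age: float,
                        max_band: str | None = None) -> Audiogram:
    """Audiogram with age-steepened high-frequency slope.

    ``max_band`` caps the severity band (e.g. "moderate" for groups whose
    eligibility excludes severe loss).
    """
    band_p = {"normal": 0.40, "slight": 0.30, "moderate": 0.20, "severe": 0.10}
    bands = list(band_p)
    target_band = str(rng.choice(bands, p=list(band_p.values())))
    if max_band is not None and bands.index(target_band) > bands.index(max_band):
        target_band = max_band
    centers = {"normal": 12.0, "slight": 33.0, "moderate": 50.0, "severe": 70.0}
    target_pta = float(np.clip(centers[target_band] + rng.normal(0, 5), -5, 85))
    slope = float(rng.uniform(2, 10)) + 0.15 * max(age - 40.0, 0.0)  # dB/octave above 1 kHz

    def ear() -> dict[float, float]:
        base = target_pta + rng.normal(0, 3)
        thr = {}
        for f in AUDIOGRAM_FREQS:
            rise = slope * max(np.log2(f / 1000.0), 0.0)
            thr[f] = float(np.clip(base - 5 + rise + rng.normal(0, 3), -10, 120))
        return thr

    return Audiogram(left=ear(), right=ear())


def _simulate_scores(rng: np.random.Generator, healthy: bool) -> tuple[
        dict[str, int] | None, dict[str, int], dict[str, int]]:
    """Draw THI/HADS totals for both sessions; most participants change little."""

    def delta(scale_sd: float) -> float:
        u = rng.random()
        if u < 0.55:                       # no real change
            return rng.normal(0, scale_sd * 0.4)
        if u < 0.80:                       # improvement
            return -abs(rng.normal(scale_sd * 1.6, scale_sd * 0.6))
        return abs(rng.normal(scale_sd * 1.4, scale_sd * 0.6))

    if healthy:
        thi = None
    else:
        s0 = int(np.clip(2 * round(rng.normal(44, 18) / 2), 0, 100))
        sf = int(np.clip(2 * round((s0 + delta(8.0)) / 2), 0, 100))
        thi = {"S0": s0, "Sf": sf}

    def hads(mean: float) -> dict[str, int]:
        s0 = int(np.clip(round(rng.normal(mean, 4)), 0, 21))
        sf = int(np.clip(round(s0 + delta(2.0)), 0, 21))
        return {"S0": s0, "Sf": sf}

    return thi, hads(4.0 if healthy else 8.0), hads(4.0 if healthy else 7.0)


def _simulate_participant(rng: np.random.Generator, pid: str, group: str) -> Participant:
    age_bracket = rng.choice(["young", "adult", "elderly"], p=[0.05, 0.60, 0.35])
    age = {"young": rng.uniform(18, 28), "adult": rng.uniform(29, 60),
           "elderly": rng.uniform(61, 80)}[str(age_bracket)]
    sex = "F" if rng.random() < 0.53 else "M"
    heart_rate = float(np.clip(rng.normal(72, 8), 45, 120))

    healthy = group == "control"
    max_band = "moderate" if group in ("placebo",) else None
    audiogram = _simulate_audiogram(rng, age, max_band="normal" if healthy else max_band)

    tinnitus = None
    if not healthy:
        if group == "BBT":
            pitch = float(rng.uniform(200, 950))
            well = True
        elif group in ("TRT", "ADT"):
            pitch = float(np.exp(rng.uniform(np.log(1000), np.log(8000))))
            well = True
        else:  # placebo / TEAE: pitch poorly identified, above the BBT cut
            pitch = float(np.exp(rng.uniform(np.log(1000), np.log(8000))))
            well = False
        # intensity positively coupled to right-ear loss (known correlation signal)
        intensity = float(np.clip(15.0 + 0.6 * audiogram.pta("right") + rng.normal(0, 12),
                                  0, 100))
        laterality = str(rng.choice(["L", "R", "B"], p=[0.50, 0.32, 0.18]))
        tinnitus = TinnitusProfile(pitch=pitch, intensity=intensity,
                                   laterality=laterality, well_identified=well)

    thi, hads_a, hads_s = _simulate_scores(rng, healthy)
    return Participant(
        id=pid, condition="healthy" if healthy else "tinnitus", age=float(age),
        sex=sex, heart_rate=heart_rate, audiogram=audiogram, tinnitus=tinnitus,
        group=group, thi_score=thi, hads_anxiety=hads_a, hads_stress=hads_s,
    )


def simulate_cohort(n_per_group: dict[str, int] | None = None,
                    seed: int | None = None) -> list[Participant]:
    """Generate a deterministic (seeded) synthetic cohort.

    Parameters
    ----------
    n_per_group
        Completed-participant count per group; defaults to the study's
        11/14/15/15/8/8 design (71 in total).
    seed
        Seed for all randomness.
    """
    sizes = dict(DEFAULT_COMPLETED) if n_per_group is None else dict(n_per_group)
    unknown = set(sizes) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown groups: {sorted(unknown)}")
    for g, n in sizes.items():
        if n < 1:
            raise ValueError(f"group size for {g!r} must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    cohort: list[Participant] = []
    k = 0
    for g in GROUPS:
        for _ in range(sizes.get(g, 0)):
            k += 1
            cohort.append(_simulate_participant(rng, f"P{k:03d}", g))
    return cohort


def cohort_to_frame(cohort: list[Participant]):
    """Flatten a cohort to one row per participant-session (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for p in cohort:
        for s in SESSIONS:
            rows.append({
                "id": p.id, "session": s, "condition": p.condition, "group": p.group,
                "age": round(p.age, 1), "sex": p.sex, "heart_rate": round(p.heart_rate, 1),
                "hl_left": round(p.audiogram.pta("left"), 1),
                "hl_right": round(p.audiogram.pta("right"), 1),
                "tinnitus_pitch": None if p.tinnitus is None else round(p.tinnitus.pitch, 1),
                "tinnitus_intensity": None if p.tinnitus is None else round(p.tinnitus.intensity, 1),
                "laterality": None if p.tinnitus is None else p.tinnitus.laterality,
                "thi": None if p.thi_score is None else p.thi_score[s],
                "hads_anxiety": p.hads_anxiety[s],
                "hads_stress": p.hads_stress[s],
            })
    return pd.DataFrame(rows)
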