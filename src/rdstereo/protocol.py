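"""The examination flow: teaching, screening, and quantitative descent.

The quantitative test starts coarse (800 arcsec) and descends through
progressively finer disparity levels.  At each level up to five figures
from the ten-figure bank are presented in seeded random order without
replacement; naming *any* one correctly passes the level immediately and
the examination moves one level down.  The descent stops at the first
level where all five figures are missed (or after the finest level), and
the lowest passed level is recorded as the stereoacuity.  A subject who
fails the coarsest level gets no stereoacuity value and is routed to the
screening graph; failing to recognise any of its three coarse concentric
figures flags suspected stereoblindness for referral.

Responders are any objects implementing ``respond(shape_id,
disparity_arcsec, options) -> str | None`` — an interactive prompt, or a
simulated observer from :mod:`rdstereo.observer`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .rds import DEFAULT_BANK_SHAPES, SCREENING_SHAPES

__all__ = [
    "LevelSchedule",
    "TrialRecord",
    "SessionResult",
    "Responder",
    "run_screening",
    "run_quantitative",
    "session_transcript",
    "parse_transcript",
]


class Responder(Protocol):
    def respond(
        self, shape_id: str, disparity_arcsec: float, options: Sequence[str]
    ) -> str | None: ...


@dataclass(frozen=True)
class LevelSchedule:
    """Disparity levels and the per-level trial budget.

    Quantitative levels run coarse-to-fine (strictly decreasing);
    screening levels coarse-to-coarser (strictly increasing).
    """

    quantitative_levels: tuple[float, ...] = (800.0, 400.0, 200.0, 100.0, 60.0, 40.0)
    screening_levels: tuple[float, ...] = (800.0, 1600.0, 2400.0)
    max_trials_per_level: int = 5

    def __post_init__(self) -> None:
        if not self.quantitative_levels:
            raise ValueError("quantitative_levels must be non-empty")
        if any(
            a <= b for a, b in zip(self.quantitative_levels, self.quantitative_levels[1:])
        ):
            raise ValueError(
                f"quantitative levels must strictly decrease: {self.quantitative_levels}"
            )
        if any(a >= b for a, b in zip(self.screening_levels, self.screening_levels[1:])):
            raise ValueError(
                f"screening levels must strictly increase: {self.screening_levels}"
            )
        if self.max_trials_per_level < 1:
            raise ValueError("max_trials_per_level must be >= 1")


@dataclass(frozen=True)
class TrialRecord:
    index: int
    level_arcsec: float
    presented: str
    response: str | None
    correct: bool

    def __post_init__(self) -> None:
        if self.correct != (self.response == self.presented):
            raise ValueError("correct flag inconsistent with presented/response")


@dataclass(frozen=True)
class SessionResult:
    """Outcome of one examination.

    ``stereoacuity_arcsec`` is the lowest level passed, or None when the
    coarsest level was failed (then ``referral_recommended`` is set and
    screening should follow).
    """

    trials: tuple[TrialRecord, ...]
    stereoacuity_arcsec: float | None
    screening_flag: str = "not_run"  # passed | stereoblind_suspect | not_run
    referral_recommended: bool = False

    def __post_init__(self) -> None:
        if self.screening_flag not in ("passed", "stereoblind_suspect", "not_run"):
            raise ValueError(f"bad screening_flag {self.screening_flag!r}")


def run_screening(
    responder: Responder,
    schedule: LevelSchedule = LevelSchedule(),
    seed: int = 0,
) -> tuple[str, tuple[TrialRecord, ...]]:
    """Present the three concentric screening figures.

    The flag is ``stereoblind_suspect`` only when *none* of the three is
    recognised; recognising any single one passes.  A responder that
    returns no answer is scored incorrect, not an error.
    """
    trials = []
    n_correct = 0
    for i, (shape_id, level) in enumerate(
        zip(SCREENING_SHAPES, schedule.screening_levels), start=1
    ):
        answer = responder.respond(shape_id, level, SCREENING_SHAPES)
        correct = answer == shape_id
        n_correct += correct
        trials.append(
            TrialRecord(
                index=i, level_arcsec=level, presented=shape_id, response=answer, correct=correct
            )
        )
    flag = "passed" if n_correct > 0 else "stereoblind_suspect"
    return flag, tuple(trials)


def run_quantitative(
    responder: Responder,
    schedule: LevelSchedule = LevelSchedule(),
    seed: int = 0,
    bank_shapes: Sequence[str] = DEFAULT_BANK_SHAPES,
) -> SessionResult:
    """Run the level-descent test and record the stereoacuity.

    Figures are sampled without replacement within a level, so no figure
    repeats among that level's (up to) five presentations.
    """
    if len(bank_shapes) < schedule.max_trials_per_level:
        raise ValueError(
            f"bank of {len(bank_shapes)} shapes cannot fill "
            f"{schedule.max_trials_per_level} distinct trials per level"
        )
    rng = np.random.default_rng(seed)
    options = tuple(bank_shapes)
    trials: list[TrialRecord] = []
    lowest_passed: float | None = None
    idx = 0
    for level in schedule.quantitative_levels:
        order = rng.permutation(len(options))[: schedule.max_trials_per_level]
        passed = False
        for j in order:
            shape_id = options[j]
            idx += 1
            answer = responder.respond(shape_id, level, options)
            correct = answer == shape_id
            trials.append(
                TrialRecord(
                    index=idx,
                    level_arcsec=level,
                    presented=shape_id,
                    response=answer,
                    correct=correct,
                )
            )
            if correct:
                passed = True
                break  # a level is passed on the first correct response
        if not passed:
            break
        lowest_passed = level
    return SessionResult(
        trials=tuple(trials),
        stereoacuity_arcsec=lowest_passed,
        screening_flag="not_run",
        referral_recommended=lowest_passed is None,
    )


# ---------------------------------------------------------------------------
# transcripts

_HEADER = "=== Random-dot distance stereotest transcript ==="
_SUBJECT_FIELDS = ("name", "age", "examination_date", "visual_acuity")


def session_transcript(result: SessionResult, subject: dict | None = None) -> str:
    """Human-readable (and machine-parseable) record of a session."""
    subject = subject or {}
    lines = [_HEADER]
    for key in _SUBJECT_FIELDS:
        lines.append(f"{key}: {subject.get(key, '-')}")
    lines.append(f"screening_flag: {result.screening_flag}")
    lines.append(f"referral_recommended: {'yes' if result.referral_recommended else 'no'}")
    if not result.trials:
        lines.append("(no trials)")
    for t in result.trials:
        lines.append(
            f"trial {t.index:03d} | level_arcsec={t.level_arcsec:g} | "
            f"presented={t.presented} | response={t.response if t.response is not None else 'none'} | "
            f"correct={'yes' if t.correct else 'no'}"
        )
    acuity = "none" if result.stereoacuity_arcsec is None else f"{result.stereoacuity_arcsec:g}"
    lines.append(f"stereoacuity_arcsec: {acuity}")
    return "\n".join(lines) + "\n"


def parse_transcript(text: str) -> SessionResult:
    """Rebuild a :class:`SessionResult` from its transcript text."""
    trials = []
    screening_flag = "not_run"
    referral = False
    acuity: float | None = None
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("screening_flag:"):
            screening_flag = line.split(":", 1)[1].strip()
        elif line.startswith("referral_recommended:"):
            referral = line.split(":", 1)[1].strip() == "yes"
        elif line.startswith("trial "):
            head, *fields = [p.strip() for p in line.split("|")]
            idx = int(head.split()[1])
            kv = dict(f.split("=", 1) for f in fields)
            response = None if kv["response"] == "none" else kv["response"]
            trials.append(
                TrialRecord(
                    index=idx,
                    level_arcsec=float(kv["level_arcsec"]),
                    presented=kv["presented"],
                    response=response,
                    correct=kv["correct"] == "yes",
                )
            )
        elif line.startswith("stereoacuity_arcsec:"):
            value = line.split(":", 1)[1].strip()
            acuity = None if value == "none" else float(value)
    return SessionResult(
        trials=tuple(trials),
        stereoacuity_arcsec=acuity,
        screening_flag=screening_flag,
        referral_recommended=referral,
    )
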