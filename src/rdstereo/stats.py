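"""Agreement statistics between paired stereoacuity instruments.

Clinical stereoacuity comparisons are run on a three-band ordinal scale
rather than raw arcsec values: *fine* (20–60 arcsec for near tests,
40–60 for distance tests), *moderate* (100–200) and *coarse* (>= 400),
coded 1 < 2 < 3.  Two instruments measured on the same subjects are
compared by cross-tabulating the grades, by simple concordance (the
fraction of subjects graded identically), and by the Wilcoxon
matched-pairs signed-rank test in the tie-corrected normal approximation
that SPSS-style packages report:

    Z = (min(W+, W-) - n(n+1)/4) / sqrt(Var),
    Var = n(n+1)(2n+1)/24 - sum(t^3 - t)/48,

with zero differences dropped before ranking, average ranks over ties,
no continuity correction, and the sign of Z following the dominant
difference direction (Z = 0, p = 1 when every pair is tied).  On ordinal
grades ties are the norm, so the tie correction is not a refinement but
the difference between a right and a wrong answer.

A 13-record reference dataset of 12 adult subjects measured with four
instruments (two near tests at 0.4 m: Randot circles and Yan's charts;
two distance tests: the Distance Randot at 3 m and an autostereoscopic
random-dot test at 5 m) ships as a fixture; one subject appears twice,
before and after refractive correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "FINE",
    "MODERATE",
    "COARSE",
    "GRADE_NAMES",
    "GradeScheme",
    "NEAR_SCHEME",
    "DISTANCE_SCHEME",
    "GradeRangeError",
    "GradedPair",
    "CrossTab",
    "WilcoxonResult",
    "grade",
    "crosstab",
    "wilcoxon_signed_rank",
    "wilcoxon_matched_pairs",
    "concordance",
    "load_table3",
    "table3_pairs",
    "fine_counts",
]

FINE, MODERATE, COARSE = 1, 2, 3
GRADE_NAMES = {FINE: "fine", MODERATE: "moderate", COARSE: "coarse"}


class GradeRangeError(ValueError):
    """A stereoacuity below the scheme's fine-band floor."""


@dataclass(frozen=True)
class GradeScheme:
    """Banding of arcsec values into ordinal grades.

    The near and distance schemes differ only in the fine band's floor
    (20 vs 40 arcsec — the finest level the respective instruments
    offer); the fine/moderate and moderate/coarse cuts are common.
    """

    name: str
    fine_floor: float
    fine_ceiling: float = 60.0
    moderate_ceiling: float = 200.0

    def __post_init__(self) -> None:
        if not 0 < self.fine_floor <= self.fine_ceiling < self.moderate_ceiling:
            raise ValueError(f"grade bands out of order in scheme {self.name!r}")


NEAR_SCHEME = GradeScheme("near", fine_floor=20.0)
DISTANCE_SCHEME = GradeScheme("distance", fine_floor=40.0)


def grade(arcsec: float, scheme: GradeScheme) -> int:
    """Map a stereoacuity to its ordinal grade (1=fine < 2 < 3=coarse)."""
    if arcsec <= 0:
        raise ValueError(f"stereoacuity must be positive, got {arcsec}")
    if arcsec < scheme.fine_floor:
        raise GradeRangeError(
            f"{arcsec} arcsec is below the {scheme.name} scheme's fine floor "
            f"({scheme.fine_floor} arcsec)"
        )
    if arcsec <= scheme.fine_ceiling:
        return FINE
    if arcsec <= scheme.moderate_ceiling:
        return MODERATE
    return COARSE


@dataclass(frozen=True)
class GradedPair:
    """One subject's grades on two instruments (A, B)."""

    subject: str
    grade_a: int
    grade_b: int

    def __post_init__(self) -> None:
        for g in (self.grade_a, self.grade_b):
            if g not in (FINE, MODERATE, COARSE):
                raise ValueError(f"grades must be 1, 2 or 3, got {g}")


@dataclass(frozen=True)
class CrossTab:
    """3x3 contingency table of A-grades (rows) vs B-grades (columns)."""

    counts: tuple[tuple[int, int, int], ...]
    label_a: str = "A"
    label_b: str = "B"

    @property
    def total(self) -> int:
        return sum(sum(row) for row in self.counts)

    @property
    def trace(self) -> int:
        return sum(self.counts[i][i] for i in range(3))

    def __str__(self) -> str:
        head = f"{self.label_a} \\ {self.label_b:>9}" + "".join(
            f"{GRADE_NAMES[g]:>10}" for g in (FINE, MODERATE, COARSE)
        )
        rows = [head]
        for g, row in zip((FINE, MODERATE, COARSE), self.counts):
            rows.append(f"{GRADE_NAMES[g]:<12}" + "".join(f"{c:>10d}" for c in row))
        return "\n".join(rows)


def crosstab(pairs: Sequence[GradedPair], label_a: str = "A", label_b: str = "B") -> CrossTab:
    if not pairs:
        raise ValueError("crosstab needs at least one pair")
    counts = [[0, 0, 0], [0, 0, 0], [0, 0, 0]]
    for p in pairs:
        counts[p.grade_a - 1][p.grade_b - 1] += 1
    return CrossTab(tuple(tuple(row) for row in counts), label_a, label_b)


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank statistic with its tie-corrected normal approximation.

    ``w_plus``/``w_minus`` are the rank sums of positive/negative
    differences (B - A); ``tie_sizes`` the sizes of tied groups of
    absolute differences among the non-zero pairs.
    """

    n_nonzero: int
    w_plus: float
    w_minus: float
    tie_sizes: tuple[int, ...]
    variance: float
    z: float
    p_value: float


def wilcoxon_signed_rank(differences: Sequence[float]) -> WilcoxonResult:
    """Tie-corrected signed-rank test on paired differences (B - A).

    Zero differences are excluded before ranking; absolute differences
    receive average ranks; the variance carries the tie correction and
    no continuity correction is applied.  With no non-zero differences
    the degenerate convention Z = 0, p = 1 is returned.  Works on any
    ordinal coding, not just the three clinical grades.
    """
    diffs = np.asarray(differences, dtype=float)
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        return WilcoxonResult(0, 0.0, 0.0, (), 0.0, 0.0, 1.0)
    ranks = rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    _, tie_counts = np.unique(np.abs(diffs), return_counts=True)
    tie_sizes = tuple(int(t) for t in tie_counts)
    variance = n * (n + 1) * (2 * n + 1) / 24.0 - sum(t**3 - t for t in tie_sizes) / 48.0
    mean = n * (n + 1) / 4.0
    z_mag = (mean - min(w_plus, w_minus)) / np.sqrt(variance) if variance > 0 else 0.0
    z = float(np.sign(w_plus - w_minus) * z_mag)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(int(n), w_plus, w_minus, tie_sizes, float(variance), z, p)


def wilcoxon_matched_pairs(pairs: Sequence[GradedPair]) -> WilcoxonResult:
    """The signed-rank test on a paired-grades dataset (B vs A)."""
    if not pairs:
        raise ValueError("wilcoxon_matched_pairs needs at least one pair")
    return wilcoxon_signed_rank([p.grade_b - p.grade_a for p in pairs])


def concordance(pairs: Sequence[GradedPair]) -> tuple[float, int, int]:
    """(proportion, agreeing, total) of identically graded pairs."""
    if not pairs:
        raise ValueError("concordance needs at least one pair")
    agree = sum(p.grade_a == p.grade_b for p in pairs)
    return agree / len(pairs), agree, len(pairs)


# ---------------------------------------------------------------------------
# reference dataset

_INSTRUMENTS = {
    "randot": NEAR_SCHEME,
    "yans": NEAR_SCHEME,
    "distance_randot": DISTANCE_SCHEME,
    "gfdrdss": DISTANCE_SCHEME,
}

_PAIRINGS = {
    "near": ("randot", "yans"),
    "distance": ("distance_randot", "gfdrdss"),
}


def load_table3() -> pd.DataFrame:
    """The bundled 13-record, 12-subject reference dataset.

    Columns: subject, condition (habitual / uncorrected / corrected),
    va_od, va_os (logMAR visual acuity), and arcsec stereoacuities for
    the four instruments (randot, yans, distance_randot, gfdrdss).
    """
    with resources.files("rdstereo").joinpath("data/table3.csv").open() as fh:
        return pd.read_csv(fh)


def table3_pairs(pairing: str = "distance") -> list[GradedPair]:
    """All 13 record pairs for a pairing ('near' or 'distance'), graded."""
    if pairing not in _PAIRINGS:
        raise ValueError(f"pairing must be one of {sorted(_PAIRINGS)}, got {pairing!r}")
    col_a, col_b = _PAIRINGS[pairing]
    df = load_table3()
    return [
        GradedPair(
            subject=f"{row.subject}/{row.condition}",
            grade_a=grade(getattr(row, col_a), _INSTRUMENTS[col_a]),
            grade_b=grade(getattr(row, col_b), _INSTRUMENTS[col_b]),
        )
        for row in df.itertuples()
    ]


def fine_counts() -> dict[str, int]:
    """Per-subject counts of fine grades (subject 7 at corrected result).

    Returns the number of the 12 subjects grading fine on each distance
    instrument, and the number fine on *both* near instruments.
    """
    df = load_table3()
    best = df[df.condition != "uncorrected"]
    out = {
        "gfdrdss_fine": int(
            sum(grade(v, DISTANCE_SCHEME) == FINE for v in best.gfdrdss)
        ),
        "distance_randot_fine": int(
            sum(grade(v, DISTANCE_SCHEME) == FINE for v in best.distance_randot)
        ),
        "near_fine_both": int(
            sum(
                grade(r, NEAR_SCHEME) == FINE and grade(y, NEAR_SCHEME) == FINE
                for r, y in zip(best.randot, best.yans)
            )
        ),
        "n_subjects": int(best.subject.nunique()),
    }
    return out
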