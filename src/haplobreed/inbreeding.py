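"""Four-state sib-mating cross-type chain for haplodiploids.

In a haplodiploid line propagated by brother-sister mating, a mated female
can be classified at any single locus into one of four cross types by her
zygosity and the allele carried by her (haploid) mate:

* ``A`` — heterozygous female, male shares no allele ([xy] x [z])
* ``B`` — heterozygous female, male shares one allele ([xy] x [x])
* ``C`` — homozygous female, male carries a different allele ([xx] x [y])
* ``D`` — homozygous female, male carries the same allele ([xx] x [x])

Type D is absorbing: once a line is fully homozygous at the locus it stays
so. One generation of random sib-mating maps the cross-type frequencies
``(A, B, C, D)`` linearly:

    A' = A/2,  B' = A/2 + B/2 + C,  C' = B/4,  D' = B/4 + D

The inbreeding coefficient is ``f = C + D`` (probability the female's two
alleles are identical by descent) and ``D`` itself is the probability the
line is fully inbred at the locus. Because every update is a halving or
quartering, the chain is computed in exact dyadic-rational arithmetic by
default (:class:`fractions.Fraction`), with an optional floating mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Literal, Union

import pandas as pd

__all__ = [
    "CrossTypeDistribution",
    "InbreedingPoint",
    "Trajectory",
    "step_cross_types",
    "inbreeding_from_distribution",
    "iterate_trajectory",
    "direct_f_recurrence",
    "generations_to_threshold",
    "UnreachableThresholdError",
]

Number = Union[int, float, Fraction]
Mode = Literal["exact-rational", "floating"]

_FLOAT_TOL = 1e-12


def _coerce(value: Number, mode: Mode) -> Number:
    if mode == "exact-rational":
        if isinstance(value, float):
            return Fraction(value)
        return Fraction(value)
    return float(value)


@dataclass(frozen=True)
class CrossTypeDistribution:
    """Frequencies of the four sib-mating cross types at one generation.

    Frequencies are probabilities summing to one; in exact mode they are
    :class:`~fractions.Fraction` instances (dyadic when started from a pure
    state). ``generation`` counts completed sib-mating generations, with
    generation 0 the founding cross.
    """

    generation: int
    freq_A: Number
    freq_B: Number
    freq_C: Number
    freq_D: Number

    def __post_init__(self) -> None:
        if self.generation < 0 or int(self.generation) != self.generation:
            raise ValueError(f"generation must be a non-negative integer, got {self.generation}")
        freqs = self.frequencies
        if any(f < 0 for f in freqs):
            raise ValueError(f"cross-type frequencies must be non-negative, got {freqs}")
        total = sum(freqs)
        if self.is_exact:
            if total != 1:
                raise ValueError(f"cross-type frequencies must sum to 1 exactly, got {total}")
        elif abs(total - 1.0) > _FLOAT_TOL:
            raise ValueError(f"cross-type frequencies must sum to 1 within {_FLOAT_TOL}, got {total}")

    @property
    def frequencies(self) -> tuple[Number, Number, Number, Number]:
        return (self.freq_A, self.freq_B, self.freq_C, self.freq_D)

    @property
    def is_exact(self) -> bool:
        return all(isinstance(f, Rational) for f in self.frequencies)

    @classmethod
    def pure(cls, cross_type: str, generation: int = 0, mode: Mode = "exact-rational") -> "CrossTypeDistribution":
        """Distribution concentrated on a single cross type (e.g. ``A_0 = 1``)."""
        cross_type = cross_type.upper()
        if cross_type not in "ABCD" or len(cross_type) != 1:
            raise ValueError(f"cross type must be one of A, B, C, D, got {cross_type!r}")
        one, zero = _coerce(1, mode), _coerce(0, mode)
        freqs = {c: (one if c == cross_type else zero) for c in "ABCD"}
        return cls(generation, freqs["A"], freqs["B"], freqs["C"], freqs["D"])

    def as_mode(self, mode: Mode) -> "CrossTypeDistribution":
        return CrossTypeDistribution(
            self.generation, *(_coerce(f, mode) for f in self.frequencies)
        )


@dataclass(frozen=True)
class InbreedingPoint:
    """Inbreeding summary at one generation: ``f = C + D`` and ``D`` itself."""

    generation: int
    f: Number
    p_fully_inbred: Number

    def __post_init__(self) -> None:
        if not (0 <= self.p_fully_inbred <= self.f <= 1):
            raise ValueError(
                f"require 0 <= p_fully_inbred <= f <= 1, got f={self.f}, "
                f"p_fully_inbred={self.p_fully_inbred}"
            )


@dataclass
class Trajectory:
    """Generation-indexed inbreeding series from generation 0 to a horizon."""

    points: list[InbreedingPoint]
    distributions: list[CrossTypeDistribution] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        gens = [p.generation for p in self.points]
        if gens != list(range(len(gens))):
            raise ValueError("trajectory generations must be 0, 1, 2, ... without gaps")

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, generation: int) -> InbreedingPoint:
        return self.points[generation]

    def to_frame(self) -> pd.DataFrame:
        """Tabular form with cross-type frequencies (if kept), f, and D."""
        rows = []
        for i, p in enumerate(self.points):
            row: dict[str, object] = {"generation": p.generation}
            if self.distributions:
                d = self.distributions[i]
                row.update(
                    freq_A=float(d.freq_A), freq_B=float(d.freq_B),
                    freq_C=float(d.freq_C), freq_D=float(d.freq_D),
                )
            row.update(f=float(p.f), p_fully_inbred=float(p.p_fully_inbred))
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_report(self) -> dict:
        return {
            "provenance": self.provenance,
            "points": [
                {
                    "generation": p.generation,
                    "f": float(p.f),
                    "p_fully_inbred": float(p.p_fully_inbred),
                }
                for p in self.points
            ],
        }


def step_cross_types(dist: CrossTypeDistribution) -> CrossTypeDistribution:
    """Advance the cross-type distribution by one sib-mating generation.

    Applies A' = A/2, B' = A/2 + B/2 + C, C' = B/4, D' = B/4 + D. Exactness
    of the input (Fraction vs float) is preserved.
    """
    a, b, c, d = dist.frequencies
    two = _coerce(2, "exact-rational") if dist.is_exact else 2.0
    four = two * 2
    return CrossTypeDistribution(
        generation=dist.generation + 1,
        freq_A=a / two,
        freq_B=a / two + b / two + c,
        freq_C=b / four,
        freq_D=b / four + d,
    )


def inbreeding_from_distribution(dist: CrossTypeDistribution) -> InbreedingPoint:
    """Inbreeding coefficient f = C + D and full-inbreeding probability D."""
    return InbreedingPoint(
        generation=dist.generation,
        f=dist.freq_C + dist.freq_D,
        p_fully_inbred=dist.freq_D,
    )


def iterate_trajectory(
    initial: CrossTypeDistribution,
    generations: int,
    mode: Mode = "exact-rational",
) -> Trajectory:
    """Iterate the chain for ``generations`` steps from ``initial``.

    Returns a trajectory of ``generations + 1`` points (generation 0 is the
    initial state). From the most-heterozygotic start ``A_0 = 1`` the point
    at generation 15 has f = 0.951263427734375 (95.1%) and
    p_fully_inbred = 0.93621826171875 (93.6%).
    """
    if generations < 1:
        raise ValueError(f"generations must be >= 1, got {generations}")
    dist = initial.as_mode(mode)
    distributions = [dist]
    for _ in range(generations):
        dist = step_cross_types(dist)
        distributions.append(dist)
    points = [inbreeding_from_distribution(d) for d in distributions]
    provenance = (
        f"initial=(A={initial.freq_A}, B={initial.freq_B}, C={initial.freq_C}, "
        f"D={initial.freq_D}) at generation {initial.generation}; mode={mode}"
    )
    return Trajectory(points=points, distributions=distributions, provenance=provenance)


def direct_f_recurrence(horizon: int, mode: Mode = "exact-rational") -> list[Number]:
    """Inbreeding coefficients f_3 .. f_horizon by the direct recurrence.

    For full sib-mating in haplodiploids, f_t = 1/4 + (1/4) f_{t-2} +
    (1/2) f_{t-1} with f_1 = f_2 = 0: with probability 1/2 both of a
    female's alleles descend from her grandmother (identical copies with
    probability 1/2 of that), otherwise one comes from the grandmother and
    one from the grandfather.

    Note the index convention: with these initial conditions the value at
    index t + 1 equals the cross-type chain's f at generation t (the chain
    indexing, generation 0 = founding cross, is canonical in this package).
    """
    if horizon < 3:
        raise ValueError(f"horizon must be >= 3, got {horizon}")
    quarter = _coerce(1, mode) / 4
    half = _coerce(1, mode) / 2
    f_prev2, f_prev1 = _coerce(0, mode), _coerce(0, mode)  # f_1, f_2
    out: list[Number] = []
    for _ in range(3, horizon + 1):
        f_t = quarter + quarter * f_prev2 + half * f_prev1
        out.append(f_t)
        f_prev2, f_prev1 = f_prev1, f_t
    return out


class UnreachableThresholdError(ValueError):
    """Raised when the requested statistic can never reach the threshold."""


def generations_to_threshold(
    threshold: Number,
    statistic: Literal["f", "p_fully_inbred"],
    initial: CrossTypeDistribution,
    mode: Mode = "exact-rational",
) -> int:
    """Smallest generation at which ``f`` or ``D`` reaches ``threshold``.

    Both statistics converge to 1 but never attain it in finite time from
    any state with mass outside D, so thresholds >= 1 raise
    :class:`UnreachableThresholdError` instead of looping forever.
    """
    if statistic not in ("f", "p_fully_inbred"):
        raise ValueError(f"statistic must be 'f' or 'p_fully_inbred', got {statistic!r}")
    if not 0 <= threshold:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if threshold >= 1:
        dist0 = initial.as_mode(mode)
        # from a pure-D state the statistic is already 1
        if not (dist0.freq_D == 1 or (statistic == "f" and dist0.freq_C + dist0.freq_D == 1)):
            raise UnreachableThresholdError(
                f"{statistic} approaches 1 asymptotically and never reaches {threshold}"
            )
    dist = initial.as_mode(mode)
    generation = dist.generation
    while True:
        point = inbreeding_from_distribution(dist)
        value = point.f if statistic == "f" else point.p_fully_inbred
        if value >= threshold:
            return generation
        dist = step_cross_types(dist)
        generation += 1
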