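"""Controlled interpopulation crossing designs for haplodiploids.

Building an outbred laboratory population from several field populations
requires every founder population to contribute equally to both the
nuclear and the mitochondrial gene pool. In haplodiploids this is harder
than in diploids: males develop from unfertilized eggs, so a hybrid male
can only be obtained one generation later, from a virgin hybrid female.

Two designs are supported, the only ones this toolkit schedules:

* **matched-pairs-4** — four populations (A–D) split into two fixed pairs;
  each pair is crossed reciprocally (A♀×B♂ and B♀×A♂; C♀×D♂ and D♀×C♂),
  and the resulting F1 hybrid females are crossed reciprocally across
  pairs with hybrid males, giving 8 fully hybrid combinations
  (ABCD, ABDC, BACD, BADC, CDAB, CDBA, DCAB, DCBA);
* **round-robin-3** — three populations (e.g. E–G) crossed reciprocally in
  all pairs; each F1 hybrid female is then mated to males from the
  population absent from her parental cross, giving 6 combinations.

Combination labels record the maternal lineage left-to-right: in ABCD the
F2 female's mother is an AB hybrid (her mother's mother from population A,
which is therefore the mitochondrial origin) and her father is a hybrid
male from a CD virgin female. Both designs give every founder population
the mitochondrial origin of exactly two combinations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

__all__ = [
    "FounderPopulation",
    "CrossingDesign",
    "HybridCombination",
    "CrossSpec",
    "HusbandryStep",
    "ScheduleBlock",
    "CrossSchedule",
    "FoundingCensus",
    "enumerate_combinations",
    "build_schedule",
    "founding_census",
    "mito_representation",
]

DesignKind = Literal["matched-pairs-4", "round-robin-3"]


@dataclass(frozen=True)
class FounderPopulation:
    """A field-collected founder population, identified by a letter label."""

    label: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.label) != 1 or not self.label.isalpha() or not self.label.isupper():
            raise ValueError(f"population label must be a single uppercase letter, got {self.label!r}")


@dataclass(frozen=True)
class CrossingDesign:
    """A crossing design: its kind, ordered founder populations, cross count."""

    kind: DesignKind
    populations: tuple[FounderPopulation, ...]
    crosses_per_type: int = 200

    def __post_init__(self) -> None:
        expected = {"matched-pairs-4": 4, "round-robin-3": 3}
        if self.kind not in expected:
            raise ValueError(
                f"unsupported design kind {self.kind!r}; supported: {sorted(expected)} "
                "(other population counts are deliberately not generalized)"
            )
        if len(self.populations) != expected[self.kind]:
            raise ValueError(
                f"{self.kind} requires exactly {expected[self.kind]} populations, "
                f"got {len(self.populations)}"
            )
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError(f"population labels must be unique, got {labels}")
        if self.crosses_per_type < 1:
            raise ValueError(f"crosses_per_type must be >= 1, got {self.crosses_per_type}")

    @classmethod
    def from_labels(
        cls, kind: DesignKind, labels: Sequence[str], crosses_per_type: int = 200
    ) -> "CrossingDesign":
        return cls(kind, tuple(FounderPopulation(l) for l in labels), crosses_per_type)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.populations)


@dataclass(frozen=True)
class HybridCombination:
    """Maternal-lineage label order of one fully hybrid genotype class."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"each founder label must appear exactly once, got {self.labels}")

    @property
    def name(self) -> str:
        return "".join(self.labels)

    @property
    def mito_origin(self) -> str:
        """Founder population contributing the mitochondrion (first label)."""
        return self.labels[0]

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class CrossSpec:
    """One cross type within a schedule block: mother class x father class."""

    mother_label: str
    father_label: str
    count: int

    def __str__(self) -> str:
        return f"{self.mother_label}♀ x {self.father_label}♂ ({self.count})"


@dataclass(frozen=True)
class HusbandryStep:
    """A non-cross action: virgin-female isolation (male production) or pooling."""

    action: Literal["isolate-virgins", "pool"]
    target_label: str
    note: str = ""


@dataclass(frozen=True)
class ScheduleBlock:
    """All crosses and husbandry steps of one generation of the protocol."""

    index: int
    crosses: tuple[CrossSpec, ...] = ()
    husbandry: tuple[HusbandryStep, ...] = ()


@dataclass(frozen=True)
class CrossSchedule:
    """Ordered generation blocks realizing a crossing design.

    Two provenance rules hold by construction and are re-checked by
    :meth:`validate`: every male class used in a cross at block g was
    produced by a virgin-isolation step at block g-1, and every hybrid
    female class used at block g was produced by a cross at block g-1
    (founder-population females come from stock and are exempt).
    """

    design: CrossingDesign
    blocks: tuple[ScheduleBlock, ...]

    def validate(self) -> None:
        founder_labels = set(self.design.labels)
        for prev, block in zip((None, *self.blocks), self.blocks):
            males_available = (
                {h.target_label for h in prev.husbandry if h.action == "isolate-virgins"}
                if prev is not None
                else set()
            )
            females_available = (
                {_cross_daughter_label(c) for c in prev.crosses}
                if prev is not None
                else set()
            )
            for cross in block.crosses:
                if cross.father_label not in males_available:
                    raise ValueError(
                        f"block {block.index}: males of class {cross.father_label} were not "
                        f"produced by virgin isolation at block {block.index - 1}"
                    )
                if cross.mother_label not in founder_labels and (
                    cross.mother_label not in females_available
                ):
                    raise ValueError(
                        f"block {block.index}: hybrid females of class {cross.mother_label} "
                        f"were not produced by a cross at block {block.index - 1}"
                    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for block in self.blocks:
            for cross in block.crosses:
                rows.append(
                    {
                        "block": block.index,
                        "step": "cross",
                        "mother_label": cross.mother_label,
                        "father_label": cross.father_label,
                        "count": cross.count,
                        "husbandry_note": ".",
                    }
                )
            for step in block.husbandry:
                rows.append(
                    {
                        "block": block.index,
                        "step": step.action,
                        "mother_label": step.target_label,
                        "father_label": ".",
                        "count": 0,
                        "husbandry_note": step.note or ".",
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_report(self) -> dict:
        return {
            "kind": self.design.kind,
            "populations": list(self.design.labels),
            "crosses_per_type": self.design.crosses_per_type,
            "blocks": [
                {
                    "index": b.index,
                    "crosses": [
                        {
                            "mother": c.mother_label,
                            "father": c.father_label,
                            "count": c.count,
                        }
                        for c in b.crosses
                    ],
                    "husbandry": [
                        {"action": h.action, "target": h.target_label, "note": h.note}
                        for h in b.husbandry
                    ],
                }
                for b in self.blocks
            ],
        }


def _cross_daughter_label(cross: CrossSpec) -> str:
    """Genotype class of the daughters of a cross: maternal labels first."""
    return cross.mother_label + cross.father_label


def enumerate_combinations(design: CrossingDesign) -> list[HybridCombination]:
    """Enumerate the fully hybrid combinations a design produces.

    matched-pairs-4 over (A, B, C, D) yields the 8 combinations ABCD, ABDC,
    BACD, BADC, CDAB, CDBA, DCAB, DCBA; round-robin-3 over (E, F, G) yields
    EFG, FEG, EGF, GEF, FGE, GFE. In either design each founder label is
    the mitochondrial origin of exactly two combinations.
    """
    labels = design.labels
    combos: list[HybridCombination] = []
    if design.kind == "matched-pairs-4":
        a, b, c, d = labels
        pair1 = [a + b, b + a]
        pair2 = [c + d, d + c]
        for mothers, fathers in ((pair1, pair2), (pair2, pair1)):
            for mother in mothers:
                for father in fathers:
                    combos.append(HybridCombination(tuple(mother + father)))
    else:  # round-robin-3
        for i, mother_a in enumerate(labels):
            for j, mother_b in enumerate(labels):
                if i == j:
                    continue
                (third,) = set(labels) - {mother_a, mother_b}
                combos.append(HybridCombination((mother_a, mother_b, third)))
        combos.sort(key=lambda c: (labels.index(c.labels[0]), labels.index(c.labels[1])))
    return combos


def build_schedule(design: CrossingDesign) -> CrossSchedule:
    """Lay out the generation-by-generation schedule realizing a design.

    Because hybrid males only exist one generation after the cross that
    made their (virgin) mothers, each cross set is repeated one generation
    later so that hybrid females and hybrid males of the same class are
    adult simultaneously. The schedule materializes those repeats as
    explicit blocks; the terminal block pools all combinations into the
    founding population.
    """
    n = design.crosses_per_type
    labels = design.labels
    combos = enumerate_combinations(design)

    def isolate(label: str, note: str) -> HusbandryStep:
        return HusbandryStep("isolate-virgins", label, note)

    blocks: list[ScheduleBlock] = []
    if design.kind == "matched-pairs-4":
        a, b, c, d = labels
        parental = tuple(
            CrossSpec(m, f, n) for m, f in ((a, b), (b, a), (c, d), (d, c))
        )
        f1_classes = [a + b, b + a, c + d, d + c]
        hybrid = tuple(
            CrossSpec(combo.name[:2], combo.name[2:], n) for combo in combos
        )
        blocks = [
            ScheduleBlock(0, husbandry=tuple(
                isolate(l, "founder males for the reciprocal parental crosses") for l in labels
            )),
            ScheduleBlock(1, crosses=parental, husbandry=tuple(
                isolate(l, "founder males for the repeated parental crosses") for l in labels
            )),
            ScheduleBlock(2, crosses=parental, husbandry=tuple(
                isolate(l, "virgin F1 hybrid females lay unfertilized eggs: hybrid males")
                for l in f1_classes
            ) + tuple(
                isolate(l, "founder males for the third parental cohort") for l in labels
            )),
            ScheduleBlock(3, crosses=parental + hybrid, husbandry=tuple(
                isolate(l, "second cohort of virgin F1 females: hybrid males for the repeat")
                for l in f1_classes
            )),
            ScheduleBlock(4, crosses=hybrid, husbandry=tuple(
                isolate(combo.name, "virgin fully hybrid females: fully hybrid males")
                for combo in combos
            )),
            ScheduleBlock(5, husbandry=tuple(
                HusbandryStep("pool", combo.name, "mix both sexes into the founding pool")
                for combo in combos
            )),
        ]
    else:  # round-robin-3
        parental = tuple(
            CrossSpec(m, f, n)
            for m in labels
            for f in labels
            if m != f
        )
        final = tuple(
            CrossSpec(combo.name[:2], combo.name[2], n) for combo in combos
        )
        blocks = [
            ScheduleBlock(0, husbandry=tuple(
                isolate(l, "founder males for the reciprocal parental crosses") for l in labels
            )),
            ScheduleBlock(1, crosses=parental, husbandry=tuple(
                isolate(l, "founder males for the F1 x founder crosses") for l in labels
            )),
            ScheduleBlock(2, crosses=parental + final, husbandry=tuple(
                isolate(l, "founder males for the repeated F1 x founder crosses") for l in labels
            )),
            ScheduleBlock(3, crosses=final, husbandry=tuple(
                isolate(combo.name, "virgin fully hybrid females: fully hybrid males")
                for combo in combos
            )),
            ScheduleBlock(4, husbandry=tuple(
                HusbandryStep("pool", combo.name, "mix both sexes into the founding pool")
                for combo in combos
            )),
        ]
    schedule = CrossSchedule(design, tuple(blocks))
    schedule.validate()
    return schedule


@dataclass(frozen=True)
class FoundingCensus:
    """Per-combination founding contributions under an equalization rule."""

    counts: Mapping[str, int]
    rule: Literal["minimum", "as-available"]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_report(self) -> dict:
        return {"rule": self.rule, "counts": dict(self.counts), "total": self.total}


def founding_census(
    available: Mapping[str, int] | Mapping[HybridCombination, int],
    rule: Literal["minimum", "as-available"] = "minimum",
) -> FoundingCensus:
    """Founding contributions per combination.

    Under the ``minimum`` rule every combination contributes the minimum of
    the available counts, equalizing representation (72 available at the
    minimum over 8 combinations founds 576 per sex); ``as-available``
    passes counts through unchanged (used for a scarce male pool where all
    males are kept regardless of combination).
    """
    if not available:
        raise ValueError("at least one combination is required")
    counts = {str(k): int(v) for k, v in available.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError(f"available counts must be non-negative, got {counts}")
    if rule == "minimum":
        floor = min(counts.values())
        counts = {k: floor for k in counts}
    elif rule != "as-available":
        raise ValueError(f"unknown census rule {rule!r}")
    return FoundingCensus(counts=counts, rule=rule)


def mito_representation(combos: Sequence[HybridCombination]) -> tuple[dict[str, int], bool]:
    """Count combinations per mitochondrial origin; report whether balanced."""
    if not combos:
        raise ValueError("at least one combination is required")
    counts: dict[str, int] = {}
    for combo in combos:
        counts[combo.mito_origin] = counts.get(combo.mito_origin, 0) + 1
    founders = {label for combo in combos for label in combo.labels}
    balanced = len(set(counts.values())) == 1 and set(counts) == founders
    return counts, balanced
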