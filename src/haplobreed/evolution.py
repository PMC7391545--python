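"""Transfer bookkeeping for serial-transfer experimental evolution.

Each replicate population under a selection regime is propagated by
transferring a fixed number of mated females (220 in the protocol this
models) to a fresh box every generation. Females are sourced with a strict
priority: first from the current experimental box, then from the previous
generation's box kept as a backup, and finally from the base outbred
population (assumed inexhaustible and unadapted, selection generation 0).

Because replenished females have experienced fewer generations of
selection, replicates accumulate selection history at different rates. The
effective number of generations of selection evolves as the transfer-
weighted mean

    Gen_{t+1} = 1 + (N_t * Gen_t + N_{t-1} * Gen_{t-1} + N_0 * Gen_0) / N_total

with Gen_0 = 0 for the base population; the backup box carries the
regime's effective-generation value of one step earlier. Values are kept
fractional — the quantity is a weighted mean, not a count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

__all__ = [
    "TransferRecord",
    "RegimeHistory",
    "plan_transfer",
    "effective_generations",
    "track_regime",
]

_TOL = 1e-9


@dataclass(frozen=True)
class TransferRecord:
    """One generation's transfer: source counts and source Gen values."""

    generation: int
    n_current: int
    n_backup: int
    n_base: int
    n_total: int
    gen_current: float = 0.0
    gen_backup: float = 0.0
    gen_base: float = 0.0

    def __post_init__(self) -> None:
        counts = (self.n_current, self.n_backup, self.n_base)
        if any(c < 0 for c in counts):
            raise ValueError(f"source counts must be non-negative, got {counts}")
        if sum(counts) != self.n_total:
            raise ValueError(
                f"source counts {counts} must sum to the transfer target {self.n_total}"
            )
        if self.n_total < 1:
            raise ValueError(f"transfer target must be >= 1, got {self.n_total}")
        gens = (self.gen_current, self.gen_backup, self.gen_base)
        if any(g < 0 for g in gens):
            raise ValueError(f"effective-generation values must be non-negative, got {gens}")
        if self.gen_base != 0:
            raise ValueError("the base population is unadapted by definition: gen_base = 0")


def plan_transfer(
    available_current: int,
    available_backup: int,
    target: int = 220,
    generation: int = 0,
) -> TransferRecord:
    """Allocate a transfer greedily: current box, then backup, then base.

    The base outbred population absorbs any shortfall, so the returned
    counts always sum to ``target``.
    """
    if target < 1:
        raise ValueError(f"target must be >= 1, got {target}")
    if available_current < 0 or available_backup < 0:
        raise ValueError("availabilities must be non-negative")
    n_current = min(available_current, target)
    n_backup = min(available_backup, target - n_current)
    n_base = target - n_current - n_backup
    return TransferRecord(
        generation=generation,
        n_current=n_current,
        n_backup=n_backup,
        n_base=n_base,
        n_total=target,
    )


def effective_generations(record: TransferRecord) -> float:
    """Effective number of generations of selection after one transfer.

    The weighted mean of the sources' Gen values plus one (the generation
    the transferred females are about to experience). Bounded by
    1 <= Gen_{t+1} <= max(Gen_t, Gen_{t-1}) + 1; a transfer sourced wholly
    from the current box gives exactly Gen_t + 1, and one sourced wholly
    from the base resets to 1. (The backup bound matters: a current box
    recently refilled from base can carry a lower Gen than its backup.)
    """
    weighted = (
        record.n_current * record.gen_current
        + record.n_backup * record.gen_backup
        + record.n_base * record.gen_base
    )
    return 1.0 + weighted / record.n_total


@dataclass
class RegimeHistory:
    """Transfer trajectory of one replicate population under one regime."""

    replicate: str
    regime: str
    records: list[TransferRecord] = field(default_factory=list)
    effective: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) != len(self.effective):
            raise ValueError("one effective-generation value per transfer record")
        for i, (rec, gen) in enumerate(zip(self.records, self.effective)):
            if gen > i + 1 + _TOL:
                raise ValueError(
                    f"effective generations ({gen}) cannot exceed chronological "
                    f"generations ({i + 1}) at step {i}"
                )
            if gen < 1 - _TOL:
                raise ValueError("effective generations are >= 1 from the first transfer on")

    @property
    def final_effective(self) -> float:
        return self.effective[-1] if self.effective else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": [r.generation for r in self.records],
                "N_current": [r.n_current for r in self.records],
                "N_backup": [r.n_backup for r in self.records],
                "N_base": [r.n_base for r in self.records],
                "N_total": [r.n_total for r in self.records],
                "effective_generations": self.effective,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, replicate: str = "", regime: str = "") -> "RegimeHistory":
        """Rebuild a history from the TSV written by :meth:`write_tsv`."""
        df = pd.read_csv(path, sep="\t")
        history = cls(replicate=replicate, regime=regime)
        prev_gen, prev_prev_gen = 0.0, 0.0
        for _, row in df.iterrows():
            rec = TransferRecord(
                generation=int(row["generation"]),
                n_current=int(row["N_current"]),
                n_backup=int(row["N_backup"]),
                n_base=int(row["N_base"]),
                n_total=int(row["N_total"]),
                gen_current=prev_gen,
                gen_backup=prev_prev_gen,
            )
            value = float(row["effective_generations"])
            history.records.append(rec)
            history.effective.append(value)
            prev_prev_gen, prev_gen = prev_gen, value
        return history


def track_regime(
    availabilities: Sequence[tuple[int, int]],
    target: int = 220,
    replicate: str = "r1",
    regime: str = "regime",
) -> RegimeHistory:
    """Chain transfers over a regime's history of (current, backup) counts.

    Each step plans the transfer greedily and updates the effective number
    of generations; the backup box at step t carries the regime's
    effective-generation value from step t-1 (the backup is simply the
    previous generation's box kept until the next transfer).
    """
    if not availabilities:
        raise ValueError("history must contain at least one generation")
    history = RegimeHistory(replicate=replicate, regime=regime)
    gen_current = 0.0  # before the first transfer the box holds base individuals
    gen_backup = 0.0
    for step, (avail_current, avail_backup) in enumerate(availabilities):
        counts = plan_transfer(avail_current, avail_backup, target, generation=step)
        record = TransferRecord(
            generation=step,
            n_current=counts.n_current,
            n_backup=counts.n_backup,
            n_base=counts.n_base,
            n_total=counts.n_total,
            gen_current=gen_current,
            gen_backup=gen_backup,
        )
        value = effective_generations(record)
        history.records.append(record)
        history.effective.append(value)
        gen_backup = gen_current
        gen_current = value
    # re-run the consistency checks with the full trajectory in place
    RegimeHistory(history.replicate, history.regime, history.records, history.effective)
    return history
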