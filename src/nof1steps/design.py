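"""Trial design: treatment labels, block layout and per-day label resolution.

A trial consists of a baseline period followed by six consecutive treatment
blocks. Two pre-specified block sequences balance each condition's position
in time; participants are randomized between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

YOGA = "YOGA"
MASSAGE = "MASSAGE"
USUAL_CARE = "USUAL_CARE"
BASELINE = "BASELINE"

TREATMENTS: Tuple[str, ...] = (YOGA, MASSAGE, USUAL_CARE)
ACTIVE_TREATMENTS: Tuple[str, ...] = (YOGA, MASSAGE)

#: Default sequences: each condition appears twice per sequence and the two
#: sequences mirror the active treatments, balancing position in time.
DEFAULT_SEQUENCE_A: Tuple[str, ...] = (YOGA, USUAL_CARE, MASSAGE, YOGA, USUAL_CARE, MASSAGE)
DEFAULT_SEQUENCE_B: Tuple[str, ...] = (MASSAGE, USUAL_CARE, YOGA, MASSAGE, USUAL_CARE, YOGA)

MINUTES_PER_DAY = 1440

BLOCKS_PER_SEQUENCE = 6


class InvalidDesignError(ValueError):
    """Raised when a trial design violates its structural invariants."""


@dataclass(frozen=True)
class TrialDesign:
    """Layout of one personalized crossover trial.

    Parameters
    ----------
    baseline_days
        Length of the pre-randomization baseline period, in days.
    block_days
        Length of each treatment block, in days.
    sequences
        Two ordered block-label sequences of length six, drawn from
        ``{YOGA, MASSAGE, USUAL_CARE}``. Both must contain the same
        multiset of labels.
    randomization_ratio
        Allocation ratio between the two sequences (block randomization).
    """

    baseline_days: int = 14
    block_days: int = 14
    sequences: Tuple[Tuple[str, ...], Tuple[str, ...]] = (
        DEFAULT_SEQUENCE_A,
        DEFAULT_SEQUENCE_B,
    )
    randomization_ratio: Tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.baseline_days < 0:
            raise InvalidDesignError("baseline_days must be >= 0")
        if self.block_days < 1:
            raise InvalidDesignError("block_days must be >= 1")
        if len(self.sequences) != 2:
            raise InvalidDesignError("exactly two treatment sequences required")
        seqs = tuple(tuple(s) for s in self.sequences)
        object.__setattr__(self, "sequences", seqs)
        for seq in seqs:
            if len(seq) != BLOCKS_PER_SEQUENCE:
                raise InvalidDesignError(
                    f"each sequence must have {BLOCKS_PER_SEQUENCE} blocks, got {len(seq)}"
                )
            bad = set(seq) - set(TREATMENTS)
            if bad:
                raise InvalidDesignError(f"unknown block labels: {sorted(bad)}")
        if sorted(seqs[0]) != sorted(seqs[1]):
            raise InvalidDesignError("sequences must contain the same multiset of labels")
        ratio = tuple(int(r) for r in self.randomization_ratio)
        if len(ratio) != 2 or any(r <= 0 for r in ratio):
            raise InvalidDesignError("randomization_ratio entries must be positive")
        object.__setattr__(self, "randomization_ratio", ratio)

    @property
    def n_blocks(self) -> int:
        return BLOCKS_PER_SEQUENCE

    @property
    def n_days(self) -> int:
        """Total trial length in days (baseline plus all blocks)."""
        return self.baseline_days + self.n_blocks * self.block_days

    def day_labels(self, sequence_index: int) -> list[str]:
        """Block label for every day of the trial, in day order."""
        seq = self.sequences[sequence_index]
        labels = [BASELINE] * self.baseline_days
        for block in seq:
            labels.extend([block] * self.block_days)
        return labels

    def block_label(self, day_index: int, sequence_index: int) -> str:
        """Block label active on ``day_index`` (0-based from first baseline day)."""
        if not 0 <= day_index < self.n_days:
            raise InvalidDesignError(
                f"day_index {day_index} outside trial of {self.n_days} days"
            )
        if day_index < self.baseline_days:
            return BASELINE
        block = (day_index - self.baseline_days) // self.block_days
        return self.sequences[sequence_index][block]
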