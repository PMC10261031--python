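"""Scoring convention for memory responses where "no response" is possible.

Every test cue belongs to one of the domain classes, so there are no true
negatives.  A retrieval classified as the cue's class is a right response; a
retrieval classified otherwise is simultaneously a false positive of the
assigned class and a false negative of the right one; a rejection is no
response.  Precision, recall and accuracy therefore coincide when every cue
gets a response, and recall (= accuracy) drops below precision otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["OutcomeCounts", "score"]


@dataclass(frozen=True)
class OutcomeCounts:
    """Raw outcome tallies of a batch of cues."""

    right: int = 0
    wrong: int = 0
    none: int = 0

    def __post_init__(self):
        if min(self.right, self.wrong, self.none) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.right + self.wrong + self.none

    def __add__(self, other: "OutcomeCounts") -> "OutcomeCounts":
        return OutcomeCounts(
            self.right + other.right,
            self.wrong + other.wrong,
            self.none + other.none,
        )


def score(counts: OutcomeCounts) -> dict[str, float]:
    """Precision, recall and accuracy in percent.

    precision = right / (right + wrong); recall = accuracy = right / total.
    With no responses at all, precision is defined as 0.
    """
    if counts.total == 0:
        raise ValueError("cannot score an empty batch")
    responded = counts.right + counts.wrong
    precision = 100.0 * counts.right / responded if responded else 0.0
    recall = 100.0 * counts.right / counts.total
    return {"precision": precision, "recall": recall, "accuracy": recall}
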