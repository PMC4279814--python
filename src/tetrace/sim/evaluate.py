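"""Benchmarking predicted events against an injection truth table.

An injected event counts as *found* when any predicted line's acceptor
interval comes within the tolerance (default +/- 300 bp) of the true
insertion point, and as *found with donor* when such a line's donor
interval additionally overlaps the true donor span.  Predictions are
counted per acceptor site (lines sharing one acceptor id are one
prediction), so duplicated donor-candidate lines do not inflate the
denominator of the positive predictive value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ..model import EventCall, INSERTION_TYPES, Interval
from .genome import PlannedEvent


def _point_distance(iv: Interval, chrom: str, pos: int) -> Optional[int]:
    if iv.chrom != chrom:
        return None
    if iv.start <= pos < iv.end:
        return 0
    return min(abs(pos - iv.start), abs(pos - (iv.end - 1)))


@dataclass
class EvaluationReport:
    n_injected: int
    n_predictions: int  # distinct predicted acceptor sites (insertions)
    found: int
    found_with_donor: int
    true_positive_predictions: int
    per_class: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def false_positives(self) -> int:
        return self.n_predictions - self.true_positive_predictions

    @property
    def sensitivity(self) -> Optional[float]:
        if self.n_injected == 0:
            return None
        return self.found_with_donor / self.n_injected

    @property
    def ppv(self) -> Optional[float]:
        """True positives / filtered predictions; None when nothing predicted."""
        if self.n_predictions == 0:
            return None
        return self.true_positive_predictions / self.n_predictions

    def to_dict(self) -> dict:
        return {
            "n_injected": self.n_injected,
            "n_predictions": self.n_predictions,
            "found": self.found,
            "found_with_donor": self.found_with_donor,
            "true_positive_predictions": self.true_positive_predictions,
            "false_positives": self.false_positives,
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "per_class": {
                k: {"injected": v[0], "found": v[1], "found_with_donor": v[2]}
                for k, v in self.per_class.items()
            },
        }

    def write_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def evaluate_calls(
    events: Sequence[EventCall],
    truth: Sequence[PlannedEvent],
    tol: int = 300,
) -> EvaluationReport:
    """Score predictions against the truth table.

    The result is invariant to event order and to duplicate lines sharing
    one acceptor id.
    """
    if not truth:
        raise ValueError("empty truth table")
    lines = [e for e in events if e.event_type in INSERTION_TYPES]
    by_acceptor: dict[str, list[EventCall]] = {}
    for e in lines:
        by_acceptor.setdefault(e.acceptor_id, []).append(e)

    found = 0
    found_with_donor = 0
    matched_ids: set[str] = set()
    per_class: dict[str, list[int]] = {}
    for t in truth:
        cls = per_class.setdefault(t.event_class, [0, 0, 0])
        cls[0] += 1
        t_found = False
        t_donor = False
        for acc_id, grp in by_acceptor.items():
            near = any(
                (d := _point_distance(e.acceptor, t.acceptor_chrom, t.acceptor_pos))
                is not None
                and d <= tol
                for e in grp
            )
            if not near:
                continue
            t_found = True
            if any(
                e.donor.overlaps(t.donor)
                and _point_distance(e.acceptor, t.acceptor_chrom, t.acceptor_pos) is not None
                and _point_distance(e.acceptor, t.acceptor_chrom, t.acceptor_pos) <= tol
                for e in grp
            ):
                t_donor = True
                matched_ids.add(acc_id)
        if t_found:
            found += 1
            cls[1] += 1
        if t_donor:
            found_with_donor += 1
            cls[2] += 1

    return EvaluationReport(
        n_injected=len(truth),
        n_predictions=len(by_acceptor),
        found=found,
        found_with_donor=found_with_donor,
        true_positive_predictions=len(matched_ids),
        per_class={k: tuple(v) for k, v in per_class.items()},
    )
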