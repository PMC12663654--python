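"""Sensitivity/precision evaluation of a domain HMM on labeled sets.

The profile is judged against a labeled positive set (proteins known to
carry the domain) and a negative control set (e.g. Argonaute proteins,
which carry a PAZ domain but must not be detected by a Dicer-specific
profile). Sensitivity (recall) is TP / (TP + FN); precision is reported
only when TP + FP > 0, otherwise left undefined. This module never runs
the HMM search itself — detections arrive as a plain id set from any
external engine at the caller's threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .dcr_classifier import round_half_up

OVERALL = "overall"


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts and derived rates for one taxonomic group."""

    group: str
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def sensitivity(self) -> float | None:
        """TP / (TP + FN); None when the group has no positives."""
        total = self.tp + self.fn
        return self.tp / total if total else None

    @property
    def sensitivity_percent(self) -> float | None:
        s = self.sensitivity
        return None if s is None else round_half_up(100.0 * s, 1)

    @property
    def precision(self) -> float | None:
        """TP / (TP + FP); None (undefined) when nothing was detected."""
        total = self.tp + self.fp
        return self.tp / total if total else None


def evaluate(
    detections: Iterable[str],
    positives: Iterable[str],
    negatives: Iterable[str],
    group_map: Mapping[str, str] | None = None,
) -> list[EvalResult]:
    """Per-group and overall confusion counts for a detection set.

    ``positives`` and ``negatives`` must be disjoint; ids in neither set
    are ignored. ``group_map`` assigns each id a taxonomic group; absent
    ids fall into the overall row only. The overall row is first.
    """
    detected = set(detections)
    pos = set(positives)
    neg = set(negatives)
    overlap = pos & neg
    if overlap:
        raise ValueError(f"ids in both positive and negative sets: {sorted(overlap)[:5]}")

    def counts(ids_pos, ids_neg) -> tuple[int, int, int, int]:
        tp = len(ids_pos & detected)
        fn = len(ids_pos - detected)
        fp = len(ids_neg & detected)
        tn = len(ids_neg - detected)
        return tp, fn, fp, tn

    results = [EvalResult(OVERALL, *counts(pos, neg))]
    if group_map:
        for group in sorted(set(group_map.values())):
            gpos = {i for i in pos if group_map.get(i) == group}
            gneg = {i for i in neg if group_map.get(i) == group}
            results.append(EvalResult(group, *counts(gpos, gneg)))
    return results


def read_labeled_tsv(stream) -> tuple[set[str], set[str], dict[str, str]]:
    """Read (id, label, group) rows; label is 'positive' or 'negative'."""
    positives: set[str] = set()
    negatives: set[str] = set()
    groups: dict[str, str] = {}
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("id\t"):
            continue
        parts = line.split("\t")
        pid, label = parts[0], parts[1].lower()
        if label == "positive":
            positives.add(pid)
        elif label == "negative":
            negatives.add(pid)
        else:
            raise ValueError(f"label must be positive/negative, got {label!r}")
        if len(parts) > 2 and parts[2]:
            groups[pid] = parts[2]
    return positives, negatives, groups


def results_to_rows(results: Iterable[EvalResult]) -> list[dict]:
    rows = []
    for r in results:
        rows.append(
            {
                "group": r.group,
                "TP": r.tp,
                "FN": r.fn,
                "FP": r.fp,
                "TN": r.tn,
                "sensitivity_pct": r.sensitivity_percent,
                "precision": None if r.precision is None else round(r.precision, 4),
            }
        )
    return rows
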