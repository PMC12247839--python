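"""Per-bone segmentation audit: label matching, error taxonomy, accuracy.

Each ground-truth bone receives exactly one outcome:

* ``correct`` — one predicted label covers it and nothing else substantially;
* ``over_split`` — two or more predicted labels each cover a substantial
  fraction of it (one bone as 2+ materials);
* ``over_connected`` — its single predicted label also substantially covers
  another truth bone (2+ bones as 1 material);
* ``missing`` — no predicted label covers it (e.g. a completely eroded bone).

The accuracy statistic is (TP + TN) / (TP + TN + FP + FN) * 100 with TN
fixed at 0: TP = correct, FP = over-split, FN = over-connected (missing
bones are counted as FN by default; a flag exposes the exclude-missing
variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .volume_io import BoneTable, LabelVolume

Outcome = Literal["correct", "over_split", "over_connected", "missing"]


@dataclass
class OutcomeRecord:
    truth_id: int
    outcome: Outcome
    matched_pred_ids: tuple[int, ...] = ()
    overlap_fractions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.outcome == "missing" and self.matched_pred_ids:
            raise ValueError("missing records cannot carry matches")
        if self.outcome == "over_split" and len(self.matched_pred_ids) < 2:
            raise ValueError("over_split requires >= 2 matched predicted ids")


@dataclass
class Correspondence:
    """Overlap bookkeeping between a predicted and a truth label map."""

    truth_ids: np.ndarray
    pred_ids: np.ndarray
    #: overlap voxel counts, indexed [truth, pred]
    overlap: dict[tuple[int, int], int]
    truth_sizes: dict[int, int]
    pred_sizes: dict[int, int]
    #: per truth id: predicted ids covering >= overlap_min of the truth volume
    matches: dict[int, list[int]]
    #: per pred id: its plurality truth partner (largest overlap, lower id wins ties)
    plurality: dict[int, int]
    overlap_min: float


def match_labels(
    pred: LabelVolume, truth: LabelVolume, overlap_min: float = 0.5
) -> Correspondence:
    """Compute the overlap table and per-truth candidate matches.

    A predicted id is a candidate match for a truth bone when it covers at
    least ``overlap_min`` of the bone's voxels.  Symmetric bookkeeping
    (plurality partners, full overlap table) is retained for diagnosis.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if not (0.0 < overlap_min <= 1.0):
        raise ValueError(f"overlap_min must be in (0, 1], got {overlap_min}")
    t = truth.labels.ravel()
    p = pred.labels.ravel()
    both = (t > 0) | (p > 0)
    pairs, counts = np.unique(
        np.stack([t[both], p[both]]), axis=1, return_counts=True
    )
    overlap: dict[tuple[int, int], int] = {}
    truth_sizes: dict[int, int] = {}
    pred_sizes: dict[int, int] = {}
    for (ti, pi), c in zip(pairs.T, counts):
        ti, pi, c = int(ti), int(pi), int(c)
        if ti > 0:
            truth_sizes[ti] = truth_sizes.get(ti, 0) + c
        if pi > 0:
            pred_sizes[pi] = pred_sizes.get(pi, 0) + c
        if ti > 0 and pi > 0:
            overlap[(ti, pi)] = c

    truth_ids = np.array(sorted(truth_sizes))
    pred_ids = np.array(sorted(pred_sizes))

    matches: dict[int, list[int]] = {int(ti): [] for ti in truth_ids}
    for (ti, pi), c in sorted(overlap.items()):
        if c >= overlap_min * truth_sizes[ti]:
            matches[ti].append(pi)

    plurality: dict[int, int] = {}
    for pi in pred_ids:
        cands = [(c, -ti) for (ti, p2), c in overlap.items() if p2 == pi]
        if cands:
            c, neg_ti = max(cands)
            plurality[int(pi)] = -neg_ti
    return Correspondence(
        truth_ids=truth_ids,
        pred_ids=pred_ids,
        overlap=overlap,
        truth_sizes=truth_sizes,
        pred_sizes=pred_sizes,
        matches=matches,
        plurality=plurality,
        overlap_min=overlap_min,
    )


def classify_outcomes(corr: Correspondence) -> list[OutcomeRecord]:
    """Assign one outcome per truth bone from the correspondence table."""
    records = []
    for ti in corr.truth_ids:
        ti = int(ti)
        cands = corr.matches[ti]
        fracs = tuple(corr.overlap[(ti, pi)] / corr.truth_sizes[ti] for pi in cands)
        if not cands:
            records.append(OutcomeRecord(ti, "missing"))
            continue
        if len(cands) >= 2:
            records.append(OutcomeRecord(ti, "over_split", tuple(cands), fracs))
            continue
        pi = cands[0]
        shared = any(
            other != ti and pi in corr.matches[int(other)] for other in corr.truth_ids
        )
        outcome = "over_connected" if shared else "correct"
        records.append(OutcomeRecord(ti, outcome, (pi,), fracs))
    return records


def counts(records: Iterable[OutcomeRecord], count_missing_as_fn: bool = True) -> dict:
    n = {"correct": 0, "over_split": 0, "over_connected": 0, "missing": 0}
    for r in records:
        n[r.outcome] += 1
    fn = n["over_connected"] + (n["missing"] if count_missing_as_fn else 0)
    return {
        "TP": n["correct"],
        "TN": 0,
        "FP": n["over_split"],
        "FN": fn,
        **n,
    }


def accuracy(records: Iterable[OutcomeRecord], count_missing_as_fn: bool = True) -> float:
    """(TP + TN) / (TP + TN + FP + FN) * 100 with TN = 0."""
    records = list(records)
    if not records:
        raise ValueError("accuracy is undefined for zero records")
    c = counts(records, count_missing_as_fn)
    denom = c["TP"] + c["TN"] + c["FP"] + c["FN"]
    if denom == 0:
        # only possible when missing bones are excluded and nothing else exists
        raise ValueError("accuracy is undefined: no counted records")
    return 100.0 * (c["TP"] + c["TN"]) / denom


@dataclass
class SegmentationReport:
    """Outcome records plus the accuracy statistic and compartment table."""

    records: list[OutcomeRecord]
    count_missing_as_fn: bool = True
    table: BoneTable | None = None

    @property
    def stats(self) -> dict:
        return counts(self.records, self.count_missing_as_fn)

    @property
    def accuracy(self) -> float:
        return accuracy(self.records, self.count_missing_as_fn)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "truth_id": r.truth_id,
                "outcome": r.outcome,
                "matched_pred_ids": ";".join(map(str, r.matched_pred_ids)),
                "overlap_fractions": ";".join(f"{f:.4f}" for f in r.overlap_fractions),
            }
            if self.table is not None:
                row["compartment"] = self.table.compartment_of(r.truth_id)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        out = {"accuracy_percent": self.accuracy, **self.stats}
        if self.table is not None:
            comp = compartment_summary(self.records, self.table, self.count_missing_as_fn)
            out["compartments"] = comp.to_dict(orient="records")
        return out


def evaluate(
    pred: LabelVolume,
    truth: LabelVolume,
    table: BoneTable | None = None,
    overlap_min: float = 0.5,
    count_missing_as_fn: bool = True,
) -> SegmentationReport:
    """End-to-end audit: match, classify and aggregate.

    When a :class:`BoneTable` is supplied it serves as the anatomical
    roster: table entries absent from the truth map (completely eroded
    bones) are reported ``missing``.
    """
    corr = match_labels(pred, truth, overlap_min)
    records = classify_outcomes(corr)
    if table is not None:
        present = {r.truth_id for r in records}
        for lid, _, _ in table.entries:
            if lid not in present:
                records.append(OutcomeRecord(lid, "missing"))
        records.sort(key=lambda r: r.truth_id)
    return SegmentationReport(records, count_missing_as_fn, table)


def compartment_summary(
    records: Iterable[OutcomeRecord],
    table: BoneTable,
    count_missing_as_fn: bool = True,
) -> pd.DataFrame:
    """Accuracy and error counts per bone compartment (tidy table)."""
    records = list(records)
    known = {lid for lid, _, _ in table.entries}
    unknown = [r.truth_id for r in records if r.truth_id not in known]
    if unknown:
        raise KeyError(f"truth ids missing from bone table: {sorted(set(unknown))}")
    by_comp: dict[str, list[OutcomeRecord]] = {}
    for r in records:
        by_comp.setdefault(table.compartment_of(r.truth_id), []).append(r)
    rows = []
    for comp in sorted(by_comp):
        recs = by_comp[comp]
        c = counts(recs, count_missing_as_fn)
        rows.append(
            {
                "compartment": comp,
                "n_bones": len(recs),
                "accuracy_percent": accuracy(recs, count_missing_as_fn),
                **c,
            }
        )
    return pd.DataFrame(rows)
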