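"""Detection scoring: sensitivity and false-positive accounting per set.

A truth nodule counts as detected when some candidate centroid lies within
``max(hit_distance_mm, truth radius)`` of its center; matching is greedy by
ascending distance, one candidate per truth (ties broken by descending
candidate response). Unmatched candidates are false positives, reported both
in total and as a per-set mean (exact and rounded to the nearest integer,
the convention clinical summaries use).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Candidate
from .errors import InputError
from .phantom import GroundTruthNodule


@dataclass
class EvalResult:
    """Aggregate detection accounting over one or more image sets."""

    n_true: int
    n_detected: int
    n_missed: int
    n_fp: int
    n_sets: int
    sensitivity_pct: float
    fp_per_set: float
    fp_per_set_rounded: int

    @classmethod
    def from_counts(cls, n_true: int, n_detected: int, n_fp: int, n_sets: int) -> "EvalResult":
        """Build a result straight from aggregate counts."""
        if n_detected > n_true or min(n_true, n_detected, n_fp) < 0 or n_sets < 1:
            raise InputError("inconsistent aggregate counts")
        sensitivity = 100.0 * n_detected / n_true if n_true else 0.0
        fp_mean = n_fp / n_sets
        return cls(
            n_true=n_true,
            n_detected=n_detected,
            n_missed=n_true - n_detected,
            n_fp=n_fp,
            n_sets=n_sets,
            sensitivity_pct=sensitivity,
            fp_per_set=fp_mean,
            fp_per_set_rounded=int(np.floor(fp_mean + 0.5)),
        )


def _match_one_set(
    candidates: list[Candidate],
    truths: list[GroundTruthNodule],
    hit_distance_mm: float,
) -> tuple[int, int]:
    """Greedy one-to-one matching; returns (n_detected, n_fp) for the set."""
    if not truths:
        return 0, len(candidates)
    if not candidates:
        return 0, 0
    pairs = []
    for ci, cand in enumerate(candidates):
        for ti, truth in enumerate(truths):
            dist = float(
                np.linalg.norm(np.asarray(cand.centroid_mm) - np.asarray(truth.center_mm))
            )
            if dist <= max(hit_distance_mm, truth.radius_mm):
                pairs.append((dist, -cand.response, ci, ti))
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    for _dist, _neg_resp, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
    return len(used_t), len(candidates) - len(used_c)


def evaluate(
    candidates_per_set: list[list[Candidate]],
    truth_per_set: list[list[GroundTruthNodule]],
    hit_distance_mm: float = 5.0,
) -> EvalResult:
    """Score candidate lists against ground truth, one list per image set."""
    if hit_distance_mm <= 0:
        raise InputError(f"hit_distance_mm must be positive, got {hit_distance_mm}")
    if len(candidates_per_set) != len(truth_per_set):
        raise InputError(
            f"{len(candidates_per_set)} candidate sets vs {len(truth_per_set)} truth sets"
        )
    n_true = sum(len(t) for t in truth_per_set)
    n_detected = 0
    n_fp = 0
    for cands, truths in zip(candidates_per_set, truth_per_set):
        det, fp = _match_one_set(cands, truths, hit_distance_mm)
        n_detected += det
        n_fp += fp
    n_sets = max(len(truth_per_set), 1)
    sensitivity = 100.0 * n_detected / n_true if n_true else 0.0
    fp_mean = n_fp / n_sets
    return EvalResult(
        n_true=n_true,
        n_detected=n_detected,
        n_missed=n_true - n_detected,
        n_fp=n_fp,
        n_sets=n_sets,
        sensitivity_pct=sensitivity,
        fp_per_set=fp_mean,
        fp_per_set_rounded=int(np.floor(fp_mean + 0.5)),
    )
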