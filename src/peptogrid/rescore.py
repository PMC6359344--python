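"""Pose scoring against a frequency grid, normalization, ranking, hit selection.

A pose's raw score is the mean, over its atoms, of the occurrence-map value
of the atom's SYBYL type at the lattice vertex nearest the atom:

    Sr = (1/N) * sum_i s(a_i)

with N the total atom count.  Atoms whose nearest vertex falls outside the
box contribute 0 but stay in the denominator, so poses escaping the site are
penalized rather than silently shortened.  Raw scores are normalized by the
maximum Sr of the run into [0, 1] and ranked (rank 1 = best).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._model import DockingBox, FrequencyGrid, Pose, PoseSet, RescoredPose

__all__ = [
    "nearest_vertex",
    "score_pose",
    "rescore_set",
    "select_top_percentile",
    "PercentileSelection",
    "score_histogram",
]


def nearest_vertex(coord, box: DockingBox) -> tuple[tuple[int, int, int], bool]:
    """Index of the lattice vertex nearest *coord*, plus an in-box flag.

    Fractional lattice coordinates are rounded half-to-even; indices are
    clamped to the lattice, and the flag is False when the unclamped index
    fell outside.
    """
    frac = (np.asarray(coord, dtype=float) - box.origin) / box.step
    idx = np.rint(frac).astype(int)
    shape = np.array(box.shape)
    in_box = bool(np.all(idx >= 0) and np.all(idx < shape))
    clamped = np.clip(idx, 0, shape - 1)
    return (int(clamped[0]), int(clamped[1]), int(clamped[2])), in_box


def score_pose(pose: Pose, grid: FrequencyGrid) -> float:
    """Raw frequency-map score Sr of one pose (mean grid value over atoms)."""
    arrays = {t: grid.counts.get(t) for t in grid.type_axis}
    total = 0.0
    for atom in pose.atoms:
        if atom.sybyl_type not in arrays:
            raise ValueError(
                f"pose {pose.pose_id!r}: atom type {atom.sybyl_type!r} absent "
                "from the grid's type axis"
            )
        arr = arrays[atom.sybyl_type]
        if arr is None:
            continue  # type never occurred in the ensemble: value 0
        idx, in_box = nearest_vertex(atom.coords, grid.box)
        if in_box:
            total += float(arr[idx])
    return total / len(pose.atoms)


def _rank_key(rp: RescoredPose):
    # better normalized score first; ties: better (lower) native energy,
    # poses without a native score last, then pose_id for reproducibility
    native = rp.native_score if rp.native_score is not None else float("inf")
    return (-rp.normalized_score, native, rp.pose_id)


def rescore_set(poses: PoseSet | list[Pose], grid: FrequencyGrid) -> list[RescoredPose]:
    """Score every pose, normalize by the run maximum, and rank.

    Returns one :class:`RescoredPose` per input pose, in rank order.  If all
    raw scores are zero the normalized scores are all zero and ranking falls
    back to input order (with a warning).
    """
    pose_list = list(poses)
    if not pose_list:
        raise ValueError("empty pose set")
    results = [
        RescoredPose(
            pose_id=p.pose_id, sequence=p.sequence, source=p.source,
            raw_sr=score_pose(p, grid), native_score=p.native_score,
        )
        for p in pose_list
    ]
    max_sr = max(r.raw_sr for r in results)
    if max_sr > 0:
        for r in results:
            r.normalized_score = r.raw_sr / max_sr
        results.sort(key=_rank_key)
    else:
        warnings.warn("all raw scores are zero; ranking follows input order")
    for i, r in enumerate(results, 1):
        r.rank = i
    return results


@dataclass
class PercentileSelection:
    """Top-percentile hit list with its per-sequence pose tally."""

    poses: list[RescoredPose]
    threshold: float
    percentile: float
    sequence_counts: Counter

    def __len__(self) -> int:
        return len(self.poses)


def select_top_percentile(results: list[RescoredPose],
                          percentile: float = 95.0) -> PercentileSelection:
    """Poses whose normalized score lies strictly above the given percentile.

    Also tallies how many selected poses each unique sequence contributes,
    the quantity used to shortlist candidate peptides.
    """
    if not results:
        raise ValueError("empty result list")
    scores = np.array([r.normalized_score for r in results])
    threshold = float(np.percentile(scores, percentile)) if percentile > 0 else -np.inf
    selected = [r for r in results if r.normalized_score > threshold]
    return PercentileSelection(
        poses=sorted(selected, key=lambda r: r.rank),
        threshold=threshold,
        percentile=percentile,
        sequence_counts=Counter(r.sequence for r in selected),
    )


def score_histogram(results: list[RescoredPose], bins: int = 20
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of normalized scores over [0, 1]; returns (counts, edges)."""
    scores = [r.normalized_score for r in results]
    return np.histogram(scores, bins=bins, range=(0.0, 1.0))
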