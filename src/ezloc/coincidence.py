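"""Voxelwise coincidence analysis of an estimated EZ against a resection mask.

Counts are accumulated inside an evaluation region (default: the whole
brain mask; recorded in every result) and summarized as sensitivity
``100 * TP / (TP + FN)`` and specificity ``100 * TN / (TN + FP)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, GridMismatchError
from .imaging import BinaryMask, Volume3D


@dataclass
class CoincidenceResult:
    tp: int
    fp: int
    fn: int
    tn: int
    domain: str = "whole-brain"

    @property
    def region_size(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return sensitivity(self)

    @property
    def specificity(self) -> float:
        return specificity(self)

    def as_dict(self) -> dict:
        return dict(
            tp=self.tp, fp=self.fp, fn=self.fn, tn=self.tn,
            sensitivity=self.sensitivity, specificity=self.specificity,
            domain=self.domain,
        )


def confusion_counts(
    ez: BinaryMask, resection: BinaryMask, region: BinaryMask,
    domain: str = "whole-brain",
) -> CoincidenceResult:
    """TP/FP/FN/TN voxel counts of ``ez`` vs ``resection`` within ``region``."""
    for other, name in ((resection, "resection"), (region, "region")):
        if not ez.same_grid(other):
            raise GridMismatchError(f"ez and {name} masks are on different grids")
    if region.n_voxels == 0:
        raise DegenerateInputError("empty evaluation region")
    r = region.data
    e = ez.data & r
    s = resection.data & r
    tp = int(np.count_nonzero(e & s))
    fp = int(np.count_nonzero(e & ~s))
    fn = int(np.count_nonzero(~e & s))
    tn = int(np.count_nonzero(r) - tp - fp - fn)
    return CoincidenceResult(tp, fp, fn, tn, domain=domain)


def sensitivity(counts: CoincidenceResult) -> float:
    """Percentage 100 * TP / (TP + FN)."""
    denom = counts.tp + counts.fn
    if denom == 0:
        raise DegenerateInputError(
            "sensitivity undefined: resection empty within region (TP + FN = 0)"
        )
    return 100.0 * counts.tp / denom


def specificity(counts: CoincidenceResult) -> float:
    """Percentage 100 * TN / (TN + FP)."""
    denom = counts.tn + counts.fp
    if denom == 0:
        raise DegenerateInputError(
            "specificity undefined: degenerate region (TN + FP = 0)"
        )
    return 100.0 * counts.tn / denom


def label_regions(ez: BinaryMask, atlas: Volume3D, lookup: dict = None) -> list:
    """Anatomical-label overlap breakdown of an EZ mask.

    Returns ``[{name, voxels, fraction}, ...]`` sorted by descending overlap;
    fractions are relative to the EZ size and exclude background (label 0).
    Labels absent from ``lookup`` are reported as ``label:<int>``.
    """
    if not ez.same_grid(atlas):
        raise GridMismatchError("ez mask and atlas are on different grids")
    lookup = lookup or {}
    labels = np.asarray(atlas.data)[ez.data]
    total = labels.size
    out = []
    if total == 0:
        return out
    vals, counts = np.unique(labels[labels != 0], return_counts=True)
    for v, c in sorted(zip(vals, counts), key=lambda t: -t[1]):
        name = lookup.get(int(v), f"label:{int(v)}")
        out.append(dict(name=name, voxels=int(c), fraction=c / total))
    return out


def read_label_lookup(path) -> dict:
    """TSV with two columns: integer label, region name."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            out[int(parts[0])] = parts[1]
    return out
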