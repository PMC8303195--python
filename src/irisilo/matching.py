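"""Distributed partial-template matching across storage silos.

Each silo holds one partial biometric reference and never releases its bits.
A probe is divided into *padded* partial templates — the probe bits at every
position a silo could need across the allowed rotation shifts — and each silo
answers with per-shift score pairs ``(d_ij, a_ij)``: the partial disagreement
fraction and the count of jointly valid bits.  The central server pools

    d_theta_j = sum_i a_ij d_ij / sum_i a_ij

per angle and takes the minimum over angles; it never touches template bits.
Rotation is modeled as integer circular column shifts (rows are circular).
Because pooling is done on integer numerators, the per-angle pooled score
equals the whole-template masked distance at that shift *exactly*, for any
division scheme and mask pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .distances import UndefinedScoreError, modified_from_plain
from .templates import PartialTemplate, Template, TemplateError

__all__ = [
    "RotationGrid",
    "PartialScore",
    "Silo",
    "MatchResult",
    "MatchRejectedError",
    "build_padded_probe",
    "partial_compare",
    "aggregate_angle",
    "distributed_match",
]


class MatchRejectedError(RuntimeError):
    """Every rotation angle was undefined; no comparison could be scored."""


@dataclass(frozen=True)
class RotationGrid:
    """Allowed rotation angles, expressed as integer column shifts."""

    shifts: tuple[int, ...]

    def __post_init__(self) -> None:
        shifts = tuple(int(s) for s in self.shifts)
        if not shifts:
            raise ValueError("rotation grid must contain at least one shift")
        if len(set(shifts)) != len(shifts):
            raise ValueError("rotation shifts must be distinct")
        object.__setattr__(self, "shifts", shifts)

    @classmethod
    def symmetric(cls, delta: int = 8) -> "RotationGrid":
        """Shifts -delta..+delta; delta = 8 columns by default."""
        if delta < 0:
            raise ValueError("delta must be >= 0")
        return cls(tuple(range(-delta, delta + 1)))

    def ordered(self) -> list[int]:
        """Shifts in tie-break order: small |shift| first, negative before positive."""
        return sorted(self.shifts, key=lambda s: (abs(s), s))


@dataclass(frozen=True)
class PartialScore:
    """One silo's answer for one angle: integer counts only."""

    mismatches: int
    valid: int  # a_ij: jointly valid bit count

    def __post_init__(self) -> None:
        if self.valid < 0 or self.mismatches < 0 or self.mismatches > self.valid:
            raise ValueError(
                f"inconsistent counts: {self.mismatches} mismatches of {self.valid}"
            )

    @property
    def defined(self) -> bool:
        return self.valid > 0

    @property
    def value(self) -> float:
        if not self.defined:
            raise UndefinedScoreError("partial score with a_ij = 0 is undefined")
        return self.mismatches / self.valid

    @property
    def as_fraction(self) -> Fraction:
        if not self.defined:
            raise UndefinedScoreError("partial score with a_ij = 0 is undefined")
        return Fraction(self.mismatches, self.valid)


def build_padded_probe(
    probe: Template, reference_positions, grid: RotationGrid
) -> PartialTemplate:
    """Probe bits at every position a silo needs across all shifts.

    For each reference position ``(r, c)`` and each shift theta the padded
    probe carries the probe bit and mask bit at ``(r, (c + theta) mod q2)``.
    """
    pos = np.asarray(reference_positions, dtype=np.int64).reshape(-1, 2)
    if len(pos) == 0:
        raise TemplateError("empty reference position set")
    q2 = probe.shape[1]
    padded = set()
    for shift in grid.shifts:
        for r, c in pos:
            padded.add((int(r), int((c + shift) % q2)))
    padded_pos = np.array(sorted(padded), dtype=np.int64)
    return PartialTemplate.from_template(probe, padded_pos)


def partial_compare(
    padded_probe: PartialTemplate, reference: PartialTemplate, shift: int
) -> PartialScore:
    """Masked disagreement counts between a padded probe and one reference
    partial, with the probe column-shifted by ``shift``."""
    if padded_probe.origin_shape != reference.origin_shape:
        raise TemplateError("padded probe and reference disagree on origin shape")
    q1, q2 = reference.origin_shape
    cover = np.zeros((q1, q2), dtype=bool)
    pval = np.zeros((q1, q2), dtype=np.uint8)
    pmask = np.zeros((q1, q2), dtype=np.uint8)
    pr, pc = padded_probe.positions[:, 0], padded_probe.positions[:, 1]
    cover[pr, pc] = True
    pval[pr, pc] = padded_probe.values
    pmask[pr, pc] = padded_probe.mask_values
    rr = reference.positions[:, 0]
    cc = (reference.positions[:, 1] + shift) % q2
    if not cover[rr, cc].all():
        raise TemplateError(
            f"padded probe does not cover the reference positions at shift {shift}"
        )
    both = (reference.mask_values & pmask[rr, cc]).astype(bool)
    mismatches = int((reference.values[both] != pval[rr, cc][both]).sum())
    return PartialScore(mismatches, int(both.sum()))


class Silo:
    """A storage location holding one partial reference.

    The reference bits never cross the silo boundary: the public surface is
    the entry-position list (needed to route padded probes) and
    :meth:`compare`, which returns only ``(d_ij, a_ij)`` counts.
    """

    def __init__(self, reference: PartialTemplate) -> None:
        self.__reference = reference

    @property
    def positions(self) -> np.ndarray:
        return self.__reference.positions

    @property
    def origin_shape(self) -> tuple[int, int]:
        return self.__reference.origin_shape

    def compare(self, padded_probe: PartialTemplate, shift: int) -> PartialScore:
        return partial_compare(padded_probe, self.__reference, shift)


def aggregate_angle(scores: Iterable[PartialScore]) -> PartialScore:
    """Pool silo scores for one angle: the a_ij-weighted mean as exact counts.

    Undefined cells (a_ij = 0) carry weight zero.  Raises
    :class:`UndefinedScoreError` if every cell is undefined.
    """
    mismatches = 0
    valid = 0
    for s in scores:
        mismatches += s.mismatches
        valid += s.valid
    if valid == 0:
        raise UndefinedScoreError("all partial scores of this angle are undefined")
    return PartialScore(mismatches, valid)


@dataclass(frozen=True)
class MatchResult:
    """Final distributed score with its per-silo, per-angle evidence table."""

    score: float
    best_shift: int
    table: pd.DataFrame  # columns: silo, shift, mismatches, valid, d


def _check_partition(partials: Sequence[PartialTemplate]) -> tuple[int, int]:
    shape = partials[0].origin_shape
    seen = np.zeros(shape, dtype=np.int32)
    for p in partials:
        if p.origin_shape != shape:
            raise TemplateError("reference partials disagree on origin shape")
        seen[p.positions[:, 0], p.positions[:, 1]] += 1
    if not (seen == 1).all():
        raise TemplateError("reference partials must partition the lattice")
    return shape


def distributed_match(
    probe: Template,
    reference_partials: Sequence[PartialTemplate],
    grid: RotationGrid | None = None,
    metric: str = "hd",
) -> MatchResult:
    """Run the full silo protocol and return the minimum over angles.

    With ``metric="mhd"`` the central server converts each pooled plain score
    through the occlusion-penalty bridge using l = sum_i a_ij, still without
    seeing any bits.  Ties between angles go to the smallest ``|shift|``,
    negative before positive.
    """
    if metric not in ("hd", "mhd"):
        raise ValueError(f"unknown metric {metric!r}")
    grid = grid or RotationGrid.symmetric()
    shape = _check_partition(reference_partials)
    if probe.shape != shape:
        raise TemplateError("probe shape differs from the reference lattice")
    n = shape[0] * shape[1]
    silos = [Silo(p) for p in reference_partials]
    padded = [build_padded_probe(probe, s.positions, grid) for s in silos]

    rows = []
    best_score = None
    best_shift = None
    for shift in grid.ordered():
        angle_scores = []
        for i, silo in enumerate(silos):
            ps = silo.compare(padded[i], shift)
            angle_scores.append(ps)
            rows.append(
                {
                    "silo": i,
                    "shift": shift,
                    "mismatches": ps.mismatches,
                    "valid": ps.valid,
                    "d": ps.value if ps.defined else np.nan,
                }
            )
        try:
            pooled = aggregate_angle(angle_scores)
        except UndefinedScoreError:
            continue  # angle skipped entirely
        score = pooled.value
        if metric == "mhd":
            score = modified_from_plain(score, pooled.valid, n)
        if best_score is None or score < best_score:
            best_score = score
            best_shift = shift
    if best_score is None:
        raise MatchRejectedError("every rotation angle had an empty mask overlap")
    table = pd.DataFrame(rows).sort_values(["shift", "silo"]).reset_index(drop=True)
    return MatchResult(best_score, best_shift, table)
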