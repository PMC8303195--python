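"""Masked dissimilarity scores between binary templates.

Two metrics are provided.  The fractional Hamming distance

    d_H(A, B) = ||(C_A xor C_B) & M_A & M_B|| / ||M_A & M_B||

is the disagreement fraction over the l jointly valid bits and is undefined
when l = 0.  The modified Hamming distance charges every jointly *invalid*
bit a score of 0.5:

    d_H'(A, B) = ||(C_A xor C_B) & M_A & M_B|| / N  +  0.5 ||~(M_A & M_B)|| / N

so a probe that hides most of its bits behind an occlusion mask is pushed
toward 0.5 instead of inheriting the distance of its few exposed bits.  The
two are linked by d_H' = 0.5 - (0.5 - d_H) * l / N, which is how a central
server can convert a pooled plain score without seeing any bits.

All counts are integers and each score is produced by a single final
division, so equal inputs give bit-identical scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .templates import Template, TemplateError

__all__ = [
    "DissimilarityScore",
    "UndefinedScoreError",
    "hamming_distance",
    "modified_hamming_distance",
    "modified_from_plain",
]


class UndefinedScoreError(ValueError):
    """No jointly valid bits: the plain Hamming distance does not exist."""


@dataclass(frozen=True)
class DissimilarityScore:
    """A score together with the integer counts that produced it.

    ``mismatches`` is the disagreement count over the overlap,
    ``compared_bits`` the overlap size l, ``total_bits`` the lattice size N.
    """

    value: float
    compared_bits: int
    total_bits: int
    mismatches: int
    metric: str

    @property
    def as_fraction(self) -> Fraction:
        """The score as an exact rational."""
        if self.metric == "hd":
            return Fraction(self.mismatches, self.compared_bits)
        return Fraction(
            2 * self.mismatches + (self.total_bits - self.compared_bits),
            2 * self.total_bits,
        )


def _overlap_counts(a: Template, b: Template) -> tuple[int, int]:
    if a.shape != b.shape:
        raise TemplateError(f"shape mismatch: {a.shape} vs {b.shape}")
    both = a.mask & b.mask
    l = int(both.sum())
    mismatches = int(((a.phase ^ b.phase) & both).sum())
    return mismatches, l


def hamming_distance(a: Template, b: Template) -> DissimilarityScore:
    """Fractional Hamming distance restricted to jointly valid bits.

    Raises
    ------
    UndefinedScoreError
        If the masks have no valid bit in common (l = 0).
    """
    mismatches, l = _overlap_counts(a, b)
    if l == 0:
        raise UndefinedScoreError(
            "no jointly valid bits; use modified_hamming_distance or reject"
        )
    return DissimilarityScore(mismatches / l, l, a.n_bits, mismatches, "hd")


def modified_hamming_distance(a: Template, b: Template) -> DissimilarityScore:
    """Occlusion-penalizing distance; defined even with empty mask overlap."""
    mismatches, l = _overlap_counts(a, b)
    n = a.n_bits
    value = (2 * mismatches + (n - l)) / (2 * n)
    return DissimilarityScore(value, l, n, mismatches, "mhd")


def modified_from_plain(dh: float, l: int, n: int) -> float:
    """Convert a plain distance on l compared bits to the modified distance.

    Implements d_H' = 0.5 - (0.5 - d_H) * l / N.  With l = N the two metrics
    coincide; with l = 0 nothing was compared and the result is 0.5.
    """
    if n <= 0:
        raise ValueError(f"total bit count must be positive, got {n}")
    if not 0 <= l <= n:
        raise ValueError(f"compared bits l={l} outside 0..{n}")
    if not 0.0 <= dh <= 1.0:
        raise ValueError(f"plain distance {dh} outside [0, 1]")
    return 0.5 - (0.5 - dh) * l / n
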