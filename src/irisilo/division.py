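"""Division of a template into partial templates.

Three schemes are supported, all of which partition the lattice (every
position lands in exactly one partial) and divide the occlusion mask
identically:

``block``
    Predetermined rectangular blocks on a (rows, cols) grid.
``r_dispersion``
    A uniformly random partition of positions into m equal groups,
    irrespective of bit values.
``z_dispersion``
    Value-homogeneous groups: positions holding 0s are spread over m/2
    partials and positions holding 1s over the other m/2, so every partial
    contains only 0s or only 1s.

Dispersed schemes are deterministic functions of their RNG seed.  The
round-trip :func:`reassemble` is the shared correctness oracle: dividing and
reassembling must reproduce the template exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .templates import PartialTemplate, Template, TemplateError

__all__ = [
    "DivisionScheme",
    "SCHEME_KINDS",
    "default_block_grid",
    "divide",
    "divide_block",
    "divide_r_dispersion",
    "divide_z_dispersion",
    "reassemble",
]

SCHEME_KINDS = ("block", "r_dispersion", "z_dispersion")


@dataclass(frozen=True)
class DivisionScheme:
    """How to split a template into ``m`` partial templates."""

    kind: str
    m: int
    block_grid: tuple[int, int] | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in SCHEME_KINDS:
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.block_grid is not None:
            gr, gc = self.block_grid
            if gr * gc != self.m:
                raise ValueError(
                    f"block grid {self.block_grid} has {gr * gc} blocks, m={self.m}"
                )


def default_block_grid(m: int, shape: tuple[int, int]) -> tuple[int, int]:
    """A (rows, cols) block grid for m partials: column bands when possible.

    Column bands (grid (1, m)) respect the row-circular topology used by
    rotation; other factorizations are tried only if m does not divide q2.
    """
    q1, q2 = shape
    if q2 % m == 0:
        return (1, m)
    for gr in range(1, m + 1):
        if m % gr == 0:
            gc = m // gr
            if q1 % gr == 0 and q2 % gc == 0:
                return (gr, gc)
    raise ValueError(f"no block grid with {m} blocks divides shape {shape}")


def divide(template: Template, scheme: DivisionScheme) -> list[PartialTemplate]:
    """Dispatch to the scheme-specific division function."""
    if scheme.kind == "block":
        grid = scheme.block_grid or default_block_grid(scheme.m, template.shape)
        return divide_block(template, grid)
    if scheme.kind == "r_dispersion":
        return divide_r_dispersion(template, scheme.m, scheme.rng_seed)
    return divide_z_dispersion(template, scheme.m, scheme.rng_seed)


def divide_block(template: Template, grid: tuple[int, int]) -> list[PartialTemplate]:
    """Split into rows*cols contiguous rectangular blocks."""
    q1, q2 = template.shape
    gr, gc = grid
    if gr < 1 or gc < 1 or q1 % gr or q2 % gc:
        raise ValueError(f"grid {grid} does not divide template shape {template.shape}")
    h, w = q1 // gr, q2 // gc
    partials = []
    for br in range(gr):
        for bc in range(gc):
            rows = np.arange(br * h, (br + 1) * h)
            cols = np.arange(bc * w, (bc + 1) * w)
            rr, cc = np.meshgrid(rows, cols, indexing="ij")
            positions = np.column_stack([rr.ravel(), cc.ravel()])
            partials.append(PartialTemplate.from_template(template, positions))
    return partials


def _positions_from_linear(linear: np.ndarray, q2: int) -> np.ndarray:
    return np.column_stack([linear // q2, linear % q2])


def divide_r_dispersion(
    template: Template, m: int, rng_seed=None
) -> list[PartialTemplate]:
    """Randomly partition all positions into m equal groups."""
    n = template.n_bits
    if m < 1 or n % m:
        raise ValueError(f"m={m} does not divide the {n}-bit lattice evenly")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    q2 = template.shape[1]
    return [
        PartialTemplate.from_template(
            template, _positions_from_linear(group, q2)
        )
        for group in perm.reshape(m, n // m)
    ]


def divide_z_dispersion(
    template: Template, m: int, rng_seed=None
) -> list[PartialTemplate]:
    """Partition into value-homogeneous groups (each partial all-0 or all-1).

    The 0-positions are shuffled and split as evenly as possible over m/2
    partials, the 1-positions over the other m/2, so ``m`` must be even and
    the template must hold at least m/2 zeros and m/2 ones.
    """
    if m < 2 or m % 2:
        raise ValueError(f"z-dispersion needs an even m >= 2, got {m}")
    flat = template.phase.ravel()
    zeros = np.flatnonzero(flat == 0)
    ones = np.flatnonzero(flat == 1)
    if len(zeros) < m // 2 or len(ones) < m // 2:
        raise ValueError(
            f"template has {len(zeros)} zeros / {len(ones)} ones; "
            f"cannot fill {m // 2} homogeneous partials of each value"
        )
    rng = np.random.default_rng(rng_seed)
    zeros = rng.permutation(zeros)
    ones = rng.permutation(ones)
    q2 = template.shape[1]
    groups = list(np.array_split(zeros, m // 2)) + list(np.array_split(ones, m // 2))
    return [
        PartialTemplate.from_template(template, _positions_from_linear(g, q2))
        for g in groups
    ]


def reassemble(partials: list[PartialTemplate]) -> Template:
    """Rebuild the original template from a full set of partials.

    Raises
    ------
    TemplateError
        If the partials' positions overlap or do not cover the lattice.
    """
    if not partials:
        raise TemplateError("no partial templates given")
    shape = partials[0].origin_shape
    if any(p.origin_shape != shape for p in partials):
        raise TemplateError("partial templates disagree on the origin shape")
    phase = np.zeros(shape, dtype=np.uint8)
    mask = np.zeros(shape, dtype=np.uint8)
    seen = np.zeros(shape, dtype=np.int32)
    for p in partials:
        r, c = p.positions[:, 0], p.positions[:, 1]
        phase[r, c] = p.values
        mask[r, c] = p.mask_values
        seen[r, c] += 1
    if (seen > 1).any():
        raise TemplateError("partial templates overlap")
    if (seen == 0).any():
        raise TemplateError("partial templates do not cover the lattice")
    return Template(phase, mask)
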