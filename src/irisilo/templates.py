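"""Core data types for binary phase-code templates.

A template is a pair ``(C, M)``: a ``q1 x q2`` array of phase bits ``C`` and a
same-shape occlusion mask ``M`` (1 = usable bit, 0 = occluded/damaged).  The
default geometry, 8 rows by 128 columns, is the real (or imaginary) channel of
a Gabor-type iris code.  Rows are circular: the first and last columns are
horizontally adjacent, which is why at least three columns are required (a
two-column row would duplicate its single horizontal edge).

Internally every coordinate is a 0-based ``(row, col)`` pair.  The 1-based
column-major linear index conventional in the lattice-model literature is
provided by :func:`univariate_index` / :func:`univariate_position` so that any
position quoted in that notation can be checked directly.

Bits are stored as ``{0, 1}``; the spin convention ``{-1, +1}`` used by the
Ising machinery is an explicit view (:func:`to_spin` / :func:`from_spin`), with
``0 <-> -1`` and ``1 <-> +1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Template",
    "SpinView",
    "PartialTemplate",
    "TemplateError",
    "ParseError",
    "to_spin",
    "from_spin",
    "univariate_index",
    "univariate_position",
    "read_template",
    "write_template",
    "read_partial",
    "write_partial",
]


class TemplateError(ValueError):
    """Invalid template data (shape, value range, or position bookkeeping)."""


class ParseError(TemplateError):
    """A template or partial-template file could not be parsed."""


def _bit_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind not in "biuf":
        raise TemplateError(f"{name} must be numeric, got dtype {arr.dtype}")
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise TemplateError(f"{name} entries must all be 0 or 1")
    out = arr.astype(np.uint8)
    out.setflags(write=False)
    return out


@dataclass(frozen=True, eq=False)
class Template:
    """Binary phase code plus occlusion mask.

    Parameters
    ----------
    phase
        2-D array of bits in ``{0, 1}``.
    mask
        Same-shape array of bits; 1 marks a valid bit.  ``None`` means
        "no occlusion" (all-valid).
    """

    phase: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        phase = _bit_array(self.phase, "phase")
        if phase.ndim != 2:
            raise TemplateError("phase must be a 2-D array")
        q1, q2 = phase.shape
        if q1 < 1 or q2 < 3:
            raise TemplateError(
                f"template shape must be at least 1 x 3, got {q1} x {q2}"
            )
        if self.mask is None:
            mask = np.ones_like(phase)
            mask.setflags(write=False)
        else:
            mask = _bit_array(self.mask, "mask")
            if mask.shape != phase.shape:
                raise TemplateError(
                    f"mask shape {mask.shape} != phase shape {phase.shape}"
                )
        object.__setattr__(self, "phase", phase)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape

    @property
    def n_bits(self) -> int:
        """Total bit count N = q1 * q2."""
        return self.phase.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, Template):
            return NotImplemented
        return np.array_equal(self.phase, other.phase) and np.array_equal(
            self.mask, other.mask
        )


@dataclass(frozen=True, eq=False)
class SpinView:
    """A template's phase bits in the spin convention {-1, +1}."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise TemplateError("spin values must be a 2-D array")
        if arr.size and not np.isin(arr, (-1, 1)).all():
            raise TemplateError("spin values must all be -1 or +1")
        arr = arr.astype(np.int8)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpinView):
            return NotImplemented
        return np.array_equal(self.values, other.values)


def to_spin(template: Template) -> SpinView:
    """Map phase bits to spins, 0 -> -1 and 1 -> +1."""
    return SpinView(template.phase.astype(np.int8) * 2 - 1)


def from_spin(view: SpinView, mask: np.ndarray | None = None) -> Template:
    """Inverse of :func:`to_spin`; the mask defaults to all-valid."""
    bits = ((view.values.astype(np.int8) + 1) // 2).astype(np.uint8)
    return Template(bits, mask)


def univariate_index(i: int, j: int, q1: int, q2: int | None = None) -> int:
    """1-based column-major linear index ``k = i + (j - 1) * q1``.

    ``i`` is the 1-based row, ``j`` the 1-based column.  The upper bound on
    ``j`` is checked only when ``q2`` is given.
    """
    if q1 < 1:
        raise TemplateError(f"q1 must be positive, got {q1}")
    if not 1 <= i <= q1:
        raise TemplateError(f"row index {i} outside 1..{q1}")
    if j < 1 or (q2 is not None and j > q2):
        raise TemplateError(f"column index {j} out of range")
    return i + (j - 1) * q1


def univariate_position(k: int, q1: int) -> tuple[int, int]:
    """Inverse of :func:`univariate_index`: 1-based ``k`` to 1-based ``(i, j)``."""
    if q1 < 1:
        raise TemplateError(f"q1 must be positive, got {q1}")
    if k < 1:
        raise TemplateError(f"linear index {k} must be >= 1")
    i = (k - 1) % q1 + 1
    j = (k - 1) // q1 + 1
    return i, j


@dataclass(frozen=True, eq=False)
class PartialTemplate:
    """Bits of a template restricted to a position set on the original lattice.

    Three ingredients are kept together: the bit values, the mask bits divided
    identically, and the entry positions on the original lattice (0-based
    ``(row, col)`` pairs), plus the originating shape so the partial can be
    placed back.
    """

    origin_shape: tuple[int, int]
    positions: np.ndarray
    values: np.ndarray
    mask_values: np.ndarray

    def __post_init__(self) -> None:
        q1, q2 = (int(v) for v in self.origin_shape)
        if q1 < 1 or q2 < 3:
            raise TemplateError(f"origin shape must be at least 1 x 3, got {q1} x {q2}")
        pos = np.asarray(self.positions, dtype=np.int64)
        if pos.size == 0:
            pos = pos.reshape(0, 2)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise TemplateError("positions must be an (n, 2) array of (row, col)")
        if pos.size:
            if pos.min() < 0 or pos[:, 0].max() >= q1 or pos[:, 1].max() >= q2:
                raise TemplateError("positions outside the origin lattice")
            if len(np.unique(pos, axis=0)) != len(pos):
                raise TemplateError("positions must be pairwise distinct")
        values = _bit_array(self.values, "values")
        mask_values = _bit_array(self.mask_values, "mask_values")
        if values.shape != (len(pos),) or mask_values.shape != (len(pos),):
            raise TemplateError("positions, values and mask_values must align")
        pos.setflags(write=False)
        object.__setattr__(self, "origin_shape", (q1, q2))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask_values", mask_values)

    @classmethod
    def from_template(cls, template: Template, positions) -> "PartialTemplate":
        pos = np.asarray(positions, dtype=np.int64).reshape(-1, 2)
        return cls(
            template.shape,
            pos,
            template.phase[pos[:, 0], pos[:, 1]],
            template.mask[pos[:, 0], pos[:, 1]],
        )

    @property
    def spins(self) -> np.ndarray:
        """Bit values in the spin convention, as the map ``s: I -> {-1, +1}``."""
        return self.values.astype(np.int8) * 2 - 1

    def __len__(self) -> int:
        return len(self.positions)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PartialTemplate):
            return NotImplemented
        return (
            self.origin_shape == other.origin_shape
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.mask_values, other.mask_values)
        )


# --- text serialization -----------------------------------------------------
#
# Template file layout: line 1 "q1 q2", then q1 lines of q2 phase characters,
# one blank line, then q1 lines of q2 mask characters.  Partial templates are
# JSON with keys origin_shape, positions, values, mask.


def write_template(template: Template, path) -> None:
    q1, _ = template.shape
    lines = [f"{template.shape[0]} {template.shape[1]}"]
    lines += ["".join(str(b) for b in row) for row in template.phase]
    lines.append("")
    lines += ["".join(str(b) for b in row) for row in template.mask]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_bit_block(lines: list[str], start: int, q1: int, q2: int, what: str) -> np.ndarray:
    rows = []
    for r in range(q1):
        lineno = start + r + 1  # 1-based for error messages
        if start + r >= len(lines):
            raise ParseError(f"line {lineno}: truncated file, expected {what} row")
        line = lines[start + r]
        if len(line) != q2:
            raise ParseError(
                f"line {lineno}: {what} row has {len(line)} characters, expected {q2}"
            )
        bad = set(line) - {"0", "1"}
        if bad:
            raise ParseError(
                f"line {lineno}: invalid character {sorted(bad)[0]!r} in {what}"
            )
        rows.append([int(ch) for ch in line])
    return np.array(rows, dtype=np.uint8)


def read_template(path) -> Template:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError("line 1: empty file")
    header = lines[0].split()
    if len(header) != 2 or not all(tok.isdigit() for tok in header):
        raise ParseError(f"line 1: expected 'q1 q2', got {lines[0]!r}")
    q1, q2 = int(header[0]), int(header[1])
    phase = _parse_bit_block(lines, 1, q1, q2, "phase")
    sep = 1 + q1
    if sep >= len(lines) or lines[sep].strip():
        raise ParseError(f"line {sep + 1}: expected blank separator line")
    mask = _parse_bit_block(lines, sep + 1, q1, q2, "mask")
    tail = sep + 1 + q1
    if any(line.strip() for line in lines[tail:]):
        raise ParseError(f"line {tail + 1}: unexpected trailing content")
    try:
        return Template(phase, mask)
    except TemplateError as exc:  # pragma: no cover - block parser catches first
        raise ParseError(str(exc)) from exc


def write_partial(partial: PartialTemplate, path) -> None:
    doc = {
        "origin_shape": list(partial.origin_shape),
        "positions": partial.positions.tolist(),
        "values": partial.values.tolist(),
        "mask": partial.mask_values.tolist(),
    }
    Path(path).write_text(json.dumps(doc) + "\n", encoding="utf-8")


def read_partial(path) -> PartialTemplate:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}") from exc
    try:
        return PartialTemplate(
            tuple(doc["origin_shape"]), doc["positions"], doc["values"], doc["mask"]
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"missing or malformed key: {exc}") from exc
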