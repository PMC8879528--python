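"""Two-dimensional even-parity code for tablet watermark payloads.

The watermark carries an ``n_rows x n_cols`` 0/1 matrix in which the last
column holds one parity bit per row, the last row holds one parity bit per
column, and the bottom-right corner protects the parity bits themselves
(it is the parity of the row parities, which equals the parity of the
column parities for a consistent matrix).  The data area is the leading
``(n_rows-1) x (n_cols-1)`` block, filled row-major from the payload.

This simple product code detects any single bit error and locates it
uniquely (one failing row check + one failing column check), so a single
flipped cell anywhere — data, parity, or corner — can be repaired.  Two or
more errors are detected but not corrected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "BitMatrix",
    "Payload",
    "Syndrome",
    "DecodeStatus",
    "CorrectionResult",
    "encode",
    "verify",
    "correct",
    "payload_from_int",
    "payload_to_int",
    "payload_from_bitstring",
    "matrix_to_text",
    "matrix_from_text",
    "matrix_to_json",
    "matrix_from_json",
]


class SizeError(ValueError):
    """Payload length or matrix shape does not match the requested code."""


@dataclass(frozen=True)
class Payload:
    """Ordered data bits, row-major over the code's data area."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("payload bits must be 0 or 1")

    def __len__(self) -> int:
        return len(self.bits)

    def __iter__(self):
        return iter(self.bits)

    def as_int(self) -> int:
        return payload_to_int(self)


@dataclass(frozen=True)
class BitMatrix:
    """Rectangular 0/1 code matrix including its parity row/column.

    Row 0 is the top row as the code is read off the tablet face; the last
    column carries row parities, the last row column parities, and cell
    ``(n_rows-1, n_cols-1)`` is the corner parity.
    """

    cells: np.ndarray

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.uint8)
        if cells.ndim != 2:
            raise SizeError("cells must be a 2-D array")
        if cells.shape[0] < 3 or cells.shape[1] < 3:
            raise SizeError("smallest supported code is 3x3 (2x2 data)")
        if not np.isin(cells, (0, 1)).all():
            raise ValueError("cells must be 0 or 1")
        object.__setattr__(self, "cells", cells)

    @property
    def n_rows(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cells.shape[1]

    @property
    def data(self) -> np.ndarray:
        """Data block (everything except the parity row/column)."""
        return self.cells[:-1, :-1]

    @property
    def row_parity(self) -> np.ndarray:
        """Stored row-parity cells (last column, excluding corner)."""
        return self.cells[:-1, -1]

    @property
    def col_parity(self) -> np.ndarray:
        """Stored column-parity cells (last row, excluding corner)."""
        return self.cells[-1, :-1]

    @property
    def corner(self) -> int:
        return int(self.cells[-1, -1])

    def payload(self) -> Payload:
        return Payload(tuple(int(b) for b in self.data.ravel()))

    def with_flipped(self, row: int, col: int) -> "BitMatrix":
        cells = self.cells.copy()
        cells[row, col] ^= 1
        return BitMatrix(cells)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BitMatrix) and np.array_equal(self.cells, other.cells)


@dataclass(frozen=True)
class Syndrome:
    """Which parity checks fail on a received matrix."""

    failing_rows: frozenset[int]
    failing_cols: frozenset[int]
    corner_ok: bool

    @property
    def clean(self) -> bool:
        return not self.failing_rows and not self.failing_cols and self.corner_ok


class DecodeStatus(str, Enum):
    OK = "ok"
    CORRECTED = "corrected"
    FAILED = "failed"


@dataclass(frozen=True)
class CorrectionResult:
    matrix: BitMatrix
    payload: Payload | None
    status: DecodeStatus
    corrected_positions: tuple[tuple[int, int], ...] = field(default_factory=tuple)


def encode(payload: Payload | Sequence[int], n_rows: int, n_cols: int) -> BitMatrix:
    """Fill the data area row-major and append even-parity cells.

    ``payload`` must supply exactly ``(n_rows-1)*(n_cols-1)`` bits.
    """
    bits = tuple(payload.bits if isinstance(payload, Payload) else payload)
    n_data = (n_rows - 1) * (n_cols - 1)
    if len(bits) != n_data:
        raise SizeError(
            f"payload has {len(bits)} bits; a {n_rows}x{n_cols} code needs {n_data}"
        )
    data = np.array(bits, dtype=np.uint8).reshape(n_rows - 1, n_cols - 1)
    cells = np.zeros((n_rows, n_cols), dtype=np.uint8)
    cells[:-1, :-1] = data
    cells[:-1, -1] = data.sum(axis=1) % 2
    cells[-1, :-1] = data.sum(axis=0) % 2
    cells[-1, -1] = int(cells[:-1, -1].sum()) % 2
    return BitMatrix(cells)


def verify(matrix: BitMatrix) -> Syndrome:
    """Recompute every parity check against the stored cells.

    The corner is checked against both readings (parity of the stored row
    parities and of the stored column parities); either mismatch marks the
    corner check as failed.
    """
    data = matrix.data
    row_expect = data.sum(axis=1) % 2
    col_expect = data.sum(axis=0) % 2
    failing_rows = frozenset(int(r) for r in np.nonzero(row_expect != matrix.row_parity)[0])
    failing_cols = frozenset(int(c) for c in np.nonzero(col_expect != matrix.col_parity)[0])
    corner_ok = (
        matrix.corner == int(matrix.row_parity.sum()) % 2
        and matrix.corner == int(matrix.col_parity.sum()) % 2
    )
    return Syndrome(failing_rows, failing_cols, corner_ok)


def correct(matrix: BitMatrix) -> CorrectionResult:
    """Repair a single flipped cell using the 2-D parity syndrome.

    A unique single-cell explanation of the syndrome is flipped back and the
    payload returned with status ``corrected``; a clean syndrome returns
    ``ok``; anything else (>=2 errors) returns ``failed`` with no payload.
    """
    syn = verify(matrix)
    if syn.clean:
        return CorrectionResult(matrix, matrix.payload(), DecodeStatus.OK)

    nr, nc = matrix.n_rows, matrix.n_cols
    flip: tuple[int, int] | None = None
    if len(syn.failing_rows) == 1 and len(syn.failing_cols) == 1 and syn.corner_ok:
        flip = (next(iter(syn.failing_rows)), next(iter(syn.failing_cols)))
    elif len(syn.failing_rows) == 1 and not syn.failing_cols and not syn.corner_ok:
        flip = (next(iter(syn.failing_rows)), nc - 1)  # row-parity cell
    elif len(syn.failing_cols) == 1 and not syn.failing_rows and not syn.corner_ok:
        flip = (nr - 1, next(iter(syn.failing_cols)))  # column-parity cell
    elif not syn.failing_rows and not syn.failing_cols and not syn.corner_ok:
        flip = (nr - 1, nc - 1)  # corner itself

    if flip is None:
        return CorrectionResult(matrix, None, DecodeStatus.FAILED)
    fixed = matrix.with_flipped(*flip)
    if not verify(fixed).clean:  # inconsistent multi-error syndrome
        return CorrectionResult(matrix, None, DecodeStatus.FAILED)
    return CorrectionResult(fixed, fixed.payload(), DecodeStatus.CORRECTED, (flip,))


def payload_from_int(value: int, width: int) -> Payload:
    """Big-endian bit expansion of ``value`` into ``width`` bits."""
    if value < 0:
        raise ValueError("payload value must be non-negative")
    if width <= 0:
        raise ValueError("width must be positive")
    if value >= 1 << width:
        raise OverflowError(f"{value} does not fit in {width} bits")
    return Payload(tuple((value >> (width - 1 - i)) & 1 for i in range(width)))


def payload_to_int(payload: Payload) -> int:
    value = 0
    for b in payload.bits:
        value = (value << 1) | b
    return value


def payload_from_bitstring(text: str) -> Payload:
    """Parse a payload from a string of 0/1 characters (whitespace ignored)."""
    bits = tuple(int(ch) for ch in text if not ch.isspace())
    return Payload(bits)


# -- plain-text / JSON round trip -------------------------------------------

def matrix_to_text(matrix: BitMatrix) -> str:
    return "\n".join(" ".join(str(int(b)) for b in row) for row in matrix.cells) + "\n"


def matrix_from_text(text: str) -> BitMatrix:
    rows = [
        [int(tok) for tok in line.split()]
        for line in text.strip().splitlines()
        if line.strip()
    ]
    return BitMatrix(np.array(rows, dtype=np.uint8))


def matrix_to_json(matrix: BitMatrix) -> str:
    return json.dumps(
        {
            "n_rows": matrix.n_rows,
            "n_cols": matrix.n_cols,
            "cells": matrix.cells.tolist(),
        }
    )


def matrix_from_json(text: str) -> BitMatrix:
    obj = json.loads(text)
    return BitMatrix(np.array(obj["cells"], dtype=np.uint8))
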