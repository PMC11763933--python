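"""Local graph structure (LGS) encoding of connectivity matrices.

An LGS operator slides a small block over a matrix with stride 1. At
each position it evaluates a fixed ordered sequence of directed edges
between block cells: an edge emits bit 1 when (from-cell - to-cell) >= 0
and 0 otherwise. The eight bits, first edge most significant, form one
8-bit code written at the block's grid position; the result is a
"code matrix" of values in [0, 255].

The encoder consumes declarative :class:`LGSPattern` tables (see
:mod:`eeglgs.patterns`), so user-defined operators plug in without
engine changes. Only pairwise order relations of matrix entries are
used, which makes every code invariant under strictly increasing
transforms of the input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .connectivity import ConnectivityMatrix
from .exceptions import ContractError

Edge = tuple[tuple[int, int], tuple[int, int]]
EdgeGroup = tuple[tuple[Edge, ...], tuple[int, ...]]

_EXPECTED_BLOCKS = {
    "SLGS": (3, 5), "LELGS": (4, 4), "VLGS": (4, 3), "VSLGS": (5, 3),
    "ZHLGS": (3, 3), "ZHMLGS": (3, 3), "ZVLGS": (3, 3), "ZVMLGS": (3, 3),
}


@dataclass(frozen=True)
class LGSPattern:
    """One operator: block geometry plus ordered directed edges.

    ``groups`` holds one or more (edges, bit_positions) pairs; the codes
    of the groups are combined per ``combine_rule`` ("none" for a single
    8-edge group, "bitwise_or" to OR the group sub-codes). Bit positions
    are MSB-first (first edge -> bit 7).
    """

    name: str
    block_rows: int
    block_cols: int
    target_cell: tuple[int, int]
    groups: tuple[EdgeGroup, ...]
    combine_rule: str = "none"

    def __post_init__(self) -> None:
        if self.combine_rule not in ("none", "bitwise_or"):
            raise ContractError(f"unknown combine_rule {self.combine_rule!r}")
        if self.combine_rule == "none" and len(self.groups) != 1:
            raise ContractError(f"{self.name}: combine_rule 'none' needs exactly one group")
        if sum(len(g[0]) for g in self.groups) != 8:
            raise ContractError(f"{self.name}: operators must have exactly 8 edges")
        for edges, positions in self.groups:
            if len(edges) != len(positions):
                raise ContractError(f"{self.name}: edges/positions length mismatch")
            for (rf, cf), (rt, ct) in edges:
                for r, c in ((rf, cf), (rt, ct)):
                    if not (0 <= r < self.block_rows and 0 <= c < self.block_cols):
                        raise ContractError(
                            f"{self.name}: offset ({r},{c}) outside "
                            f"{self.block_rows}x{self.block_cols} block"
                        )
            if any(not 0 <= p <= 7 for p in positions):
                raise ContractError(f"{self.name}: bit positions must lie in [0,7]")
        tr, tc = self.target_cell
        if not (0 <= tr < self.block_rows and 0 <= tc < self.block_cols):
            raise ContractError(f"{self.name}: target cell outside block")

    @property
    def edges(self) -> tuple[Edge, ...]:
        """All edges across groups, in traversal order."""
        return tuple(e for edges, _ in self.groups for e in edges)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "block": [self.block_rows, self.block_cols],
            "target": list(self.target_cell),
            "groups": [
                {"edges": [[list(a), list(b)] for a, b in edges],
                 "positions": list(positions)}
                for edges, positions in self.groups
            ],
            "combine": self.combine_rule,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LGSPattern":
        return cls(
            name=d["name"],
            block_rows=int(d["block"][0]),
            block_cols=int(d["block"][1]),
            target_cell=(int(d["target"][0]), int(d["target"][1])),
            groups=tuple(
                (
                    tuple(((int(a[0]), int(a[1])), (int(b[0]), int(b[1])))
                          for a, b in g["edges"]),
                    tuple(int(p) for p in g["positions"]),
                )
                for g in d["groups"]
            ),
            combine_rule=d.get("combine", "none"),
        )


@dataclass
class CodeMatrix:
    """Grid of 8-bit LGS codes from one operator over one matrix."""

    codes: np.ndarray
    operator: str
    band: str = ""
    segment_index: int = 0
    subject_id: str = ""
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ContractError("codes must be integers")
        if self.codes.size == 0:
            raise ContractError("empty code matrix")
        if self.codes.min() < 0 or self.codes.max() > 255:
            raise ContractError("codes must lie in [0, 255]")


def builtin_patterns() -> tuple[LGSPattern, ...]:
    """The eight built-in operators in canonical (alphabetical) order."""
    from .patterns import ALL_PATTERNS

    return ALL_PATTERNS


def save_patterns(patterns, path: str | Path) -> None:
    Path(path).write_text(json.dumps([p.to_dict() for p in patterns], indent=1))


def load_patterns(path: str | Path) -> tuple[LGSPattern, ...]:
    return tuple(LGSPattern.from_dict(d) for d in json.loads(Path(path).read_text()))


def _positions(pattern: LGSPattern, bit_order: str) -> list[tuple[Edge, int]]:
    out = []
    for edges, positions in pattern.groups:
        for e, p in zip(edges, positions):
            out.append((e, p if bit_order == "msb" else 7 - p))
    return out


def encode_block(
    block: np.ndarray,
    pattern: LGSPattern,
    comparison: str = "source_minus_neighbor",
    bit_order: str = "msb",
) -> int:
    """Encode a single block into one 8-bit code.

    ``comparison`` selects the sign convention of the edge difference;
    the default compares the edge's from-cell minus its to-cell, with
    ties (difference exactly 0) encoding 1.
    """
    block = np.asarray(block, dtype=np.float64)
    if block.shape != (pattern.block_rows, pattern.block_cols):
        raise ContractError(
            f"block shape {block.shape} does not match pattern "
            f"{pattern.name} ({pattern.block_rows}x{pattern.block_cols})"
        )
    code = 0
    for ((rf, cf), (rt, ct)), pos in _positions(pattern, bit_order):
        diff = block[rf, cf] - block[rt, ct]
        if comparison == "neighbor_minus_source":
            diff = -diff
        code |= int(diff >= 0) << pos
    return code


def apply_lgs(
    cm: ConnectivityMatrix | np.ndarray,
    pattern: LGSPattern,
    stride: int = 1,
    comparison: str = "source_minus_neighbor",
    bit_order: str = "msb",
) -> CodeMatrix:
    """Slide one operator over a matrix (stride 1, fully-contained blocks).

    For an m x n input and an R x C block the output grid has shape
    ((m - R) // stride + 1) x ((n - C) // stride + 1); no padding is used.
    Vectorized over window positions: each edge contributes one shifted
    boolean comparison of the whole matrix.
    """
    if isinstance(cm, ConnectivityMatrix):
        X, meta = cm.values, cm
    else:
        X, meta = np.asarray(cm, dtype=np.float64), None
    m, n = X.shape
    R, C = pattern.block_rows, pattern.block_cols
    if m < R or n < C:
        raise ContractError(
            f"matrix {m}x{n} smaller than {pattern.name} block {R}x{C}"
        )
    out_r = (m - R) // stride + 1
    out_c = (n - C) // stride + 1
    codes = np.zeros((out_r, out_c), dtype=np.int64)
    rs = slice(None, None, stride)
    for ((rf, cf), (rt, ct)), pos in _positions(pattern, bit_order):
        A = X[rf : rf + m - R + 1, cf : cf + n - C + 1][rs, rs][:out_r, :out_c]
        B = X[rt : rt + m - R + 1, ct : ct + n - C + 1][rs, rs][:out_r, :out_c]
        diff = A - B
        if comparison == "neighbor_minus_source":
            diff = -diff
        codes |= (diff >= 0).astype(np.int64) << pos
    return CodeMatrix(
        codes=codes,
        operator=pattern.name,
        band=meta.band.name if meta is not None and meta.band is not None else "",
        segment_index=meta.segment_index if meta is not None else 0,
        subject_id=meta.subject_id if meta is not None else "",
        class_label=meta.class_label if meta is not None else None,
    )


def apply_all(
    cm: ConnectivityMatrix | np.ndarray,
    patterns: tuple[LGSPattern, ...] | None = None,
    **kwargs,
) -> list[CodeMatrix]:
    """Apply every operator (canonical alphabetical order) to one matrix."""
    if patterns is None:
        patterns = builtin_patterns()
    ordered = sorted(patterns, key=lambda p: p.name)
    return [apply_lgs(cm, p, **kwargs) for p in ordered]
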