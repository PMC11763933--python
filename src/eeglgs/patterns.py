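"""Declarative edge tables for the eight local graph structure operators.

Each operator is a small block of cells with an ordered list of directed
edges between cell offsets. Encoding compares the two endpoint values of
each edge and emits one bit, so the tables below fully determine the
operator; the engine in :mod:`eeglgs.lgs` never special-cases a name.

Offsets are (row, col) within the block, 0-indexed from the top-left.
Bit positions are given MSB-first: the first edge traversed contributes
bit 7 of the 8-bit code. Operators whose published diagrams build two
sub-codes (LELGS) list two edge groups whose codes are OR-combined.

The geometry (block shape, target cell, traversal style) follows the
published descriptions of these descriptors; the exact arrow sequences
are a transcription of the diagrams and are the authoritative definition
used by this package.
"""

from __future__ import annotations

from .lgs import LGSPattern

# Symmetric LGS: 3x5 block, target at the centre. Four edges loop
# counterclockwise through the left diamond, four clockwise through the
# right diamond; left nibble is the high nibble of the code.
SLGS = LGSPattern(
    name="SLGS",
    block_rows=3,
    block_cols=5,
    target_cell=(1, 2),
    groups=(
        (
            (((1, 2), (0, 1)), ((0, 1), (1, 0)), ((1, 0), (2, 1)), ((2, 1), (1, 2)),
             ((1, 2), (0, 3)), ((0, 3), (1, 4)), ((1, 4), (2, 3)), ((2, 3), (1, 2))),
            (7, 6, 5, 4, 3, 2, 1, 0),
        ),
    ),
    combine_rule="none",
)

# Logically extended LGS: 4x4 block; a vertical chain and a horizontal
# chain each yield a 4-bit sub-code (placed in the high / low nibble)
# and the two sub-codes are combined with bitwise OR.
LELGS = LGSPattern(
    name="LELGS",
    block_rows=4,
    block_cols=4,
    target_cell=(1, 1),
    groups=(
        (
            (((0, 1), (1, 1)), ((1, 1), (2, 1)), ((2, 1), (3, 1)), ((3, 1), (0, 1))),
            (7, 6, 5, 4),
        ),
        (
            (((1, 0), (1, 1)), ((1, 1), (1, 2)), ((1, 2), (1, 3)), ((1, 3), (1, 0))),
            (3, 2, 1, 0),
        ),
    ),
    combine_rule="bitwise_or",
)

# Vertical LGS: 4x3 block, a single directed walk sweeping the block
# top-to-bottom and returning toward the target.
VLGS = LGSPattern(
    name="VLGS",
    block_rows=4,
    block_cols=3,
    target_cell=(1, 1),
    groups=(
        (
            (((1, 1), (0, 1)), ((0, 1), (1, 0)), ((1, 0), (2, 0)), ((2, 0), (3, 0)),
             ((3, 0), (2, 1)), ((2, 1), (3, 1)), ((3, 1), (2, 2)), ((2, 2), (1, 1))),
            (7, 6, 5, 4, 3, 2, 1, 0),
        ),
    ),
    combine_rule="none",
)

# Vertical symmetric LGS: 5x3 block, the transposed analogue of SLGS —
# counterclockwise through the upper diamond, clockwise through the lower.
VSLGS = LGSPattern(
    name="VSLGS",
    block_rows=5,
    block_cols=3,
    target_cell=(2, 1),
    groups=(
        (
            (((2, 1), (1, 0)), ((1, 0), (0, 1)), ((0, 1), (1, 2)), ((1, 2), (2, 1)),
             ((2, 1), (3, 0)), ((3, 0), (4, 1)), ((4, 1), (3, 2)), ((3, 2), (2, 1))),
            (7, 6, 5, 4, 3, 2, 1, 0),
        ),
    ),
    combine_rule="none",
)

# Zigzag horizontal LGS: 3x3 block, zigzag walk alternating between the
# top two rows while moving right, then sweeping the bottom row back.
ZHLGS = LGSPattern(
    name="ZHLGS",
    block_rows=3,
    block_cols=3,
    target_cell=(0, 0),
    groups=(
        (
            (((0, 0), (1, 0)), ((1, 0), (0, 1)), ((0, 1), (1, 1)), ((1, 1), (0, 2)),
             ((0, 2), (1, 2)), ((1, 2), (2, 2)), ((2, 2), (2, 1)), ((2, 1), (2, 0))),
            (7, 6, 5, 4, 3, 2, 1, 0),
        ),
    ),
    combine_rule="none",
)

# Zigzag horizontal middle LGS: as ZHLGS but the walk starts from the
# central cell of the block.
ZHMLGS = LGSPattern(
    name="ZHMLGS",
    block_rows=3,
    block_cols=3,
    target_cell=(1, 1),
    groups=(
        (
            (((1, 1), (1, 0)), ((1, 0), (0, 0)), ((0, 0), (0, 1)), ((0, 1), (0, 2)),
             ((0, 2), (1, 2)), ((1, 2), (2, 2)), ((2, 2), (2, 1)), ((2, 1), (2, 0))),
            (7, 6, 5, 4, 3, 2, 1, 0),
        ),
    ),
    combine_rule="none",
)

# Zigzag vertical LGS: transpose of ZHLGS (zigzag down the left columns,
# sweep the right column back up).
ZVLGS = LGSPattern(
    name="ZVLGS",
    block_rows=3,
    block_cols=3,
    target_cell=(0, 0),
    groups=(
        (
            (((0, 0), (0, 1)), ((0, 1), (1, 0)), ((1, 0), (1, 1)), ((1, 1), (2, 0)),
             ((2, 0), (2, 1)), ((2, 1), (2, 2)), ((2, 2), (1, 2)), ((1, 2), (0, 2))),
            (7, 6, 5, 4, 3, 2, 1, 0),
        ),
    ),
    combine_rule="none",
)

# Zigzag vertical middle LGS: transpose of ZHMLGS, starting at the
# central cell.
ZVMLGS = LGSPattern(
    name="ZVMLGS",
    block_rows=3,
    block_cols=3,
    target_cell=(1, 1),
    groups=(
        (
            (((1, 1), (0, 1)), ((0, 1), (0, 0)), ((0, 0), (1, 0)), ((1, 0), (2, 0)),
             ((2, 0), (2, 1)), ((2, 1), (2, 2)), ((2, 2), (1, 2)), ((1, 2), (0, 2))),
            (7, 6, 5, 4, 3, 2, 1, 0),
        ),
    ),
    combine_rule="none",
)

#: Canonical (alphabetical) operator order; fixes feature column order.
ALL_PATTERNS: tuple[LGSPattern, ...] = (
    LELGS, SLGS, VLGS, VSLGS, ZHLGS, ZHMLGS, ZVLGS, ZVMLGS,
)
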