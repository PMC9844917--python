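"""QR module-matrix construction: function patterns, data placement, masking.

A matrix is a list of rows of ints (0 light, 1 dark). Function modules
(finders, separators, timing, alignment, format/version areas, dark module)
are tracked in a parallel boolean mask so data placement can skip them; the
same placement generator drives both writing (encode) and reading (decode).
"""

from __future__ import annotations

from .tables import (
    ALIGNMENT_POSITIONS,
    format_info_bits,
    version_info_bits,
)

__all__ = [
    "symbol_size",
    "build_base_matrix",
    "data_module_coords",
    "place_data",
    "apply_mask",
    "mask_value",
    "write_format_info",
    "format_info_coords",
    "penalty_score",
]


def symbol_size(version: int) -> int:
    return 17 + 4 * version


def _place_finder(mat, func, row, col):
    for r in range(-1, 8):
        for c in range(-1, 8):
            rr, cc = row + r, col + c
            if 0 <= rr < len(mat) and 0 <= cc < len(mat):
                inside = 0 <= r <= 6 and 0 <= c <= 6
                ring = inside and (r in (0, 6) or c in (0, 6))
                core = inside and 2 <= r <= 4 and 2 <= c <= 4
                mat[rr][cc] = 1 if (ring or core) else 0
                func[rr][cc] = True


def build_base_matrix(version: int) -> tuple[list[list[int]], list[list[bool]]]:
    """Matrix with all function patterns placed and format/version areas
    reserved (format bits themselves are written after masking)."""
    n = symbol_size(version)
    mat = [[0] * n for _ in range(n)]
    func = [[False] * n for _ in range(n)]

    _place_finder(mat, func, 0, 0)
    _place_finder(mat, func, 0, n - 7)
    _place_finder(mat, func, n - 7, 0)

    # timing patterns
    for i in range(8, n - 8):
        v = 1 - (i % 2)
        for rr, cc in ((6, i), (i, 6)):
            mat[rr][cc] = v
            func[rr][cc] = True

    # alignment patterns (skip any overlapping a finder)
    centers = ALIGNMENT_POSITIONS[version]
    for r in centers:
        for c in centers:
            # skip the three corners occupied by finder patterns
            if (r < 9 and c < 9) or (r < 9 and c > n - 10) or (r > n - 10 and c < 9):
                continue
            for dr in range(-2, 3):
                for dc in range(-2, 3):
                    dark = max(abs(dr), abs(dc)) != 1
                    mat[r + dr][c + dc] = 1 if dark else 0
                    func[r + dr][c + dc] = True

    # reserve format information areas
    for a, b in format_info_coords(n):
        func[a[0]][a[1]] = True
        func[b[0]][b[1]] = True

    # dark module
    mat[n - 8][8] = 1
    func[n - 8][8] = True

    # version information (versions >= 7), two 6x3 blocks
    if version >= 7:
        bits = version_info_bits(version)
        for i in range(18):
            bit = (bits >> i) & 1
            r, c = i // 3, n - 11 + i % 3
            mat[r][c] = bit
            func[r][c] = True
            mat[c][r] = bit
            func[c][r] = True
    return mat, func


def format_info_coords(n: int) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """For each of the 15 format bits (MSB first), its two module positions."""
    coords = []
    # copy 1 around the top-left finder, bit 14 first
    copy1 = (
        [(8, c) for c in range(0, 6)] + [(8, 7), (8, 8), (7, 8)]
        + [(r, 8) for r in range(5, -1, -1)]
    )
    # copy 2: right of top row / bottom of left column
    copy2 = [(r, 8) for r in range(n - 1, n - 8, -1)] + [
        (8, c) for c in range(n - 8, n)
    ]
    for a, b in zip(copy1, copy2):
        coords.append((a, b))
    return coords


def write_format_info(mat, n: int, level: str, mask: int) -> None:
    bits = format_info_bits(level, mask)
    for i, (a, b) in enumerate(format_info_coords(n)):
        bit = (bits >> (14 - i)) & 1
        mat[a[0]][a[1]] = bit
        mat[b[0]][b[1]] = bit


def data_module_coords(n: int, func) -> list[tuple[int, int]]:
    """Placement order: two-module columns, right to left, serpentine
    vertical scan, skipping the vertical timing column and function modules."""
    coords = []
    col = n - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(n - 1, -1, -1) if upward else range(n)
        for r in rows:
            for c in (col, col - 1):
                if not func[r][c]:
                    coords.append((r, c))
        upward = not upward
        col -= 2
    return coords


def place_data(mat, func, bitstream: str) -> None:
    coords = data_module_coords(len(mat), func)
    if len(bitstream) > len(coords):
        raise ValueError("bitstream longer than data capacity")
    for (r, c), bit in zip(coords, bitstream):
        mat[r][c] = int(bit)


def mask_value(mask: int, r: int, c: int) -> bool:
    if mask == 0:
        return (r + c) % 2 == 0
    if mask == 1:
        return r % 2 == 0
    if mask == 2:
        return c % 3 == 0
    if mask == 3:
        return (r + c) % 3 == 0
    if mask == 4:
        return (r // 2 + c // 3) % 2 == 0
    if mask == 5:
        return (r * c) % 2 + (r * c) % 3 == 0
    if mask == 6:
        return ((r * c) % 2 + (r * c) % 3) % 2 == 0
    if mask == 7:
        return ((r + c) % 2 + (r * c) % 3) % 2 == 0
    raise ValueError(f"mask {mask} out of range")


def apply_mask(mat, func, mask: int) -> None:
    """XOR the mask over data modules; involutory, so also unmasks."""
    n = len(mat)
    for r in range(n):
        for c in range(n):
            if not func[r][c] and mask_value(mask, r, c):
                mat[r][c] ^= 1


def penalty_score(mat) -> int:
    """Standard four-rule penalty used to pick the mask pattern."""
    n = len(mat)
    score = 0

    # rule 1: runs of >= 5 same-coloured modules, rows and columns
    for line in mat:
        score += _run_penalty(line)
    for c in range(n):
        score += _run_penalty([mat[r][c] for r in range(n)])

    # rule 2: 2x2 blocks of one colour
    for r in range(n - 1):
        for c in range(n - 1):
            if mat[r][c] == mat[r][c + 1] == mat[r + 1][c] == mat[r + 1][c + 1]:
                score += 3

    # rule 3: finder-like 1011101 pattern with 4 light modules on either side
    pat1 = [1, 0, 1, 1, 1, 0, 1, 0, 0, 0, 0]
    pat2 = pat1[::-1]
    for r in range(n):
        row = mat[r]
        col = [mat[i][r] for i in range(n)]
        for i in range(n - 10):
            if row[i : i + 11] in (pat1, pat2):
                score += 40
            if col[i : i + 11] in (pat1, pat2):
                score += 40

    # rule 4: dark-module proportion deviation from 50%
    dark = sum(sum(row) for row in mat)
    pct = dark * 100 / (n * n)
    score += int(abs(pct - 50) // 5) * 10
    return score


def _run_penalty(line) -> int:
    score = 0
    run = 1
    for i in range(1, len(line)):
        if line[i] == line[i - 1]:
            run += 1
        else:
            if run >= 5:
                score += 3 + run - 5
            run = 1
    if run >= 5:
        score += 3 + run - 5
    return score
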