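"""QR symbol reading for clean, axis-aligned images (as produced by
:mod:`ddqr.qr.encode` or any conformant generator; photographic distortions
such as perspective or rotation are out of scope).

Pipeline: grayscale + threshold -> locate the three finder patterns by
1:1:3:1:1 run-length scanning -> fit the sampling grid -> read and
BCH-validate the format information -> unmask -> de-interleave codewords ->
Reed-Solomon error correction -> byte-mode segment parse.
"""

from __future__ import annotations

import io

import numpy as np
from PIL import Image

from ..errors import AmbiguousSymbolError, NoSymbolError, QrDecodeError
from . import matrix as M
from . import tables as T
from .gf256 import rs_correct_block

__all__ = ["read_qr", "read_matrix"]


def _binarize(image_bytes: bytes) -> np.ndarray:
    img = Image.open(io.BytesIO(image_bytes)).convert("L")
    arr = np.asarray(img, dtype=np.uint8)
    lo, hi = int(arr.min()), int(arr.max())
    if hi - lo < 32:  # blank or near-blank image: nothing to find
        return np.zeros_like(arr, dtype=bool)
    return arr < (lo + hi) / 2  # True = dark


def _finder_candidates_in_line(line: np.ndarray) -> list[tuple[float, float]]:
    """(centre, module_size) for every 1:1:3:1:1 dark/light run pattern."""
    out = []
    n = len(line)
    runs = []  # (value, start, length)
    i = 0
    while i < n:
        j = i
        while j < n and line[j] == line[i]:
            j += 1
        runs.append((bool(line[i]), i, j - i))
        i = j
    for k in range(len(runs) - 4):
        window = runs[k : k + 5]
        if not (window[0][0] and not window[1][0] and window[2][0]
                and not window[3][0] and window[4][0]):
            continue
        sizes = [w[2] for w in window]
        unit = sum(sizes) / 7.0
        ok = (
            abs(sizes[0] - unit) < 0.75 * unit
            and abs(sizes[1] - unit) < 0.75 * unit
            and abs(sizes[2] - 3 * unit) < 1.5 * unit
            and abs(sizes[3] - unit) < 0.75 * unit
            and abs(sizes[4] - unit) < 0.75 * unit
        )
        if ok:
            centre = window[2][1] + window[2][2] / 2.0
            out.append((centre, unit))
    return out


def _locate_finders(dark: np.ndarray) -> list[tuple[float, float, float]]:
    """Return (row, col, module_size) for each finder pattern centre."""
    h, w = dark.shape
    hits: list[tuple[float, float, float]] = []
    for r in range(h):
        for cx, unit in _finder_candidates_in_line(dark[r]):
            # confirm vertically through the candidate centre
            col = dark[:, int(round(cx))]
            for cy, vunit in _finder_candidates_in_line(col):
                if abs(cy - r) <= 2 * vunit and abs(vunit - unit) < 0.5 * max(
                    vunit, unit
                ):
                    u = (unit + vunit) / 2.0
                    if _diagonal_check(dark, cy, cx, u) and _template_check(
                        dark, cy, cx, u
                    ):
                        hits.append((cy, cx, u))
                    break
    # cluster by proximity
    centres: list[list[float]] = []  # [row_sum, col_sum, unit_sum, count]
    for r, c, u in hits:
        for cl in centres:
            if abs(cl[0] / cl[3] - r) < 3 * u and abs(cl[1] / cl[3] - c) < 3 * u:
                cl[0] += r
                cl[1] += c
                cl[2] += u
                cl[3] += 1
                break
        else:
            centres.append([r, c, u, 1])
    # a real finder core is ~3 modules tall, so it is re-detected on many rows
    return [
        (cl[0] / cl[3], cl[1] / cl[3], cl[2] / cl[3])
        for cl in centres
        if cl[3] >= max(2.0, 1.5 * cl[2] / cl[3])
    ]


def _diagonal_check(dark: np.ndarray, cy: float, cx: float, unit: float) -> bool:
    """Require the 1:1:3:1:1 pattern along the main diagonal as well."""
    h, w = dark.shape
    half = int(round(4.5 * unit))
    ys = np.arange(-half, half + 1) + int(round(cy))
    xs = np.arange(-half, half + 1) + int(round(cx))
    keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    line = dark[ys[keep], xs[keep]]
    off = int(np.argmax(keep))  # leading out-of-image samples dropped
    centre_idx = half - off
    for c, u in _finder_candidates_in_line(line):
        if abs(c - centre_idx) <= 1.5 * u:
            return True
    return False


def _template_check(dark: np.ndarray, cy: float, cx: float, unit: float) -> bool:
    """Sample the full 7x7 finder template: dark ring, light ring, dark core."""
    h, w = dark.shape
    for i in range(7):
        for j in range(7):
            y = int(round(cy + (i - 3) * unit))
            x = int(round(cx + (j - 3) * unit))
            if not (0 <= y < h and 0 <= x < w):
                return False
            ring = i in (0, 6) or j in (0, 6)
            core = 2 <= i <= 4 and 2 <= j <= 4
            if bool(dark[y, x]) != (ring or core):
                return False
    return True


def read_matrix(image_bytes: bytes) -> list[list[int]]:
    """Sample the module matrix out of an image."""
    dark = _binarize(image_bytes)
    finders = _locate_finders(dark)
    if len(finders) < 3:
        raise NoSymbolError(f"found {len(finders)} finder patterns, need 3")
    if len(finders) > 3:
        raise AmbiguousSymbolError(
            f"found {len(finders)} finder patterns; more than one symbol?"
        )
    # assign corners (axis-aligned geometry)
    by_sum = sorted(finders, key=lambda f: f[0] + f[1])
    tl = by_sum[0]
    rest = by_sum[1:]
    tr = max(rest, key=lambda f: f[1] - f[0])
    bl = max(rest, key=lambda f: f[0] - f[1])
    if tr is bl:
        raise NoSymbolError("finder patterns do not form a symbol corner set")
    unit = (tl[2] + tr[2] + bl[2]) / 3.0
    span = ((tr[1] - tl[1]) + (bl[0] - tl[0])) / 2.0
    dim_est = span / unit + 7
    version = max(1, min(40, int(round((dim_est - 17) / 4))))
    n = M.symbol_size(version)
    # module steps from the finder-centre span (centres sit 3.5 modules in)
    step_c = (tr[1] - tl[1]) / (n - 7)
    step_r = (bl[0] - tl[0]) / (n - 7)
    if step_c <= 0 or step_r <= 0:
        raise NoSymbolError("degenerate finder geometry")
    h, w = dark.shape
    mat = [[0] * n for _ in range(n)]
    for r in range(n):
        y = tl[0] + (r - 3) * step_r
        for c in range(n):
            x = tl[1] + (c - 3) * step_c
            yi, xi = int(round(y)), int(round(x))
            if not (0 <= yi < h and 0 <= xi < w):
                raise NoSymbolError("symbol extends outside the image")
            mat[r][c] = 1 if dark[yi, xi] else 0
    return mat


def _read_format(mat) -> tuple[str, int]:
    n = len(mat)
    coords = M.format_info_coords(n)
    for which in (0, 1):
        bits = 0
        for i, pair in enumerate(coords):
            r, c = pair[which]
            bits |= mat[r][c] << (14 - i)
        best = None
        for cw, (level, mask) in T.FORMAT_CODEWORDS.items():
            d = bin(bits ^ cw).count("1")
            if best is None or d < best[0]:
                best = (d, level, mask)
        if best and best[0] <= 3:
            return best[1], best[2]
    raise QrDecodeError("format information unreadable")


def _deinterleave(codewords: list[int], version: int, level: str):
    ec_per_block, groups = T.block_structure(version, level)
    sizes = [k for n_b, k in groups for _ in range(n_b)]
    blocks: list[list[int]] = [[] for _ in sizes]
    it = iter(codewords)
    for i in range(max(sizes)):
        for b, k in zip(blocks, sizes):
            if i < k:
                b.append(next(it))
    ec_blocks: list[list[int]] = [[] for _ in sizes]
    for _ in range(ec_per_block):
        for e in ec_blocks:
            e.append(next(it))
    return blocks, ec_blocks, ec_per_block


def _parse_byte_mode(bits: str, version: int) -> str:
    pos = 0
    out = bytearray()
    while pos + 4 <= len(bits):
        mode = bits[pos : pos + 4]
        pos += 4
        if mode == "0000" or not mode:  # terminator
            break
        if mode != "0100":
            raise QrDecodeError(f"unsupported segment mode {mode!r}")
        count_bits = 8 if version <= 9 else 16
        count = int(bits[pos : pos + count_bits], 2)
        pos += count_bits
        if pos + 8 * count > len(bits):
            raise QrDecodeError("segment length exceeds data stream")
        for i in range(count):
            out.append(int(bits[pos : pos + 8], 2))
            pos += 8
    return out.decode("latin-1")


def read_qr(image_bytes: bytes) -> str:
    """Decode the textual payload of the single QR symbol in an image.

    Raises NoSymbolError when no symbol is found, AmbiguousSymbolError when
    more than one is present, and QrDecodeError when a located symbol cannot
    be decoded.
    """
    mat = read_matrix(image_bytes)
    n = len(mat)
    version = (n - 17) // 4
    level, mask = _read_format(mat)

    _, func = M.build_base_matrix(version)
    work = [row[:] for row in mat]
    M.apply_mask(work, func, mask)
    coords = M.data_module_coords(n, func)
    bits = "".join(str(work[r][c]) for r, c in coords)
    n_cw = T.total_codewords(version)
    codewords = [int(bits[8 * i : 8 * i + 8], 2) for i in range(n_cw)]

    blocks, ec_blocks, n_ec = _deinterleave(codewords, version, level)
    data: list[int] = []
    for b, e in zip(blocks, ec_blocks):
        try:
            corrected = rs_correct_block(b + e, n_ec)
        except ValueError as exc:
            raise QrDecodeError(f"uncorrectable block: {exc}") from exc
        data.extend(corrected[: len(b)])
    stream = "".join(format(cw, "08b") for cw in data)
    return _parse_byte_mode(stream, version)
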