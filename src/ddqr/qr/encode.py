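"""QR symbol generation: byte-mode segmentation, block interleaving, masking,
and PNG rendering via Pillow."""

from __future__ import annotations

import io
from dataclasses import dataclass

from PIL import Image

from ..errors import CapacityExceededError
from . import matrix as M
from . import tables as T
from .gf256 import rs_encode_block

__all__ = ["QrRenderConfig", "build_symbol", "render_qr"]


@dataclass(frozen=True)
class QrRenderConfig:
    """Rendering parameters.

    error_correction: L/M/Q/H recovery level (default M, the common
    density/robustness compromise). module_pixel_size: square pixels per
    module. border_modules: quiet-zone width (the symbology requires >= 4
    for reliable scanning).
    """

    error_correction: str = "M"
    module_pixel_size: int = 10
    border_modules: int = 4
    image_format: str = "PNG"

    def __post_init__(self):
        if self.error_correction not in T.EC_LEVELS:
            raise ValueError(f"error_correction must be one of {T.EC_LEVELS}")
        if self.module_pixel_size < 1:
            raise ValueError("module_pixel_size must be positive")
        if self.border_modules < 0:
            raise ValueError("border_modules must be non-negative")


def _choose_version(n_bytes: int, level: str) -> int:
    for v in range(1, 41):
        if T.byte_mode_capacity(v, level) >= n_bytes:
            return v
    raise CapacityExceededError(n_bytes, T.byte_mode_capacity(40, level), level)


def _data_bitstream(payload: bytes, version: int, level: str) -> str:
    count_bits = 8 if version <= 9 else 16
    bits = "0100" + format(len(payload), f"0{count_bits}b")
    bits += "".join(format(b, "08b") for b in payload)
    capacity = 8 * T.data_codewords(version, level)
    bits += "0" * min(4, capacity - len(bits))  # terminator
    bits += "0" * ((-len(bits)) % 8)
    pad = (capacity - len(bits)) // 8
    for i in range(pad):
        bits += "11101100" if i % 2 == 0 else "00010001"
    return bits


def _interleave(bits: str, version: int, level: str) -> str:
    ec_per_block, groups = T.block_structure(version, level)
    data = [int(bits[i : i + 8], 2) for i in range(0, len(bits), 8)]
    blocks: list[list[int]] = []
    pos = 0
    for n_blocks, k in groups:
        for _ in range(n_blocks):
            blocks.append(data[pos : pos + k])
            pos += k
    ec_blocks = [rs_encode_block(b, ec_per_block) for b in blocks]
    out: list[int] = []
    for i in range(max(len(b) for b in blocks)):
        for b in blocks:
            if i < len(b):
                out.append(b[i])
    for i in range(ec_per_block):
        for e in ec_blocks:
            out.append(e[i])
    stream = "".join(format(cw, "08b") for cw in out)
    return stream + "0" * T.remainder_bits(version)


def build_symbol(text: str, level: str = "M") -> list[list[int]]:
    """Build the final module matrix (no quiet zone) for a text payload.

    The payload is encoded in byte mode as ISO 8859-1; DDQR strings are pure
    ASCII so this is lossless for them.
    """
    payload = text.encode("latin-1")
    version = _choose_version(len(payload), level)
    bits = _interleave(_data_bitstream(payload, version, level), version, level)

    mat, func = M.build_base_matrix(version)
    M.place_data(mat, func, bits)

    best_mask, best_score, best = 0, None, None
    for mask in range(8):
        M.apply_mask(mat, func, mask)
        M.write_format_info(mat, len(mat), level, mask)
        score = M.penalty_score(mat)
        if best_score is None or score < best_score:
            best_mask, best_score = mask, score
            best = [row[:] for row in mat]
        M.apply_mask(mat, func, mask)  # unmask for the next candidate
    assert best is not None
    return best


def render_qr(text: str, config: QrRenderConfig | None = None) -> bytes:
    """Render a payload into a PNG QR image; returns the PNG bytes.

    The decoded textual payload of the image equals ``text`` exactly.
    Raises CapacityExceededError when the payload does not fit version 40 at
    the configured error-correction level, and ValueError on empty payload.
    """
    if not text:
        raise ValueError("empty payload")
    cfg = config or QrRenderConfig()
    mat = build_symbol(text, cfg.error_correction)
    n = len(mat)
    scale = cfg.module_pixel_size
    border = cfg.border_modules
    dim = (n + 2 * border) * scale
    img = Image.new("L", (dim, dim), 255)
    px = img.load()
    for r in range(n):
        for c in range(n):
            if mat[r][c]:
                for dr in range(scale):
                    for dc in range(scale):
                        px[(border + c) * scale + dc, (border + r) * scale + dr] = 0
    buf = io.BytesIO()
    img.save(buf, format=cfg.image_format)
    return buf.getvalue()
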