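"""GF(256) arithmetic and Reed-Solomon coding for the QR symbology.

The field is GF(2^8) with the QR primitive polynomial
x^8 + x^4 + x^3 + x^2 + 1 (0x11d) and generator element 2. Encoding uses
polynomial division by the generator polynomial prod_{i=0..n-1} (x - 2^i);
decoding runs syndromes -> Berlekamp-Massey -> Chien search -> Forney,
correcting up to floor(n_ec/2) byte errors per block.
"""

from __future__ import annotations

__all__ = ["gf_mul", "gf_div", "rs_generator_poly", "rs_encode_block", "rs_correct_block"]

_PRIM = 0x11D

EXP = [0] * 512
LOG = [0] * 256
_x = 1
for _i in range(255):
    EXP[_i] = _x
    LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= _PRIM
for _i in range(255, 512):
    EXP[_i] = EXP[_i - 255]


def gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return EXP[LOG[a] + LOG[b]]


def gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError("division by zero in GF(256)")
    if a == 0:
        return 0
    return EXP[LOG[a] - LOG[b] + 255]


def _poly_mul(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        if a:
            for j, b in enumerate(q):
                out[i + j] ^= gf_mul(a, b)
    return out


def _poly_eval(poly: list[int], x: int) -> int:
    # Horner, highest-degree coefficient first
    y = 0
    for c in poly:
        y = gf_mul(y, x) ^ c
    return y


def rs_generator_poly(n_ec: int) -> list[int]:
    """Generator polynomial with roots 2^0 .. 2^(n_ec-1), monic, degree-first."""
    g = [1]
    for i in range(n_ec):
        g = _poly_mul(g, [1, EXP[i]])
    return g


def rs_encode_block(data: list[int], n_ec: int) -> list[int]:
    """Return the n_ec error-correction codewords for a data block."""
    gen = rs_generator_poly(n_ec)
    rem = list(data) + [0] * n_ec
    for i in range(len(data)):
        coef = rem[i]
        if coef:
            for j in range(1, len(gen)):
                rem[i + j] ^= gf_mul(gen[j], coef)
    return rem[len(data):]


def _syndromes(codeword: list[int], n_ec: int) -> list[int]:
    return [_poly_eval(codeword, EXP[i]) for i in range(n_ec)]


def rs_correct_block(codeword: list[int], n_ec: int) -> list[int]:
    """Correct up to floor(n_ec/2) byte errors in place; return the codeword.

    Raises ValueError when the error pattern is uncorrectable.
    """
    synd = _syndromes(codeword, n_ec)
    if not any(synd):
        return codeword

    # Berlekamp-Massey, constant term first: Lambda(x) = 1 + l1 x + ...
    lam = [1] + [0] * n_ec
    B = [1] + [0] * n_ec
    L, m, b = 0, 1, 1
    for i in range(n_ec):
        delta = 0
        for j in range(L + 1):
            delta ^= gf_mul(lam[j], synd[i - j])
        if delta == 0:
            m += 1
        else:
            coef = gf_div(delta, b)
            if 2 * L <= i:
                T = lam.copy()
                for j in range(n_ec - m + 1):
                    lam[j + m] ^= gf_mul(coef, B[j])
                L = i + 1 - L
                B, b, m = T, delta, 1
            else:
                for j in range(n_ec - m + 1):
                    lam[j + m] ^= gf_mul(coef, B[j])
                m += 1
    locator = lam[: L + 1]
    n_err = L
    if n_err * 2 > n_ec:
        raise ValueError("too many errors to correct")

    # Chien search over codeword positions
    n = len(codeword)
    positions = []
    for pos in range(n):
        # X_j = 2^(n-1-pos); error at pos iff locator(X_j^-1) == 0
        x_inv = EXP[(255 - (n - 1 - pos)) % 255]
        acc = 0
        for k, c in enumerate(locator):
            acc ^= gf_mul(c, EXP[(LOG[x_inv] * k) % 255]) if c and x_inv else (c if k == 0 else 0)
        if acc == 0:
            positions.append(pos)
    if len(positions) != n_err:
        raise ValueError("error locator roots do not match error count")

    # Forney: error evaluator omega = synd * locator mod x^n_ec
    synd_poly = list(synd)  # constant term first
    omega = [0] * n_ec
    for i, s in enumerate(synd_poly):
        if s:
            for j, c in enumerate(locator):
                if i + j < n_ec and c:
                    omega[i + j] ^= gf_mul(s, c)
    for pos in positions:
        x = EXP[(n - 1 - pos) % 255]
        x_inv = gf_div(1, x)
        # omega(x_inv)
        num = 0
        for k, c in enumerate(omega):
            num ^= gf_mul(c, EXP[(LOG[x_inv] * k) % 255]) if c else 0
        # formal derivative of locator, evaluated at x_inv
        den = 0
        for k in range(1, len(locator), 2):
            c = locator[k]
            if c:
                den ^= gf_mul(c, EXP[(LOG[x_inv] * (k - 1)) % 255]) if x_inv else 0
        if den == 0:
            raise ValueError("Forney denominator zero")
        # first consecutive generator root is alpha^0, hence the extra X factor
        codeword[pos] ^= gf_mul(x, gf_div(num, den))
    if any(_syndromes(codeword, n_ec)):
        raise ValueError("correction failed verification")
    return codeword
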