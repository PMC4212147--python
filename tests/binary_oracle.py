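"""Independent scalar transcription of the 44 binary similarity coefficients.

This module is the test oracle: each formula, bounding transform and
degenerate-input rule is re-coded here in plain piecewise scalar arithmetic,
separately from the vectorized registry in :mod:`chemsi.similarity`. The
exhaustive agreement test compares the two codings over every confusion
quadruple with p <= 12.
"""

from __future__ import annotations

import math

# ids whose formula attains 1 on identical non-empty inputs
SELF_UNIT = {
    1, 2, 3, 4, 7, 8, 9, 10, 11, 12, 13, 14, 16, 18, 19, 20, 21, 24, 25, 27,
    28, 29, 30, 31, 32, 33, 34, 35, 36, 37, 38, 39, 40, 42, 44,
}

# ids treated as correlation-type (undefined 0/0 -> 0.5)
CORRELATION = {17, 20, 21, 23, 24, 25, 26, 30, 34, 35, 36, 37, 43}


def _clip(v: float) -> float:
    return 0.0 if v < 0.0 else 1.0 if v > 1.0 else v


def _pm1(v: float) -> float:
    return (v + 1.0) / 2.0


def _posinf(v: float) -> float:
    return v / (1.0 + v)


def oracle_binary(cid: int, a: int, b: int, c: int, d: int) -> float:
    """[0,1] similarity for coefficient ``cid`` on counts (a, b, c, d)."""
    if b > c:
        b, c = c, b
    p = a + b + c + d
    if p == 0:
        raise ValueError("p must be positive")
    identical = b == 0 and c == 0
    if identical and a == 0:
        return 1.0
    if identical and cid in SELF_UNIT:
        return 1.0
    try:
        value = _raw(cid, a, b, c, d, p)
    except ZeroDivisionError:
        return 1.0 if identical else (0.5 if cid in CORRELATION else 0.0)
    if value != value or value in (math.inf, -math.inf):  # nan/inf fallthrough
        return 1.0 if identical else (0.5 if cid in CORRELATION else 0.0)
    return _clip(value)


def _raw(cid: int, a: int, b: int, c: int, d: int, p: int) -> float:
    if cid == 1:
        return (a + d) / p
    if cid == 2:
        return (a + d) / (p + b + c)
    if cid == 3:
        return a / (a + b + c)
    if cid == 4:
        return 2 * a / (2 * a + b + c)
    if cid == 5:
        return a / p
    if cid == 6:
        return _posinf(a * p / ((a + b) * (a + c)))
    if cid == 7:
        return a / min(a + b, a + c)
    if cid == 8:
        return a / max(a + b, a + c)
    if cid == 9:
        return a / math.sqrt((a + b) * (a + c))
    if cid == 10:
        root = math.sqrt(a * d)
        return (root + a) / (root + a + b + c)
    if cid == 11:
        return _posinf(a / (b + c))
    if cid == 12:
        return a / (a + 2 * (b + c))
    if cid == 13:
        return 2 * (a + d) / (p + a + d)
    if cid == 14:
        return 3 * a / (3 * a + b + c)
    if cid == 15:
        return (a + 0.5 * d) / p
    if cid == 16:
        return _posinf(2 * a / (a * b + a * c + 2 * b * c))
    if cid == 17:
        return _pm1(4 * (a * d - b * c) / ((a + d) ** 2 + (b + c) ** 2))
    if cid == 18:
        first = a / (2 * a + b + c) if 2 * a + b + c else 0.5
        second = d / (2 * d + b + c) if 2 * d + b + c else 0.5
        return first + second
    if cid == 19:
        first = a / (a + b + c) if a + b + c else 1.0
        second = d / (d + b + c) if d + b + c else 1.0
        return 0.5 * (first + second)
    if cid == 20:
        return _pm1((a * d - b * c) / (a * d + b * c))
    if cid == 21:
        num = math.sqrt(a * d) - math.sqrt(b * c)
        den = math.sqrt(a * d) + math.sqrt(b * c)
        return _pm1(num / den)
    if cid == 22:
        return _posinf(p * (a - 0.5) ** 2 / ((a + b) * (a + c)))
    if cid == 23:
        raw = (a * d - b * c) / math.sqrt(p * (a + b) * (a + c))
        return (raw + math.sqrt(p) / 2) / (1.5 * math.sqrt(p))
    if cid == 24:
        return _pm1((a * d - b * c) / ((a + b) * (b + d)))
    if cid == 25:
        return _pm1((a * d - b * c) / ((a + c) * (c + d)))
    if cid == 26:
        return 2 * ((a * d - b * c) / p**2) + 0.5
    if cid == 27:
        m = min(a, d)
        return _pm1((2 * m - b - c) / (2 * m + b + c))
    if cid == 28:
        return _posinf((a + d) / (b + c))
    if cid == 29:
        total = 0.0
        identical = b == 0 and c == 0
        for num, den in ((a, a + b), (a, a + c), (d, d + b), (d, d + c)):
            total += num / den if den else (1.0 if identical else 0.0)
        return total / 4.0
    if cid == 30:
        return _pm1((a * d - b * c) / math.sqrt((a + b) * (a + c) * (b + d) * (c + d)))
    if cid == 31:
        return a / (a + b)
    if cid == 32:
        return a / (a + c)
    if cid == 33:
        return a * a / ((a + b) * (a + c))
    if cid == 34:
        return _pm1(2 * (a * d - b * c) / ((a + b) * (b + d) + (a + c) * (c + d)))
    if cid == 35:
        return _pm1((a * d - b * c) / ((a + b) * (c + d)))
    if cid == 36:
        return _pm1((a * d - b * c) / ((a + c) * (b + d)))
    if cid == 37:
        return _pm1(2 * (a * d - b * c) / ((a + b) * (c + d) + (a + c) * (b + d)))
    if cid == 38:
        first = a * (2 * d + b + c) / (2 * (a + b + c)) if a + b + c else 0.0
        second = d * (2 * a + b + c) / (2 * (b + c + d)) if b + c + d else 0.0
        return (first + second) / p
    if cid == 39:
        return math.log(1 + a + d) / math.log(1 + p)
    if cid == 40:
        return (math.log(1 + p) - math.log(1 + b + c)) / math.log(1 + p)
    if cid == 41:
        return math.log(1 + a) / math.log(1 + p)
    if cid == 42:
        return math.log(1 + a) / math.log(1 + a + b + c)
    if cid == 43:
        return _pm1(
            (math.log(1 + a * d) - math.log(1 + b * c)) / math.log(1 + p * p / 4.0)
        )
    if cid == 44:
        return 2.0 / math.pi * math.asin(math.sqrt((a + d) / p))
    raise ValueError(f"unknown coefficient id {cid}")
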