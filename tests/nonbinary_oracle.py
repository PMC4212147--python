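"""Independent scalar transcription of the 6 non-binary coefficients."""

from __future__ import annotations

import math
from typing import Sequence


def oracle_nonbinary(cid: int, x: Sequence[float], y: Sequence[float]) -> float:
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if list(x) == list(y):
        return 1.0
    if cid == 1:  # Mean Canberra, as a similarity
        total = 0.0
        for xi, yi in zip(x, y):
            if xi + yi != 0:
                total += abs(xi - yi) / (xi + yi)
        return 1.0 - total / len(x)
    if cid == 2:  # Divergence, as a similarity
        total = 0.0
        for xi, yi in zip(x, y):
            if xi + yi != 0:
                total += ((xi - yi) / (xi + yi)) ** 2
        return 1.0 - total / len(x)
    if cid == 3:  # Bray-Curtis, as a similarity
        denom = sum(xi + yi for xi, yi in zip(x, y))
        if denom == 0:
            return 1.0
        return 1.0 - sum(abs(xi - yi) for xi, yi in zip(x, y)) / denom
    dot = sum(xi * yi for xi, yi in zip(x, y))
    xx = sum(xi * xi for xi in x)
    yy = sum(yi * yi for yi in y)
    if cid == 4:  # Dice
        return 0.0 if xx + yy == 0 else 2.0 * dot / (xx + yy)
    if cid == 5:  # Sokal/Sneath continuous form
        denom = 2.0 * xx + 2.0 * yy - 3.0 * dot
        return 0.0 if denom == 0 else dot / denom
    if cid == 6:  # Cosine/Ochiai
        denom = math.sqrt(xx * yy)
        return 0.0 if denom == 0 else dot / denom
    raise ValueError(f"unknown coefficient id {cid}")
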