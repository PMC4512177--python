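"""Independent brute-force oracle for the histogram-reflection arithmetic.

Plain scalar loops over explicit (negative bins, zero bin, positive bins)
count lists — no shared code with the package implementation.
"""

from __future__ import annotations

import math


def brute_force_decompose(
    neg: list[int], zero: int, pos: list[int], bin_width: float = 0.025, mask_z: float = 2.0
):
    """Reflect-subtract arithmetic on an explicit small histogram.

    ``neg`` is ordered from the bin nearest zero outward (neg[0] spans
    (-1.5w/2...), i.e. center -w); ``pos`` likewise from the bin nearest zero
    outward.  Returns (failure_rate, probability, amplitude_or_None).
    """
    total = sum(neg) + zero + sum(pos)
    if total == 0:
        raise ValueError("empty histogram")
    # failure mass: negative side + its mirror + the whole zero bin
    failure = zero + 2 * sum(neg)
    failure_rate = min(max(failure / total, 0.0), 1.0)
    probability = min(max(1.0 - failure_rate, 0.0), 1.0)

    # response mass: positive counts minus mirrored negative counts, floored
    n = max(len(pos), len(neg))
    masses, centers, refl = [], [], []
    for i in range(n):
        p_i = pos[i] if i < len(pos) else 0
        r_i = neg[i] if i < len(neg) else 0
        masses.append(max(p_i - r_i, 0.0))
        refl.append(r_i)
        centers.append((i + 1) * bin_width)
    num = den = 0.0
    for m, c, r in zip(masses, centers, refl):
        if m > mask_z * math.sqrt(2.0 * r):
            num += m * c
            den += m
    amplitude = (num / den) if den > 0 else None
    return failure_rate, probability, amplitude
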