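"""Scalar brute-force reference implementations used as independent oracles.

These deliberately avoid numpy vectorization and the package's own code
paths: plain ``math`` arithmetic on one pixel at a time.
"""

import math

VEG_A = 0.667


def scalar_rgb_indices(rp: float, gp: float, bp: float) -> dict[str, float]:
    total = rp + gp + bp
    out = {}
    if total > 0:
        out["r"] = rp / total
        out["g"] = gp / total
        out["b"] = bp / total
        out["ExG"] = 2 * out["g"] - out["r"] - out["b"]
    else:
        out["r"] = out["g"] = out["b"] = out["ExG"] = math.nan
    out["VEG"] = gp / (rp**VEG_A * bp ** (1 - VEG_A)) if rp > 0 and bp > 0 else math.nan
    den = gp + rp - bp
    out["VARI"] = (gp - rp) / den if den != 0 else math.nan
    return out


def scalar_mask_score_pea(r: float, g: float, b: float) -> float:
    den = 0.1 * g + 0.1 * r + b
    return 5 * 255 * (0.1 * g) / den if den > 0 else math.nan


def scalar_mask_score_wheat(r: float, g: float, b: float) -> float:
    den = 0.1 * g + 0.1 * r + b
    return 5 * 255 * (0.1 * g - r) / den if den > 0 else math.nan


def scalar_norm_diff(a: float, b: float) -> float:
    return (a - b) / (a + b) if a + b != 0 else math.nan


def scalar_pearson(xs, ys) -> float:
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / math.sqrt(sxx * syy)
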