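"""Closed-form bench calculations: Poisson infection statistics and
caliper tumor volume."""

from __future__ import annotations

import math


def infected_fraction(moi: float) -> float:
    """Fraction of cells infected at multiplicity ``moi``: P = 1 - e^-m.

    Assumes Poisson-distributed infection events per cell, so the uninfected
    fraction is the zero-count probability e^-m.
    """
    if moi < 0:
        raise ValueError("MOI must be non-negative")
    return 1.0 - math.exp(-moi)


def moi_from_fraction(p: float) -> float:
    """MOI yielding infected fraction ``p``: m = -ln(1 - P)."""
    if not 0.0 <= p < 1.0:
        raise ValueError("infected fraction must lie in [0, 1)")
    return -math.log(1.0 - p)


def tumor_volume(d: float, dd: float) -> float:
    """Ellipsoid-approximation tumor volume d^2 * D / 2 (mm^3) from the
    shortest (d) and longest (D) caliper diameters."""
    if d <= 0:
        raise ValueError("diameters must be positive")
    if d > dd:
        raise ValueError("shortest diameter exceeds longest")
    return d * d * dd / 2.0
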