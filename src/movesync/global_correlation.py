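"""Global zero-lag cross-correlation of a dyad and its three transforms.

The simplest synchrony battery: the Pearson correlation of the two full
series at lag zero (CC-raw), its absolute value (CC-abs), Fisher's Z
(CC-Z) and its square, the coefficient of determination (CC-R2). The sign
problem motivates the transforms: sections of positive and negative
coupling cancel in the raw average, so sign-free variants are carried
alongside. Since atanh and squaring are strictly monotone on their domains,
CC-raw/CC-Z and CC-abs/CC-R2 agree perfectly in rank across any cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._stats import fisher_z
from .datatypes import DyadTimeSeries

__all__ = ["CCResult", "compute_cc"]


@dataclass(frozen=True)
class CCResult:
    raw: float
    abs: float
    z: float
    r2: float
    clamped: bool = False  # |raw| at 1: Fisher Z was capped


def compute_cc(dyad: DyadTimeSeries) -> CCResult:
    """Pearson correlation of the aligned series at lag 0 plus transforms.

    Raises on constant members ("degenerate variance"): a correlation is
    undefined there and silently emitting 0 would bias cohort averages.
    """
    a, b = dyad.a, dyad.b
    if a.size < 3:
        raise ValueError("need at least 3 frames")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("degenerate variance: constant member series")
    raw = float(np.corrcoef(a, b)[0, 1])
    raw = min(1.0, max(-1.0, raw))
    return CCResult(raw=raw, abs=abs(raw), z=float(fisher_z(raw)), r2=raw * raw,
                    clamped=abs(raw) >= 1.0)
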