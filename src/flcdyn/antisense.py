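"""Antisense-mediated repression of FLC sense transcription.

The antisense pathway enters the model as a single repression factor
r(t) in [0, 1] multiplying sense initiation in the non-nucleated and
nucleated states.  It combines a slowly accumulating cold component
(first-order relaxation toward ``a_slow_max`` below ``T_cold``) with a
fast temperature response: a step of size ``a_fast`` below the freezing
threshold ``T_fast`` plus a graded exponential term that strengthens
continuously as temperature falls, so repression tracks daily cycles
that never reach freezing.  The combined repression is additive and
clamped to [0, 1].

COOLAIR-defective lines (``disabled``) have r = 1 always; ntl8-D3-like
lines (``constitutive``) hold the slow component at its maximum
independent of temperature.
"""

from __future__ import annotations

import math

from .params import AntisenseParams


def a_slow_rhs(a_slow: float, T: float, p: AntisenseParams) -> float:
    """d(a_slow)/dt (1/day) for the slow repression component."""
    if p.disabled:
        return -p.k_pin * a_slow
    if p.constitutive:
        return p.k_pin * (p.a_slow_max - a_slow)
    if T < p.T_cold:
        return p.k_on * (p.a_slow_max - a_slow)
    return -p.k_off * a_slow

def fast_component(T: float, p: AntisenseParams) -> float:
    """Fast (within-day) repression increment at temperature T."""
    if p.disabled:
        return 0.0
    f = 0.0
    if T < p.T_fast:
        f += p.a_fast
    if T < p.T_grad_on:
        f += p.a_grad * math.exp(-(T - p.T_fast) / p.T_grad_scale)
    return f


def repression_factor(a_slow: float, T: float, p: AntisenseParams) -> float:
    """Multiplier r in [0,1] on sense initiation; 1 = no repression."""
    if p.disabled:
        return 1.0
    total = a_slow + fast_component(T, p)
    return 1.0 - min(1.0, max(0.0, total))
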