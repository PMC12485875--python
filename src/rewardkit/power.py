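"""Reliability-attenuated correlation power arithmetic.

Classical attenuation: an observed correlation between two measures with
reliabilities ``rel_x`` and ``rel_y`` is

    r_obs = r_true * sqrt(rel_x * rel_y)

and the sample size needed to detect ``r_obs`` at two-sided level alpha
with the target power follows the Fisher-z normal approximation

    n = ((z_{1-alpha/2} + z_{power}) / atanh(r_obs))^2 + 3

truncated to an integer.  Truncation (rather than the conventional
round-up) is deliberate: the quantity is reported as the integer part of
the approximation.  With a true correlation of .30 at 80% power and
alpha = .05, dropping one measure's reliability from .80 to .30 moves the
required sample from the optimistic double-.80 regime into the hundreds
(n = 361), and to .10 into the thousands (n = 1087).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerQuery", "attenuated_r", "required_n"]


@dataclass(frozen=True)
class PowerQuery:
    """A power question: true effect, measure reliabilities, alpha, power."""

    r_true: float = 0.30
    rel_x: float = 0.80
    rel_y: float = 0.80
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not abs(self.r_true) < 1:
            raise ValueError("|r_true| must be < 1")
        for name in ("rel_x", "rel_y"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")


def attenuated_r(q: PowerQuery) -> float:
    """Observed correlation after attenuation by the two reliabilities."""
    return q.r_true * math.sqrt(q.rel_x * q.rel_y)


def required_n(q: PowerQuery) -> int:
    """Sample size for the attenuated correlation, Fisher-z approximation."""
    r_obs = attenuated_r(q)
    if r_obs == 0:
        raise ValueError("attenuated correlation is zero; no finite sample "
                         "size achieves the target power")
    z_alpha = stats.norm.ppf(1.0 - q.alpha / 2.0)
    z_power = stats.norm.ppf(q.power)
    n = ((z_alpha + z_power) / math.atanh(r_obs)) ** 2 + 3.0
    return int(math.floor(n))
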