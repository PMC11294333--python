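"""Analytic statistical power for two-sample MR with a binary outcome.

Uses the non-centrality approximation popularised by the mRnd calculator:
the test statistic for the causal log odds ratio has mean

    z_alt = |ln(OR)| * sqrt(N * R²_xz * K * (1 − K)),

with N the outcome-study size, R²_xz the exposure variance explained by
the instruments and K the case fraction, so

    power = Phi(z_alt − z_{1−alpha/2}).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

from .exceptions import ValidationError


@dataclass(frozen=True)
class PowerInputs:
    n_outcome: int
    r2_xz: float
    or_alt: float
    case_fraction: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_outcome <= 0:
            raise ValidationError("n_outcome must be positive")
        if not (0 <= self.r2_xz < 1):
            raise ValidationError("r2_xz must lie in [0, 1)")
        if self.or_alt <= 0:
            raise ValidationError("or_alt must be positive")
        if not (0 < self.case_fraction < 1):
            raise ValidationError("case_fraction must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")


def mr_power_binary(
    n_outcome: int | PowerInputs,
    r2_xz: float | None = None,
    or_alt: float | None = None,
    case_fraction: float | None = None,
    alpha: float = 0.05,
) -> float:
    """Power (as a fraction) to detect ``or_alt`` at two-sided ``alpha``.

    Accepts a :class:`PowerInputs` or the individual arguments.  With
    ``r2_xz = 0`` and a non-null OR, the instruments carry no signal and
    the nominal type-I rate is returned with a warning.
    """
    if isinstance(n_outcome, PowerInputs):
        inputs = n_outcome
    else:
        inputs = PowerInputs(n_outcome, r2_xz, or_alt, case_fraction, alpha)
    z_crit = stats.norm.ppf(1.0 - inputs.alpha / 2.0)
    if inputs.r2_xz == 0 and inputs.or_alt != 1:
        warnings.warn(
            "r2_xz = 0 with a non-null OR: instruments explain no exposure "
            "variance; returning the null rejection rate",
            stacklevel=2,
        )
    ncp = abs(math.log(inputs.or_alt)) * math.sqrt(
        inputs.n_outcome
        * inputs.r2_xz
        * inputs.case_fraction
        * (1.0 - inputs.case_fraction)
    )
    return float(stats.norm.cdf(ncp - z_crit))
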