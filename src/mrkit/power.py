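"""A priori power and minimum-detectable-OR for binary-outcome two-sample MR.

The sampling SE of the pooled log-odds-per-SD estimate is approximated from
the outcome GWAS size N and the exposure variance r² explained by the
instruments.  Two variance models are exposed:

* ``standardized`` (default): SE = 1/sqrt(N·r²);
* ``binomial``: SE = 1/sqrt(N·r²·phi·(1-phi)) with phi the case fraction,
  which accounts for the binomial information of a case/control outcome and
  is always the more conservative of the two.

Power for the two-sided Wald test at level alpha against log-OR b is then
Phi(|b|/SE - z_{1-alpha/2}) + Phi(-|b|/SE - z_{1-alpha/2}), exactly
symmetric in OR <-> 1/OR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .gwas_io import ValidationError

VARIANCE_MODELS = ("standardized", "binomial")


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a binary-outcome MR power calculation."""

    n_cases: int
    n_controls: int
    r2: float
    alpha: float = 0.05
    or_alt: float | None = None
    n_exposure: int | None = None  # accepted but unused by the first-order formula

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValidationError("case and control counts must be positive")
        if not 0.0 < self.r2 < 1.0:
            raise ValidationError(f"r2 {self.r2} not in (0,1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha {self.alpha} not in (0,1)")
        if self.or_alt is not None and not self.or_alt > 0:
            raise ValidationError(f"or_alt {self.or_alt} must be > 0")

    @property
    def n_outcome(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_outcome


def _se_beta(spec: PowerSpec, variance_model: str) -> float:
    if variance_model not in VARIANCE_MODELS:
        raise ValueError(f"unknown variance model {variance_model!r}")
    info = spec.n_outcome * spec.r2
    if variance_model == "binomial":
        phi = spec.case_fraction
        info *= phi * (1.0 - phi)
    return 1.0 / np.sqrt(info)


def mr_power_binary(spec: PowerSpec, variance_model: str = "standardized") -> float:
    """Power of the two-sided Wald test to detect ``spec.or_alt``."""
    if spec.or_alt is None:
        raise ValidationError("or_alt must be set for a power calculation")
    b = abs(np.log(spec.or_alt))
    se = _se_beta(spec, variance_model)
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(b / se - z) + stats.norm.cdf(-b / se - z))


def min_detectable_or(
    spec: PowerSpec, target_power: float, variance_model: str = "standardized"
) -> float:
    """Smallest OR > 1 detectable with at least ``target_power``, by bisection.

    Inverse-consistent with :func:`mr_power_binary` to 1e-6 on the OR scale.
    """
    if not spec.alpha < target_power < 1.0:
        raise ValidationError(f"target power {target_power} must lie in (alpha, 1)")

    def gap(or_alt: float) -> float:
        return mr_power_binary(replace(spec, or_alt=or_alt), variance_model) - target_power

    hi = 1.0 + 1e-6
    while gap(hi) < 0.0:
        hi = 1.0 + 2.0 * (hi - 1.0)
        if hi > 1e6:
            raise EstimationBracketError("power never reaches the target (r² too small?)")
    return float(optimize.brentq(gap, 1.0 + 1e-12, hi, xtol=1e-6))


class EstimationBracketError(RuntimeError):
    """The minimum-detectable-OR search could not bracket the target power."""
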