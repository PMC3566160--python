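"""qPCR validation calculators: percent-of-input and comparative ddCt.

ChIP-qPCR enrichment at a promoter is quantified by the standard-curve
method: a dilution series fits Ct = slope * log10(quantity) + intercept
(slope near -3.32 for perfect doubling chemistry), Cts convert back to
quantities, and the immunoprecipitated signal is expressed as a
percentage of the dilution-corrected input chromatin. RT-qPCR relative
expression uses the comparative ddCt method against an endogenous
control gene: fold change = 2^(-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import CurveQualityError, ValidationError

CT_ROLES = ("ip", "input", "target", "endogenous_control")
DEFAULT_REPLICATE_SPREAD = 0.5  # cycles; wider replicate ranges get flagged


@dataclass
class StandardCurve:
    """Least-squares dilution line: Ct per log10(quantity)."""

    slope: float
    intercept: float
    r_squared: float

    def quantity(self, ct: float) -> float:
        """Invert the curve: relative quantity at a measured Ct."""
        return 10.0 ** ((ct - self.intercept) / self.slope)


@dataclass
class CtMeasurement:
    """Replicate Ct values of one sample/target pair."""

    sample: str
    target: str
    cts: Sequence[float]
    role: str = "target"

    def __post_init__(self) -> None:
        if self.role not in CT_ROLES:
            raise ValidationError(f"role must be one of {CT_ROLES}")
        if not len(self.cts) or any(c <= 0 for c in self.cts):
            raise ValidationError("Ct values must be positive and non-empty")

    @property
    def ct(self) -> float:
        """Arithmetic mean of replicate Cts."""
        return mean(self.cts)

    def spread_flagged(self, threshold: float = DEFAULT_REPLICATE_SPREAD) -> bool:
        return (max(self.cts) - min(self.cts)) > threshold


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit Ct = slope * log10(quantity) + intercept from >= 3 dilution points."""
    if len(points) < 3:
        raise ValidationError("standard curve needs >= 3 points")
    x = np.asarray([p[0] for p in points], dtype=np.float64)
    y = np.asarray([p[1] for p in points], dtype=np.float64)
    if len(np.unique(x)) < 2:
        raise ValidationError("standard curve needs distinct quantities")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise CurveQualityError(
            f"standard-curve slope {fit.slope:.3f} is not negative; "
            "Ct must decrease with template quantity")
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue ** 2))


def percent_input(ct_ip: float, ct_input: float, curve: StandardCurve,
                  input_fraction: float) -> float:
    """ChIP signal as a percentage of the dilution-corrected input.

    ``input_fraction`` is the fraction of chromatin the measured input
    aliquot represents (e.g. 0.01 for a 1% input); it has no universal
    default and must be supplied.
    """
    if not (0 < input_fraction <= 1):
        raise ValidationError("input_fraction must be in (0, 1]")
    q_ip = curve.quantity(ct_ip)
    q_input_total = curve.quantity(ct_input) / input_fraction
    return 100.0 * q_ip / q_input_total


def ddct_relative_expression(ct_target_sample: float, ct_ref_sample: float,
                             ct_target_calibrator: float,
                             ct_ref_calibrator: float) -> float:
    """Comparative ddCt fold change, 2^(-ddCt), vs an endogenous control."""
    for ct in (ct_target_sample, ct_ref_sample, ct_target_calibrator,
               ct_ref_calibrator):
        if ct <= 0:
            raise ValidationError("Ct values must be positive")
    ddct = ((ct_target_sample - ct_ref_sample)
            - (ct_target_calibrator - ct_ref_calibrator))
    return float(2.0 ** (-ddct))
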