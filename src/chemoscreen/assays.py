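"""Small quantitative assay computations: competitive-proliferation index,
relative viability, and four-parameter log-logistic dose-response fits.

The competitive-proliferation index follows the double-normalization used
for marker-mixing experiments (e.g. GFP:BFP co-cultures): the treated
marker ratio is normalized to its own day-0 ratio, then to the matched
untreated ratio normalized the same way, so an index of 1 means the
knockout pool proliferates like its untreated counterpart and >1 means a
proliferative advantage under drug.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import NumericalError, ValidationError


@dataclass
class CompetitionSeries:
    """Marker+/marker- cell ratios over time for one treated/untreated pair.

    ``timepoints`` (days) must include day 0; ratios are positive and
    aligned with timepoints.
    """

    timepoints: np.ndarray
    ratio_treated: np.ndarray
    ratio_untreated: np.ndarray

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.ratio_treated = np.asarray(self.ratio_treated, dtype=float)
        self.ratio_untreated = np.asarray(self.ratio_untreated, dtype=float)
        if not (len(self.timepoints) == len(self.ratio_treated) == len(self.ratio_untreated)):
            raise ValidationError("timepoints and ratio arrays must have equal length")
        if 0.0 not in self.timepoints:
            raise ValidationError("a day-0 entry is required")
        if (self.ratio_treated <= 0).any() or (self.ratio_untreated <= 0).any():
            raise ValidationError("ratios must be positive")


def competition_index(series: CompetitionSeries) -> np.ndarray:
    """index(t) = (treated(t)/treated(0)) / (untreated(t)/untreated(0)).

    Returned in timepoint order; index(0) == 1 by construction.
    """
    i0 = int(np.flatnonzero(series.timepoints == 0.0)[0])
    treated = series.ratio_treated / series.ratio_treated[i0]
    untreated = series.ratio_untreated / series.ratio_untreated[i0]
    return treated / untreated


def relative_viability(signal, untreated_signal) -> float:
    """Mean assay signal relative to the mean untreated signal."""
    signal = np.asarray(signal, dtype=float)
    untreated = np.asarray(untreated_signal, dtype=float)
    if untreated.size == 0 or untreated.mean() <= 0:
        raise ValidationError("untreated mean signal must be positive")
    return float(signal.mean() / untreated.mean())


@dataclass
class DoseResponse:
    """Fitted 4-parameter log-logistic curve:
    response = bottom + (top - bottom) / (1 + (dose/ic50)^hill)."""

    top: float
    bottom: float
    ic50: float
    hill: float
    sse: float

    def predict(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(dose > 0, (dose / self.ic50) ** self.hill, 0.0)
        return self.bottom + (self.top - self.bottom) / (1.0 + ratio)


def fit_dose_response(doses, responses) -> DoseResponse:
    """Least-squares 4PL fit with bounded parameters and multi-start.

    Responses are expected on the untreated-normalized scale (untreated = 1),
    hence the bounds bottom >= 0, top <= 1.5, hill in [0.2, 10]. Starting
    ic50 values are taken from dose quantiles so the fit is equivariant
    under rescaling all doses. Flat data (no transition) is unidentifiable
    and raises :class:`NumericalError`.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape or doses.ndim != 1:
        raise ValidationError("doses and responses must be equal-length 1-d arrays")
    if (doses < 0).any() or (responses < 0).any():
        raise ValidationError("doses and responses must be non-negative")
    if len(np.unique(doses)) < 5:
        raise ValidationError("need at least 5 distinct doses spanning the transition")
    if np.ptp(responses) < 1e-6:
        raise NumericalError("responses are flat; ic50 is unidentifiable")

    pos = np.unique(doses[doses > 0])
    lo, hi = pos.min() * 1e-3, pos.max() * 1e3

    def residuals(theta):
        top, bottom, log_ic50, hill = theta
        ic50 = np.exp(log_ic50)
        with np.errstate(divide="ignore"):
            ratio = np.where(doses > 0, (doses / ic50) ** hill, 0.0)
        return bottom + (top - bottom) / (1.0 + ratio) - responses

    bounds = (
        [0.0, 0.0, np.log(lo), 0.2],
        [1.5, 1.5, np.log(hi), 10.0],
    )
    top0 = float(np.clip(responses.max(), 0.1, 1.5))
    bot0 = float(np.clip(responses.min(), 0.0, 1.5))
    best = None
    for ic0 in np.quantile(pos, [0.25, 0.5, 0.75]):
        for hill0 in (0.5, 1.0, 2.0, 4.0):
            x0 = [top0, bot0, np.log(ic0), hill0]
            try:
                sol = least_squares(
                    residuals, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14
                )
            except Exception:  # singular start; try the next one
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
    if best is None:
        raise NumericalError("dose-response fit failed to converge from any start")
    top, bottom, log_ic50, hill = best.x
    return DoseResponse(
        top=float(top),
        bottom=float(bottom),
        ic50=float(np.exp(log_ic50)),
        hill=float(hill),
        sse=float(2.0 * best.cost),
    )
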