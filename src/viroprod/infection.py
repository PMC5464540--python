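"""Infection-frequency metrics and intrinsic viral decay.

FIC (frequency of lytically infected cells) converts the accumulated viral
rises of an incubation into the fraction of the prokaryotic standing stock
that must have been infected before the experiment started, given a burst
size.  FLC (frequency of lysogenically infected cells) is the excess FIC in
mitomycin C-induced incubations over untreated controls, reported only when
the duplicate ranges separate cleanly.  Intrinsic viral decay (VD_INT) is
the ln-linear decay slope in ultra-filtered, cell- and particle-free water,
subject to a statistical detection rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .series import (
    DuplicateSummary,
    ExtremaSegmentation,
    IncubationSeries,
    InvalidSeriesError,
    UndefinedResultError,
    detect_extrema,
)

__all__ = [
    "DEFAULT_BURST_SIZE",
    "InfectionEstimates",
    "DecayFit",
    "fic",
    "flc",
    "empirical_burst_size",
    "fic_rescale_factor",
    "vd_int",
]

#: Burst size (viruses released per lysed cell) assumed when no empirical
#: estimate is available; a literature TEM value for brackish suboxic waters.
DEFAULT_BURST_SIZE = 28.0

#: Detection rule for the ln-linear decay regression: a decay rate is
#: reported only when the fit is significant, reasonably supported, and the
#: slope is actually negative.
DECAY_P_MAX = 0.05
DECAY_R2_MIN = 0.50


@dataclass(frozen=True)
class DecayFit:
    """ln-linear least-squares fit of viral abundance against time.

    ``slope`` is the fitted coefficient in h^-1 (signed); the intrinsic
    decay rate magnitude is ``-slope`` when ``detected``.  ``detected`` is
    true only if p <= 0.05, R^2 >= 0.50 and the slope is negative; positive
    slopes are reported but never flagged detected.
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    @property
    def detected(self) -> bool:
        return (
            self.p_value <= DECAY_P_MAX
            and self.r_squared >= DECAY_R2_MIN
            and self.slope < 0
        )

    @property
    def decay_rate(self) -> float | None:
        """Decay-rate magnitude in h^-1, or None when below detection."""
        return -self.slope if self.detected else None


@dataclass(frozen=True)
class InfectionEstimates:
    """FIC/FLC/burst-size bundle for one sample and approach.

    ``fic`` is in percent of prokaryotic standing stock (may exceed 100 in
    reinfection-dominated incubations; ``fic_exceeds_stock`` flags this).
    ``flc_percent`` is None when undetectable under the range-overlap rule.
    """

    fic: DuplicateSummary
    flc_percent: float | None
    burst_size_assumed: float = DEFAULT_BURST_SIZE
    burst_size_empirical: float | None = None
    fic_rescale_factor: float | None = None

    @property
    def fic_exceeds_stock(self) -> bool:
        return self.fic.average > 100.0


def fic(
    viral_series: IncubationSeries,
    p0: float,
    burst: float = DEFAULT_BURST_SIZE,
    correction: float = 1.0,
    extrema: ExtremaSegmentation | None = None,
) -> float:
    """Frequency of lytically infected cells, percent of standing stock.

    FIC = 100 * correction * (sum of rising viral amplitudes) / (burst * p0)

    Parameters
    ----------
    viral_series : IncubationSeries
        Viral abundance over the incubation.
    p0 : float
        Prokaryotic abundance at the start of the experiment (mL^-1).
    burst : float
        Viruses released per lysed cell (default 28).
    correction : float
        Dilution correction factor (in situ / t0 prokaryotes); 1 for
        undiluted incubations.
    """
    if p0 <= 0 or burst <= 0 or correction <= 0:
        raise InvalidSeriesError("p0, burst and correction must be > 0")
    if extrema is None:
        extrema = detect_extrema(viral_series)
    rise = 0.0 if extrema.degenerate else extrema.total_rise
    return 100.0 * correction * rise / (burst * p0)


def flc(
    fic_control: DuplicateSummary, fic_mitc: DuplicateSummary
) -> float | None:
    """Frequency of lysogenically infected cells, or None if undetectable.

    FLC = FIC(mitC) - FIC(control), reported only when the duplicate ranges
    of the two treatments do not overlap (closed intervals) AND the induced
    average exceeds the control average.  Computed per approach (undiluted
    vs dilution); never pool across approaches.
    """
    if fic_control.overlaps(fic_mitc):
        return None
    if fic_mitc.average <= fic_control.average:
        return None
    return fic_mitc.average - fic_control.average


def empirical_burst_size(vp: float, mortality: float) -> float:
    """Burst size as the ratio of virus production to prokaryotic mortality.

    Both rates must come from the same (virus-dilution) replicate, where
    production and mortality can be attributed to lysis alone.

    Raises
    ------
    UndefinedResultError
        When mortality is zero.
    """
    if vp < 0 or mortality < 0:
        raise InvalidSeriesError("rates must be non-negative")
    if mortality == 0:
        raise UndefinedResultError("burst size undefined at zero mortality")
    return vp / mortality


def fic_rescale_factor(assumed_bs: float, empirical_bs: float) -> float:
    """Factor by which FIC grows when replacing the assumed burst size.

    FIC scales inversely with burst size, so the factor is
    ``assumed_bs / empirical_bs``.
    """
    if assumed_bs <= 0 or empirical_bs <= 0:
        raise InvalidSeriesError("burst sizes must be > 0")
    return assumed_bs / empirical_bs


def vd_int(decay_series: IncubationSeries) -> DecayFit:
    """Intrinsic viral decay from a decay-only incubation.

    Ordinary least squares of ln(viral abundance) on incubation time.  The
    slope magnitude is the decay rate in h^-1 when the detection rule holds
    (p <= 0.05, R^2 >= 0.50, slope < 0); otherwise the rate is reported as
    below the detection limit.
    """
    v = np.asarray(decay_series.abundances, dtype=float)
    t = np.asarray(decay_series.times, dtype=float)
    if len(v) < 3:
        raise InvalidSeriesError("need at least 3 points for the decay fit")
    if np.any(v <= 0):
        raise InvalidSeriesError("zero abundance: ln-linear fit undefined")
    res = sps.linregress(t, np.log(v))
    # a perfectly constant ln-series has undefined r; treat as flat fit
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return DecayFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=p,
        n=len(v),
    )
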