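"""qPCR and assay analytics: ddCt, spike-in correction, standard curves,
mRNA decay half-life fitting, and simple morphometric formulas.

Relative quantification follows the ddCt convention with an assumed
amplification efficiency of 2 (perfect doubling per cycle). Absolute
quantification inverts an OLS standard curve of Ct against log10 copy
number. Half-lives come from log-linear regression of percent-remaining
time courses after transcription block (actinomycin D), with an optional
nonlinear least-squares mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

LN2 = math.log(2.0)


@dataclass(frozen=True)
class CtRecord:
    """One qPCR observation: target Ct paired with its reference-gene Ct."""

    sample: str
    target: str
    ct: float
    reference_ct: float
    group: str = "control"  # "control" | "treated"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct) and math.isfinite(self.reference_ct)):
            raise ValueError(f"{self.sample}/{self.target}: non-finite Ct")

    @property
    def dct(self) -> float:
        return self.ct - self.reference_ct


def ddct(treated: CtRecord, control: CtRecord) -> float:
    """Relative expression 2^(-ddCt) of treated vs control.

    ddCt = (Ct - reference Ct)_treated - (Ct - reference Ct)_control.
    Both records must measure the same target assay.
    """
    if treated.target != control.target:
        raise ValueError(
            f"target mismatch: {treated.target!r} vs {control.target!r}"
        )
    return 2.0 ** (-(treated.dct - control.dct))


def spike_normalize(quantity: float, spike_ct_sample: float,
                    spike_ct_reference: float) -> float:
    """Correct a relative quantity for purification recovery via a spike-in.

    A spike-in (e.g. cel-miR-39a added before extraction) appearing one cycle
    later in the sample than in the reference indicates half the recovery, so
    the quantity is multiplied by 2^(spike_ct_sample - spike_ct_reference).
    """
    if not (math.isfinite(spike_ct_sample) and math.isfinite(spike_ct_reference)):
        raise ValueError("non-finite spike-in Ct")
    return quantity * 2.0 ** (spike_ct_sample - spike_ct_reference)


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Ct (y) against log10 copy number (x)."""

    slope: float  # cycles per log10 copies; < 0 for a valid curve
    intercept: float  # Ct at 1 copy
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(f"invalid standard curve: slope {self.slope} >= 0")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency as a fraction (1.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def predict_ct(self, copies: float) -> float:
        return self.slope * math.log10(copies) + self.intercept


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit a standard curve to (log10 copies, Ct) dilution points.

    Requires at least 3 points spanning at least 2 log10 units and a negative
    slope (Ct decreasing with template amount).
    """
    if len(points) < 3:
        raise ValueError("standard curve requires >= 3 dilution points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if x.max() - x.min() < 2.0:
        raise ValueError("dilution series must span >= 2 log10 units")
    fit = stats.linregress(x, y)
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue**2))


def absolute_copies(curve: StandardCurve, ct: float) -> float:
    """Invert the standard curve: copies = 10^((ct - intercept) / slope)."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


@dataclass(frozen=True)
class DecaySeries:
    """Percent mRNA remaining over time after transcription block.

    The value at t = 0 (the moment actinomycin D is added) is 100 by
    convention; all values must be positive for log-linear fitting.
    """

    timepoints_h: tuple[float, ...]
    percent_remaining: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.timepoints_h) != len(self.percent_remaining):
            raise ValueError("timepoints and values differ in length")
        if any(t < 0 for t in self.timepoints_h):
            raise ValueError("negative timepoint")
        if 0.0 not in self.timepoints_h:
            raise ValueError("series must include t = 0")


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit; halflife_h = ln2 / k, defined only for k > 0."""

    k: float  # decay rate, 1/h
    r_squared: float
    decaying: bool

    @property
    def halflife_h(self) -> float:
        if not self.decaying:
            return math.nan
        return LN2 / self.k


def fit_decay(series: DecaySeries, method: str = "loglinear") -> DecayFit:
    """Fit percent = 100 * exp(-k t) to a decay time course.

    ``method="loglinear"`` (default): OLS of ln(percent) on time — exact on
    noiseless exponentials. ``method="nls"``: nonlinear least squares on the
    linear scale, for sensitivity checks. A non-decaying fit (k <= 0) is
    returned flagged, with halflife undefined.
    """
    t = np.asarray(series.timepoints_h, dtype=float)
    y = np.asarray(series.percent_remaining, dtype=float)
    if len(t) < 3:
        raise ValueError("decay fit requires >= 3 timepoints")
    if (y <= 0).any():
        raise ValueError("non-positive percent value")
    if method == "loglinear":
        fit = stats.linregress(t, np.log(y))
        k = -float(fit.slope)
        r2 = float(fit.rvalue**2)
    elif method == "nls":
        (a, k), _ = optimize.curve_fit(
            lambda tt, a, k: a * np.exp(-k * tt), t, y, p0=(100.0, 0.1)
        )
        resid = y - a * np.exp(-k * t)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
        k = float(k)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DecayFit(k=k, r_squared=r2, decaying=k > 0)


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume V = 0.5 * L * W^2 (mm^3)."""
    if length_mm < 0 or width_mm < 0:
        raise ValueError("negative caliper measurement")
    return 0.5 * length_mm * width_mm**2


def gap_closure(area_t0: float, area_t24: float,
                control_closure: float | None = None) -> float:
    """Percent scratch-gap closure relative to the gap area at 0 h.

    raw = (1 - area_t24 / area_t0) * 100. If ``control_closure`` is given,
    the control's raw closure is subtracted so the control maps to 0%.
    """
    if area_t0 <= 0:
        raise ValueError("gap area at 0 h must be positive")
    if area_t24 < 0:
        raise ValueError("negative gap area")
    raw = (1.0 - area_t24 / area_t0) * 100.0
    if control_closure is not None:
        return raw - control_closure
    return raw
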