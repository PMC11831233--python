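"""qPCR quantification and mRNA decay kinetics.

Covers the comparative-Ct (2^-ddCt) fold change, standard-curve conversion
of Ct values to percent-remaining, and one-phase exponential decay fits

    N(t) = N0 * exp(-K * (t - t0)),     t_half = ln(2) / K

with the plateau fixed at zero (complete decay) and the time origin ``t0``
set to the first time point at which decay is underway (6 h of
transcription-blocking treatment by default; earlier points are excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


def ddct_fold_change(
    ct_target: float,
    ct_reference: float,
    ct_target_cal: float,
    ct_reference_cal: float,
) -> float:
    """Comparative-Ct fold change: ``2 ** -ddCt`` against a calibrator sample.

    ``ddCt = (ct_target - ct_reference) - (ct_target_cal - ct_reference_cal)``.
    """
    ddct = (ct_target - ct_reference) - (ct_target_cal - ct_reference_cal)
    return 2.0 ** (-ddct)


@dataclass
class StandardCurve:
    """Linear fit Ct = slope * log10(quantity) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def quantity(self, ct: float) -> float:
        """Invert the fit: relative quantity for an observed Ct."""
        return 10.0 ** ((ct - self.intercept) / self.slope)

    def percent_remaining(self, ct: float, reference_ct: float) -> float:
        """Quantity at ``ct`` rescaled so ``reference_ct`` reads 100%."""
        return 100.0 * self.quantity(ct) / self.quantity(reference_ct)

    @property
    def efficiency(self) -> float:
        """Amplification efficiency implied by the slope (1.0 = doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(ct, log10_quantity) -> StandardCurve:
    """OLS fit of Ct against log10 relative quantity (>= 3 dilution points)."""
    ct = np.asarray(ct, dtype=float)
    lq = np.asarray(log10_quantity, dtype=float)
    if len(ct) != len(lq) or len(ct) < 3:
        raise ValueError("need >= 3 matched dilution points")
    res = stats.linregress(lq, ct)
    if res.slope >= 0:
        raise ValueError(
            f"standard curve slope must be negative, got {res.slope:.4g}"
        )
    return StandardCurve(float(res.slope), float(res.intercept), float(res.rvalue**2))


@dataclass
class DecayFit:
    K: float  # decay constant, 1/h
    N0: float  # fitted initial percent
    t0: float  # time origin, h
    t_half: float  # ln(2)/K, h; inf when no decay detected
    converged: bool

    @property
    def has_decay(self) -> bool:
        return math.isfinite(self.t_half)


K_TOL = 1e-6  # 1/h; below this (t1/2 ~ centuries) decay is treated as absent


def fit_decay(times, percent, t0: float = 6.0) -> DecayFit:
    """Least-squares one-phase decay fit with plateau fixed at 0.

    Points before ``t0`` are excluded. N0 is fitted (initialized at 100) to
    absorb normalization error; K is constrained non-negative. When the
    fitted K is zero within tolerance, ``t_half`` is returned non-finite
    with the ``converged`` flag still describing the optimizer.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(percent, dtype=float)
    keep = t >= t0
    t, y = t[keep], y[keep]
    if len(t) < 3:
        raise ValueError("need >= 3 time points at or after t0")

    def model(tt, n0, k):
        return n0 * np.exp(-k * (tt - t0))

    # data-driven K init: log-linear slope, clipped into the bounds
    with np.errstate(divide="ignore"):
        logy = np.log(np.clip(y, 1e-12, None))
    slope = np.polyfit(t, logy, 1)[0]
    k_init = min(max(-slope, 1e-6), 100.0)
    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            y,
            p0=[100.0, k_init],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
        n0, k = float(popt[0]), float(popt[1])
        converged = True
    except RuntimeError:
        n0, k = float("nan"), 0.0
        converged = False
    t_half = math.log(2) / k if k > K_TOL else math.inf
    return DecayFit(K=k, N0=n0, t0=t0, t_half=t_half, converged=converged)
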