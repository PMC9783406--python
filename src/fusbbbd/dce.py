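"""DCE-MRI permeability estimation: T1 fitting, signal-to-concentration
conversion, Patlak-model Ktrans/vp estimation, and signal enhancement.

The Patlak model describes unidirectional leakage of a gadolinium contrast
agent from plasma into tissue::

    C_t(t) = Ktrans * integral_0^t C_p(tau) dtau  +  v_p * C_p(t)

where ``Ktrans`` (min^-1) is the volume transfer constant quantifying
blood-brain-barrier permeability and ``v_p`` the fractional plasma volume.
Dividing by C_p(t) linearizes the model; ordinary least squares on the
Patlak coordinates

    y(t) = C_t(t) / C_p(t),   x(t) = integral_0^t C_p dtau / C_p(t)

gives Ktrans as the slope and v_p as the intercept.  The plasma integral is
the cumulative trapezoid with C_p(0) = 0.

T1 is estimated from a variable-repetition-time (VTR) saturation-recovery
series, S(TR) = S0 * (1 - exp(-TR / T1)); concentration follows from the
linear relaxivity relation C = (1/T1_post - 1/T1_pre) / r1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TRSeries",
    "T1RecoveryModel",
    "T1Results",
    "ConcentrationCurve",
    "PatlakModel",
    "PatlakResults",
    "fit_t1",
    "concentration_from_t1",
    "signal_from_concentration",
    "concentration_from_signal",
    "patlak_fit",
    "enhancement_percent",
    "fit_roi_set",
]


@dataclass
class TRSeries:
    """Variable-TR saturation-recovery acquisition."""

    tr_values: np.ndarray  # s
    signals: np.ndarray    # a.u.

    def __post_init__(self) -> None:
        self.tr_values = np.asarray(self.tr_values, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.tr_values.shape != self.signals.shape:
            raise ValueError("tr_values and signals must have the same shape")
        if np.unique(self.tr_values).size < 3:
            raise ValueError("need at least 3 distinct TR values")
        if np.any(self.signals < 0):
            raise ValueError("signals must be nonnegative")


@dataclass
class ConcentrationCurve:
    """Contrast-agent concentration (mM) on a strictly increasing time grid
    (minutes)."""

    times: np.ndarray   # min
    values: np.ndarray  # mM

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if self.times.size and self.times[0] < 0:
            raise ValueError("first time must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


class T1RecoveryModel:
    """Saturation-recovery T1 model S(TR) = s0 * (1 - exp(-TR/t1)).

    Fit by bounded Levenberg-style nonlinear least squares with a
    deterministic initialization (s0 <- max signal, t1 <- median TR).
    """

    def __init__(self, series: TRSeries):
        self.series = series

    def fit(self, xtol: float = 1e-10, max_iter: int = 200) -> "T1Results":
        tr, s = self.series.tr_values, self.series.signals
        if np.ptp(s) == 0:
            raise ValueError("degenerate series: all signals equal")

        def resid(theta):
            s0, t1 = theta
            return s0 * (1.0 - np.exp(-tr / t1)) - s

        x0 = np.array([float(np.max(s)), float(np.median(tr))])
        sol = least_squares(
            resid,
            x0,
            bounds=([1e-12, 1e-6], [np.inf, np.inf]),
            xtol=xtol,
            ftol=xtol,
            gtol=xtol,
            max_nfev=max_iter * 10,
        )
        if not sol.success:
            raise RuntimeError(f"T1 fit did not converge: {sol.message}")
        s0, t1 = map(float, sol.x)
        return T1Results(model=self, s0=s0, t1=t1, rss=float(np.sum(sol.fun**2)))


@dataclass
class T1Results:
    model: T1RecoveryModel
    s0: float   # a.u.
    t1: float   # s
    rss: float  # a.u.^2

    def predict(self, tr: np.ndarray) -> np.ndarray:
        tr = np.asarray(tr, dtype=float)
        return self.s0 * (1.0 - np.exp(-tr / self.t1))

    def summary(self) -> str:
        lines = [
            "Saturation-recovery T1 fit",
            "==========================",
            f"n points      {self.model.series.tr_values.size:>10d}",
            f"s0 (a.u.)     {self.s0:>10.4g}",
            f"T1 (s)        {self.t1:>10.4g}",
            f"RSS (a.u.^2)  {self.rss:>10.4g}",
        ]
        return "\n".join(lines)


def fit_t1(series: TRSeries) -> T1Results:
    """Convenience wrapper: fit the saturation-recovery model to a VTR series."""
    return T1RecoveryModel(series).fit()


def concentration_from_t1(t1_post: float, t1_pre: float, r1: float = 3.5) -> float:
    """Contrast concentration (mM) from pre/post T1 via linear relaxivity.

    C = (1/t1_post - 1/t1_pre) / r1, with r1 in L mmol^-1 s^-1 and T1 in s.
    """
    t1_post = np.asarray(t1_post, dtype=float)
    t1_pre = np.asarray(t1_pre, dtype=float)
    if np.any(t1_post <= 0) or np.any(t1_pre <= 0):
        raise ValueError("T1 values must be positive")
    if r1 <= 0:
        raise ValueError("relaxivity must be positive")
    c = (1.0 / t1_post - 1.0 / t1_pre) / r1
    return float(c) if c.ndim == 0 else c


def signal_from_concentration(
    conc_mM, t1_pre: float, r1: float = 3.5, tr: float = 0.05, s0: float = 1000.0
):
    """Forward T1-weighted signal model for a dynamic series.

    1/T1(t) = 1/t1_pre + r1 * C(t); S = s0 * (1 - exp(-tr / T1(t))).
    Times are s for tr/t1, mM for concentration.
    """
    conc = np.asarray(conc_mM, dtype=float)
    r1_eff = 1.0 / t1_pre + r1 * conc
    return s0 * (1.0 - np.exp(-tr * r1_eff))


def concentration_from_signal(
    signal, t1_pre: float, r1: float = 3.5, tr: float = 0.05, s0: float = 1000.0
):
    """Invert the dynamic signal model back to concentration (mM)."""
    s = np.asarray(signal, dtype=float)
    frac = 1.0 - s / s0
    if np.any(frac <= 0):
        raise ValueError("signal at or above saturation; cannot invert")
    r1_eff = -np.log(frac) / tr
    return (r1_eff - 1.0 / t1_pre) / r1


def _plasma_integral(times: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid of C_p with the convention C_p(0) = 0."""
    from scipy.integrate import cumulative_trapezoid

    return cumulative_trapezoid(cp, times, initial=0.0)


class PatlakModel:
    """Patlak graphical model for one ROI-averaged curve pair.

    Parameters
    ----------
    ct, cp : ConcentrationCurve
        Tissue and plasma concentration curves.  If their grids differ, cp
        is resampled onto ct's grid by linear interpolation.
    fit_window : (t_lo, t_hi) in minutes, optional
        Restrict the regression to this time range (default: full record).
    fit_vp : bool
        If False, force v_p = 0 (slope-only regression through the origin).
    """

    def __init__(
        self,
        ct: ConcentrationCurve,
        cp: ConcentrationCurve,
        fit_window: tuple | None = None,
        fit_vp: bool = True,
    ):
        self.ct = ct
        self.cp = cp
        self.fit_window = fit_window
        self.fit_vp = fit_vp

    def _design(self):
        t = self.ct.times
        cp = self.cp.values
        if self.cp.times.shape != t.shape or not np.allclose(self.cp.times, t):
            cp = np.interp(t, self.cp.times, self.cp.values)
        integral = _plasma_integral(t, cp)
        mask = np.ones(t.size, dtype=bool)
        if self.fit_window is not None:
            lo, hi = self.fit_window
            mask &= (t >= lo) & (t <= hi)
        used = mask & (cp != 0)
        if np.any(mask & (cp < 0)):
            raise ValueError("C_p < 0 inside the fit window")
        # t=0 has cp=0 by convention and is excluded; any other zero is an error
        if np.any(mask & (cp == 0) & (t > t[0])):
            raise ValueError("C_p = 0 at an interior fit point")
        if used.sum() < 2:
            raise ValueError("fewer than 2 usable points in fit_window")
        x = integral[used] / cp[used]
        y = self.ct.values[used] / cp[used]
        return x, y, int(used.sum())

    def fit(self) -> "PatlakResults":
        x, y, n = self._design()
        if self.fit_vp:
            X = np.column_stack([x, np.ones_like(x)])
        else:
            X = x[:, None]
        # closed-form OLS via normal equations kept deterministic
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        yhat = X @ beta
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        # guard the degenerate constant-y case (e.g. ct = vp*cp exactly):
        # a perfect fit of a flat line is R^2 = 1, not 1 - eps/eps
        scale = max(float(np.sum(y**2)), 1.0)
        if ss_tot <= 1e-14 * scale:
            r2 = 1.0 if ss_res <= 1e-14 * scale else 0.0
        else:
            r2 = 1.0 - ss_res / ss_tot
        # OLS standard errors (slope, intercept)
        dof = max(n - X.shape[1], 1)
        sigma2 = ss_res / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        bse = np.sqrt(np.diag(cov))
        ktrans = float(beta[0])
        vp = float(beta[1]) if self.fit_vp else 0.0
        return PatlakResults(
            model=self,
            ktrans=ktrans,
            vp=vp,
            ktrans_se=float(bse[0]),
            vp_se=float(bse[1]) if self.fit_vp else 0.0,
            r_squared=r2,
            n_points_used=n,
        )


@dataclass
class PatlakResults:
    """Patlak fit: Ktrans (min^-1), v_p, their OLS standard errors and R^2."""

    model: PatlakModel
    ktrans: float
    vp: float
    ktrans_se: float
    vp_se: float
    r_squared: float
    n_points_used: int

    def summary(self) -> str:
        lines = [
            "Patlak model fit",
            "================",
            f"n points used        {self.n_points_used:>10d}",
            f"Ktrans (min^-1)      {self.ktrans:>10.4g}  (se {self.ktrans_se:.2g})",
            f"v_p                  {self.vp:>10.4g}  (se {self.vp_se:.2g})",
            f"R-squared            {self.r_squared:>10.4f}",
        ]
        return "\n".join(lines)


def patlak_fit(
    ct: ConcentrationCurve,
    cp: ConcentrationCurve,
    fit_window: tuple | None = None,
    fit_vp: bool = True,
) -> PatlakResults:
    """Fit the Patlak model to one tissue/plasma curve pair."""
    return PatlakModel(ct, cp, fit_window=fit_window, fit_vp=fit_vp).fit()


def enhancement_percent(pre_signal: float, post_signal: float) -> float:
    """Relative MR signal enhancement, 100 * (post - pre) / pre."""
    if pre_signal <= 0:
        raise ValueError("pre_signal must be positive")
    return 100.0 * (post_signal - pre_signal) / pre_signal


def fit_roi_set(
    curves: dict,
    cp: ConcentrationCurve,
    fit_window: tuple | None = None,
    fit_vp: bool = True,
) -> pd.DataFrame:
    """Fit the Patlak model to a collection of ROI tissue curves.

    ``curves`` maps roi_id -> ConcentrationCurve.  Per-ROI failures are
    flagged (NaN estimates, flag column carries the message) rather than
    aborting the batch.  Returns columns roi_id, ktrans_per_min, vp,
    r_squared, flag.
    """
    rows = []
    for roi_id, ct in curves.items():
        try:
            res = patlak_fit(ct, cp, fit_window=fit_window, fit_vp=fit_vp)
            rows.append(
                {
                    "roi_id": roi_id,
                    "ktrans_per_min": res.ktrans,
                    "vp": res.vp,
                    "r_squared": res.r_squared,
                    "flag": "",
                }
            )
        except (ValueError, RuntimeError) as exc:
            rows.append(
                {
                    "roi_id": roi_id,
                    "ktrans_per_min": np.nan,
                    "vp": np.nan,
                    "r_squared": np.nan,
                    "flag": str(exc),
                }
            )
    columns = ["roi_id", "ktrans_per_min", "vp", "r_squared", "flag"]
    return pd.DataFrame(rows, columns=columns)
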