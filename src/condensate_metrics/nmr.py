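"""NMR intensity-ratio and relaxation analysis on peak lists.

Works downstream of spectral processing and assignment: the inputs are
per-residue peak tables (intensity plus a spectral-noise estimate) and
delay–intensity relaxation series.  Provided analyses:

* per-residue intensity-ratio profiles between two spectra, with the
  uncertainty propagated from each peak's signal-to-noise:
  ``sigma = ratio * sqrt((noise_num/I_num)^2 + (noise_den/I_den)^2)``.
  Peaks that fall below a noise multiple (default 3x) are flagged
  "broadened beyond detection" and excluded from the ratio — in a
  titration this is the signature of tight, slow-exchange binding;
* single-exponential fits ``I(t) = A exp(-R t)`` for TRACT-style decay
  series, initialised from a log-linear regression;
* the TRACT cross-correlated relaxation rate
  ``eta_xy = (R_anti - R_trosy) / 2``;
* the two-point paramagnetic relaxation enhancement (PRE) rate
  ``Gamma2 = ln(I_dia / I_para) / delta_t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PeakTable",
    "DecaySeries",
    "PRERecord",
    "FitError",
    "intensity_ratio_profile",
    "fit_exponential",
    "tract_eta",
    "pre_delta_r2",
    "DEFAULT_DETECTION_NOISE_MULTIPLE",
]

#: A peak with intensity below this multiple of its noise sd is treated as
#: broadened beyond detection.
DEFAULT_DETECTION_NOISE_MULTIPLE = 3.0


class FitError(RuntimeError):
    """Exponential fit failed; carries the initialisation values."""

    def __init__(self, message: str, init_amplitude: float | None = None,
                 init_rate: float | None = None):
        super().__init__(message)
        self.init_amplitude = init_amplitude
        self.init_rate = init_rate


@dataclass
class PeakTable:
    """Per-residue peak intensities with spectral noise estimates.

    Wraps a DataFrame with columns ``residue_id`` (unique ints),
    ``residue_name``, ``intensity``, ``noise`` (> 0) and optionally
    ``h_ppm``, ``n_ppm``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"residue_id", "intensity", "noise"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"peak table missing columns: {sorted(missing)}")
        if "residue_name" not in self.data.columns:
            self.data = self.data.assign(residue_name="")
        if self.data["residue_id"].duplicated().any():
            raise ValueError("residue_id must be unique within a peak table")
        if (self.data["noise"] <= 0).any():
            raise ValueError("noise estimates must be positive")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DecaySeries:
    """A relaxation decay: intensity versus delay for one residue.

    ``component`` distinguishes the TROSY and anti-TROSY branches of a
    TRACT experiment (``"generic"`` otherwise).  Delays must be strictly
    increasing with at least two points.
    """

    residue_id: int
    delays_s: np.ndarray
    intensities: np.ndarray
    component: str = "generic"

    def __post_init__(self) -> None:
        self.delays_s = np.asarray(self.delays_s, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.delays_s.size != self.intensities.size:
            raise ValueError("delays and intensities must have equal length")
        if self.delays_s.size < 2:
            raise ValueError("a decay series needs at least 2 points")
        if np.any(self.delays_s < 0) or np.any(np.diff(self.delays_s) <= 0):
            raise ValueError("delays must be non-negative and strictly increasing")
        if self.component not in ("trosy", "anti_trosy", "generic"):
            raise ValueError("component must be trosy, anti_trosy or generic")


@dataclass
class PRERecord:
    """Paired paramagnetic/diamagnetic intensities for the two-point PRE."""

    residue_id: int
    i_para: float
    i_dia: float
    delta_t_s: float
    gamma2_per_s: float | None = None
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.delta_t_s <= 0:
            raise ValueError("delta_t_s must be positive")


# ---------------------------------------------------------------------------
# Intensity ratios
# ---------------------------------------------------------------------------

def intensity_ratio_profile(
    numerator: PeakTable,
    denominator: PeakTable,
    noise_multiple: float = DEFAULT_DETECTION_NOISE_MULTIPLE,
) -> pd.DataFrame:
    """Per-residue intensity ratio numerator/denominator with propagated sigma.

    Returns a table over the union of residue ids with columns
    ``residue_id, ratio, sigma, status`` where status is one of

    * ``"ok"`` — ratio and sigma computed;
    * ``"broadened"`` — either peak's intensity is below
      ``noise_multiple * noise`` (broadened beyond detection); ratio None;
    * ``"missing_numerator"`` / ``"missing_denominator"`` — residue present
      in only one table.

    Raises
    ------
    ValueError
        If the tables share no residue ids.
    """
    num = numerator.data.set_index("residue_id")
    den = denominator.data.set_index("residue_id")
    shared = num.index.intersection(den.index)
    if shared.empty:
        raise ValueError("peak tables share no residue ids")

    rows = []
    for rid in sorted(num.index.union(den.index)):
        if rid not in den.index:
            rows.append({"residue_id": rid, "ratio": None, "sigma": None,
                         "status": "missing_denominator"})
            continue
        if rid not in num.index:
            rows.append({"residue_id": rid, "ratio": None, "sigma": None,
                         "status": "missing_numerator"})
            continue
        i_n, s_n = float(num.at[rid, "intensity"]), float(num.at[rid, "noise"])
        i_d, s_d = float(den.at[rid, "intensity"]), float(den.at[rid, "noise"])
        if i_n < noise_multiple * s_n or i_d < noise_multiple * s_d:
            rows.append({"residue_id": rid, "ratio": None, "sigma": None,
                         "status": "broadened"})
            continue
        ratio = i_n / i_d
        sigma = ratio * np.sqrt((s_n / i_n) ** 2 + (s_d / i_d) ** 2)
        rows.append({"residue_id": rid, "ratio": ratio, "sigma": sigma,
                     "status": "ok"})
    return pd.DataFrame(rows, columns=["residue_id", "ratio", "sigma", "status"])


# ---------------------------------------------------------------------------
# Exponential fitting
# ---------------------------------------------------------------------------

def _loglinear_init(delays: np.ndarray, intensities: np.ndarray) -> tuple[float, float]:
    """Initial (A, R) from a log-linear regression of the positive points."""
    pos = intensities > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(delays[pos], np.log(intensities[pos]), 1)
        return float(np.exp(intercept)), float(max(-slope, 1e-6))
    span = delays[-1] - delays[0]
    return float(abs(intensities[0]) or 1.0), float(1.0 / span)


def fit_exponential(
    series: DecaySeries,
    weights: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Least-squares fit of ``I(t) = A exp(-R t)``.

    Returns ``(rate_per_s, amplitude, rate_sigma)`` with the rate
    uncertainty taken from the fit covariance.  The fit is unweighted by
    default; pass per-point standard deviations in ``weights`` for a
    1/sigma^2-weighted fit.

    Raises
    ------
    FitError
        On fewer than 3 points, a constant series, or non-convergence
        (the error carries the log-linear initialisation).
    """
    t, y = series.delays_s, series.intensities
    if t.size < 3:
        raise FitError("exponential fit needs at least 3 points")
    if np.allclose(y, y[0]):
        raise FitError("constant intensities: decay rate unidentifiable")
    a0, r0 = _loglinear_init(t, y)
    try:
        popt, pcov = curve_fit(
            lambda tt, a, r: a * np.exp(-r * tt),
            t, y, p0=(a0, r0), sigma=weights, absolute_sigma=weights is not None,
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"fit did not converge: {exc}", init_amplitude=a0,
                       init_rate=r0) from exc
    amplitude, rate = float(popt[0]), float(popt[1])
    rate_sigma = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    return rate, amplitude, rate_sigma


def tract_eta(
    trosy: DecaySeries, anti_trosy: DecaySeries
) -> tuple[float, float, float, float]:
    """TRACT cross-correlated relaxation rate from the two decay branches.

    Fits both series and returns ``(r_trosy, r_anti, eta_xy, eta_sigma)``
    with ``eta_xy = (R_anti - R_trosy) / 2`` and the uncertainty combined
    in quadrature from the two fit sigmas.
    """
    r_t, _, s_t = fit_exponential(trosy)
    r_a, _, s_a = fit_exponential(anti_trosy)
    eta = (r_a - r_t) / 2.0
    sigma = float(np.sqrt(s_a**2 + s_t**2) / 2.0)
    return r_t, r_a, eta, sigma


# ---------------------------------------------------------------------------
# PRE
# ---------------------------------------------------------------------------

def pre_delta_r2(rec: PRERecord) -> PRERecord:
    """Two-point PRE rate ``Gamma2 = ln(I_dia / I_para) / delta_t``.

    Returns the record with ``gamma2_per_s`` filled in, or None with a
    reason code when either intensity is non-positive (peak bleached or
    undetected).
    """
    if rec.i_para <= 0:
        rec.gamma2_per_s = None
        rec.reason = "paramagnetic peak undetected (intensity <= 0)"
        return rec
    if rec.i_dia <= 0:
        rec.gamma2_per_s = None
        rec.reason = "diamagnetic peak undetected (intensity <= 0)"
        return rec
    rec.gamma2_per_s = float(np.log(rec.i_dia / rec.i_para) / rec.delta_t_s)
    rec.reason = None
    return rec


def pre_profile(
    para: PeakTable, dia: PeakTable, delta_t_s: float = 0.007
) -> pd.DataFrame:
    """Two-point PRE rates for all residues shared by the two tables."""
    p = para.data.set_index("residue_id")
    d = dia.data.set_index("residue_id")
    shared = p.index.intersection(d.index)
    if shared.empty:
        raise ValueError("peak tables share no residue ids")
    rows = []
    for rid in sorted(shared):
        rec = pre_delta_r2(
            PRERecord(
                residue_id=int(rid),
                i_para=float(p.at[rid, "intensity"]),
                i_dia=float(d.at[rid, "intensity"]),
                delta_t_s=delta_t_s,
            )
        )
        rows.append(
            {"residue_id": rec.residue_id, "gamma2_per_s": rec.gamma2_per_s,
             "reason": rec.reason}
        )
    return pd.DataFrame(rows, columns=["residue_id", "gamma2_per_s", "reason"])
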