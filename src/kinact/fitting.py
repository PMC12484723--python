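"""Two-step estimation of k_inact and K_I from occupancy observations.

Step 1 (`fit_kobs`): for each inhibitor concentration, occupancy-vs-time
points are fitted with the constrained one-phase association
Y = 1 - exp(-k_obs t) (floor 0, plateau 1), giving one apparent rate per
concentration. A single (occupancy, t) point inverts in closed form,
k_obs = -ln(1 - occ)/t.

Step 2 (`fit_mm`): the ([I], k_obs) points are fitted with the hyperbolic
(Michaelis-Menten-form) model k_obs = k_inact [I]/(K_I + [I]), initialized at
k_inact = max(k_obs) and K_I = the concentration nearest half-max. Replicate
k_obs values at the same concentration enter as separate points. The
through-origin Lineweaver-Burk regression k_obs = k_eff * [I] provides the
fallback k_eff when the full fit is non-identifiable.

Positivity is enforced by fitting internally in log parameters with a
trust-region least-squares solver (cost tolerance 1e-10, <= 1000 iterations);
standard errors are symmetric approximations from the local covariance
(delta method back to the natural scale).

`CovalentKineticsModel` wraps the two steps behind a model/results interface:
build from a tidy occupancy table, call ``fit()``, and read estimates,
standard errors and diagnostics off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from .kinetics import KineticParams, OccupancyPoint, RatePoint

__all__ = [
    "KobsFit",
    "MMFit",
    "fit_kobs",
    "fit_mm",
    "fit_lineweaver_burk_origin",
    "CovalentKineticsModel",
    "CovalentKineticsResults",
]

OCC_CLAMP = 1.0 - 1e-6  # occupancy of exactly 1 is clamped here before logs


@dataclass(frozen=True)
class KobsFit:
    """One-phase association fit at a single concentration."""

    conc: float
    k_obs: float
    stderr: Optional[float]
    n_points: int
    rss: float
    flag: str = ""

    def as_rate_point(self, replicate: str = "") -> RatePoint:
        return RatePoint(
            conc=self.conc, k_obs=self.k_obs, stderr=self.stderr,
            replicate=replicate, flag=self.flag,
        )


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten fit of ([I], k_obs): the kinetic endpoint.

    ``status`` is "ok" for a clean two-parameter fit; "keff-only" when the
    data never leave the linear regime (fitted K_I > 10 * max conc, only the
    ratio k_inact/K_I is identified); "kinact-only" when the data sit on the
    plateau (fitted K_I < min conc / 10); "failed" when the optimizer did not
    converge, in which case ``k_eff`` still carries the through-origin
    Lineweaver-Burk estimate.
    """

    params: Optional[KineticParams]
    stderr_kinact: Optional[float]
    stderr_KI: Optional[float]
    stderr_keff: Optional[float]
    k_eff: float
    status: str
    n_points: int
    rss: float
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def fit_kobs(points: Sequence[OccupancyPoint]) -> KobsFit:
    """Fit k_obs from occupancy-vs-time points at one concentration.

    All points must share one concentration (replicates welcome). One point
    with t > 0 gives the closed-form inversion; two or more are fitted by
    least squares under Y = 1 - exp(-k_obs t).
    """
    if not points:
        raise ValueError("no occupancy points supplied")
    concs = {p.conc for p in points}
    if len(concs) != 1:
        raise ValueError(f"fit_kobs expects a single concentration, got {sorted(concs)}")
    conc = points[0].conc
    pts = [p for p in points if p.time > 0]
    if not pts:
        raise ValueError("need at least one point with time > 0")
    t = np.array([p.time for p in pts])
    occ = np.array([min(p.occupancy, OCC_CLAMP) for p in pts])
    n = len(pts)

    if float(np.max(occ)) < 1e-6:
        return KobsFit(conc=conc, k_obs=0.0, stderr=None, n_points=n,
                       rss=float(np.sum(occ**2)), flag="no_signal")

    singles = -np.log1p(-occ) / t
    if n == 1:
        return KobsFit(conc=conc, k_obs=float(singles[0]), stderr=None,
                       n_points=1, rss=0.0)

    def model(tt, k):
        return -np.expm1(-k * tt)

    popt, pcov = curve_fit(
        model, t, occ, p0=[float(np.median(singles))],
        bounds=(0.0, np.inf), maxfev=10_000,
    )
    k = float(popt[0])
    resid = occ - model(t, k)
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else None
    return KobsFit(conc=conc, k_obs=k, stderr=stderr, n_points=n,
                   rss=float(np.sum(resid**2)))


def fit_lineweaver_burk_origin(points: Sequence[RatePoint]) -> float:
    """k_eff as the slope of the no-intercept regression of k_obs on [I].

    In the linear regime ([I] << K_I) k_obs ~= (k_inact/K_I) [I]; the
    through-origin least-squares slope sum(x y)/sum(x^2) is then a stable
    estimator of the inactivation efficiency even when the individual
    parameters are unidentifiable.
    """
    if not points:
        raise ValueError("no rate points supplied")
    x = np.array([p.conc for p in points])
    y = np.array([p.k_obs for p in points])
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("all concentrations are zero; slope undefined")
    return float(np.sum(x * y) / sxx)


def _mm_initial_values(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # k_inact starts at the largest observed rate, K_I at the concentration
    # whose rate is nearest half of that (the YMAX / X-at-YMID rule)
    k0 = float(np.max(y))
    i = int(np.argmin(np.abs(y - 0.5 * k0)))
    ki0 = float(x[i]) if x[i] > 0 else float(np.median(x[x > 0]))
    return max(k0, 1e-12), max(ki0, 1e-15)


def fit_mm(
    points: Sequence[RatePoint],
    weighted: bool = False,
) -> MMFit:
    """Least-squares (k_inact, K_I) from ([I], k_obs) points.

    Residuals are unweighted by default; ``weighted=True`` applies 1/SE^2
    weights where standard errors are available. Standard errors of the
    estimates (and of the derived k_eff) are symmetric approximations from
    the local covariance at the optimum.
    """
    if len(points) < 2:
        raise ValueError("need >= 2 rate points for the Michaelis-Menten fit")
    x = np.array([p.conc for p in points])
    y = np.array([p.k_obs for p in points])
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct concentrations")
    n = len(points)

    if weighted:
        se = np.array([p.stderr if p.stderr else np.nan for p in points])
        w = np.where(np.isfinite(se) & (se > 0), 1.0 / se, 1.0)
    else:
        w = np.ones(n)

    lb = fit_lineweaver_burk_origin(points)

    if float(np.max(y)) <= 0.0:
        return MMFit(params=None, stderr_kinact=None, stderr_KI=None,
                     stderr_keff=None, k_eff=lb, status="failed", n_points=n,
                     rss=float(np.sum((w * y) ** 2)), message="all rates are zero")

    k0, ki0 = _mm_initial_values(x, y)
    theta0 = np.log([k0, ki0])

    def resid(theta):
        a, b = np.exp(theta)
        return w * (y - a * x / (b + x))

    sol = least_squares(resid, theta0, method="trf", ftol=1e-10, xtol=1e-12,
                        gtol=1e-12, max_nfev=1000)
    if not sol.success:
        return MMFit(params=None, stderr_kinact=None, stderr_KI=None,
                     stderr_keff=None, k_eff=lb, status="failed", n_points=n,
                     rss=float(np.nan), message=f"optimizer: {sol.message}")

    k_inact, K_I = np.exp(sol.x)
    rss = float(2.0 * sol.cost)
    dof = max(n - 2, 1)
    s2 = rss / dof
    J = sol.jac
    try:
        cov_theta = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov_theta = np.full((2, 2), np.nan)
    # delta method: d k_inact/d theta1 = k_inact, etc.; k_eff = exp(th1 - th2)
    se_kinact = float(k_inact * np.sqrt(cov_theta[0, 0])) if np.isfinite(cov_theta[0, 0]) else None
    se_KI = float(K_I * np.sqrt(cov_theta[1, 1])) if np.isfinite(cov_theta[1, 1]) else None
    ke = k_inact / K_I
    var_keff = ke**2 * (cov_theta[0, 0] + cov_theta[1, 1] - 2 * cov_theta[0, 1])
    se_keff = float(np.sqrt(var_keff)) if np.isfinite(var_keff) and var_keff >= 0 else None

    params = KineticParams(k_inact=float(k_inact), K_I=float(K_I))
    status = "ok"
    k_eff_out = params.k_eff
    # identifiability guards mirroring the two-point triage logic at full scale
    if K_I > 10.0 * float(np.max(x)):
        status = "keff-only"
        k_eff_out = lb  # only the initial slope is determined by the data
    elif K_I < float(np.min(x[x > 0], initial=np.inf)) / 10.0:
        status = "kinact-only"
    return MMFit(params=params, stderr_kinact=se_kinact, stderr_KI=se_KI,
                 stderr_keff=se_keff, k_eff=float(k_eff_out), status=status,
                 n_points=n, rss=rss)


class CovalentKineticsModel:
    """Two-step kinetic model for one analyte's occupancy observations.

    Parameters
    ----------
    data : pandas.DataFrame
        Tidy occupancy table with columns ``conc`` (M), ``time`` (s),
        ``occupancy`` (fraction) and optionally ``replicate``.
    weighted : bool
        Apply 1/SE^2 weights in the second stage.

    Examples
    --------
    >>> res = CovalentKineticsModel(df).fit()
    >>> res.params.k_inact, res.params.K_I, res.k_eff
    """

    def __init__(self, data: pd.DataFrame, weighted: bool = False):
        required = {"conc", "time", "occupancy"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"occupancy table is missing columns: {sorted(missing)}")
        self.data = data.copy()
        if "replicate" not in self.data.columns:
            self.data["replicate"] = ""
        # empty labels can round-trip through TSV as NaN; groupby would drop them
        self.data["replicate"] = self.data["replicate"].fillna("").astype(str)
        self.weighted = weighted

    @classmethod
    def from_points(cls, points: Sequence[OccupancyPoint], **kw) -> "CovalentKineticsModel":
        df = pd.DataFrame(
            [
                {"conc": p.conc, "time": p.time, "occupancy": p.occupancy,
                 "replicate": p.replicate}
                for p in points
            ]
        )
        return cls(df, **kw)

    def fit(self) -> "CovalentKineticsResults":
        kobs_fits: list[KobsFit] = []
        rate_points: list[RatePoint] = []
        # replicate occupancy sets are fitted separately; their k_obs values
        # then enter the MM stage jointly as independent points
        for (rep, conc), grp in self.data.groupby(["replicate", "conc"], sort=True):
            pts = [
                OccupancyPoint(conc=float(conc), time=float(r.time),
                               occupancy=float(np.clip(r.occupancy, 0.0, 1.0)),
                               replicate=str(rep))
                for r in grp.itertuples()
            ]
            kf = fit_kobs(pts)
            kobs_fits.append(kf)
            if kf.flag != "no_signal":
                rate_points.append(kf.as_rate_point(replicate=str(rep)))
        if len(rate_points) >= 2 and len({p.conc for p in rate_points}) >= 2:
            mm = fit_mm(rate_points, weighted=self.weighted)
        else:
            lbp = rate_points or [k.as_rate_point() for k in kobs_fits]
            try:
                lb = fit_lineweaver_burk_origin(lbp)
            except ValueError:
                lb = 0.0
            mm = MMFit(params=None, stderr_kinact=None, stderr_KI=None,
                       stderr_keff=None, k_eff=lb, status="failed",
                       n_points=len(rate_points), rss=float("nan"),
                       message="insufficient concentrations with signal")
        return CovalentKineticsResults(model=self, kobs_fits=kobs_fits, mm=mm)


@dataclass
class CovalentKineticsResults:
    """Estimates, uncertainties and diagnostics of the two-step fit."""

    model: CovalentKineticsModel
    kobs_fits: list[KobsFit]
    mm: MMFit

    @property
    def params(self) -> Optional[KineticParams]:
        return self.mm.params

    @property
    def k_eff(self) -> float:
        return self.mm.k_eff

    @property
    def status(self) -> str:
        return self.mm.status

    @property
    def bse(self) -> dict:
        """Standard errors of the natural-scale estimates."""
        return {
            "k_inact": self.mm.stderr_kinact,
            "K_I": self.mm.stderr_KI,
            "k_eff": self.mm.stderr_keff,
        }

    def kobs_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"conc_M": k.conc, "k_obs_s": k.k_obs, "stderr": k.stderr,
                 "n_points": k.n_points, "rss": k.rss, "flag": k.flag}
                for k in self.kobs_fits
            ]
        )

    def summary(self) -> str:
        lines = ["Two-step covalent kinetics fit", "=" * 46]
        lines.append(f"status: {self.status}   n(k_obs points): {self.mm.n_points}")
        if self.params is not None:
            se = self.bse
            lines.append(
                f"k_inact = {self.params.k_inact:.4g} s^-1"
                + (f"  (SE {se['k_inact']:.2g})" if se["k_inact"] else "")
            )
            lines.append(
                f"K_I     = {self.params.K_I:.4g} M"
                + (f"  (SE {se['K_I']:.2g})" if se["K_I"] else "")
            )
        lines.append(f"k_eff   = {self.k_eff:.4g} M^-1 s^-1")
        lines.append("-" * 46)
        lines.append(f"{'conc (M)':>12} {'k_obs (s^-1)':>14} {'n':>3} {'flag':>10}")
        for k in self.kobs_fits:
            lines.append(f"{k.conc:>12.3e} {k.k_obs:>14.4e} {k.n_points:>3} {k.flag:>10}")
        return "\n".join(lines)
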