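"""Non-compartmental analysis of concentration-time profiles.

Emulates the common commercial defaults: the terminal rate constant
``lambda_z`` is the log-linear regression over the suffix window (>= 3
points, excluding tmax) that maximizes adjusted R^2, ties broken toward
more points; AUC uses the linear-up/log-down trapezoid by default with an
all-linear alternative; AUC(0, inf) adds ``C_last / lambda_z``.  Apparent
clearance is ``dose / AUC(0, inf)`` (CL/F for extravascular routes) and
``Vz = CL / lambda_z``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConcProfile",
    "NCAResult",
    "NCAError",
    "fit_lambda_z",
    "auc",
    "run_nca",
    "read_profiles",
    "write_profiles",
]

#: Default assay lower limit of quantification, ng/mL (plasma assay linear
#: range 1-1000 ng/mL).
DEFAULT_LLOQ = 1.0


class NCAError(ValueError):
    """Raised when a profile does not admit the requested estimate."""


@dataclass(frozen=True)
class ConcProfile:
    """One subject's concentration-time profile.

    Times in hours (strictly increasing after construction — inputs are
    sorted), concentrations in ng/mL, dose in mg/kg.
    """

    times: tuple[float, ...]
    conc: tuple[float, ...]
    dose: float                 # mg/kg
    route: str = "ip"
    subject: str = "sim"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.conc):
            raise NCAError("times and concentrations differ in length")
        if len(self.times) < 3:
            raise NCAError("need at least 3 samples")
        order = np.argsort(np.asarray(self.times))
        t = tuple(float(self.times[i]) for i in order)
        c = tuple(float(self.conc[i]) for i in order)
        if any(t2 <= t1 for t1, t2 in zip(t, t[1:])):
            raise NCAError("sampling times must be distinct")
        if any(x < 0 for x in c):
            raise NCAError("concentrations must be >= 0")
        if not any(x > 0 for x in c):
            raise NCAError("profile has no positive concentration")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.times), np.asarray(self.conc)

    def censored(self, lloq: float) -> tuple["ConcProfile", int]:
        """Drop samples below the LLOQ; returns (profile, number dropped)."""
        t, c = self.arrays()
        keep = c >= lloq
        dropped = int((~keep).sum())
        if keep.sum() < 3:
            raise NCAError("fewer than 3 samples remain above the LLOQ")
        return ConcProfile(tuple(t[keep]), tuple(c[keep]), self.dose,
                           self.route, self.subject), dropped


@dataclass(frozen=True)
class NCAResult:
    """WinNonlin-style parameter set with internal-consistency guarantees."""

    cmax: float          # ng/mL
    tmax: float          # h
    auc_0_t: float       # h*ng/mL
    auc_0_inf: float     # h*ng/mL
    lambda_z: float      # 1/h
    t_half: float        # h
    cl: float            # mL/h/kg (CL/F for extravascular dosing)
    vz: float            # L/kg
    n_lambda_points: int
    r2_adj: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _adjusted_r2(t: np.ndarray, logc: np.ndarray) -> tuple[float, float]:
    """Slope and adjusted R^2 of the least-squares line through (t, logc)."""
    n = len(t)
    slope, intercept = np.polyfit(t, logc, 1)
    resid = logc - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((logc - logc.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, r2_adj


def fit_lambda_z(profile: ConcProfile) -> tuple[float, float, int]:
    """Terminal elimination rate constant by best-adjusted-R^2 window search.

    Candidate windows are the suffixes of the positive-concentration samples
    strictly after tmax, each with >= 3 points; the window with the highest
    adjusted R^2 wins, ties (within 1e-9) broken toward more points.

    Returns ``(lambda_z, r2_adj, n_points)``.  Raises :class:`NCAError` when
    no window exists or the best slope is non-negative.
    """
    t, c = profile.arrays()
    i_max = int(np.argmax(c))
    mask = (np.arange(len(t)) > i_max) & (c > 0)
    t_tail, c_tail = t[mask], np.log(c[mask])
    n = len(t_tail)
    if n < 3:
        raise NCAError("need >= 3 positive samples after tmax for lambda_z")
    best: tuple[float, int, float] | None = None   # (r2_adj, n_points, slope)
    for start in range(n - 2):
        slope, r2_adj = _adjusted_r2(t_tail[start:], c_tail[start:])
        n_pts = n - start
        if best is None or r2_adj > best[0] + 1e-9:
            best = (r2_adj, n_pts, slope)
        # equal fits prefer more points: earlier (longer) windows already won
    r2_adj, n_pts, slope = best
    if slope >= 0:
        raise NCAError("terminal slope is non-negative; lambda_z undefined")
    return float(-slope), float(r2_adj), int(n_pts)


def auc(profile: ConcProfile, method: str = "lin_up_log_down",
        extrapolate: bool = False,
        lambda_z: float | None = None) -> tuple[float, float | None]:
    """AUC(0, t_last) by trapezoids, optionally extrapolated to infinity.

    ``lin_up_log_down`` uses the linear trapezoid while concentrations rise
    or stay level and the logarithmic trapezoid while they fall; ``linear``
    uses the linear rule throughout.  With ``extrapolate`` the terminal tail
    ``C_last / lambda_z`` is added (``lambda_z`` fitted if not supplied).

    Returns ``(auc_0_t, auc_0_inf | None)``.
    """
    if method not in ("lin_up_log_down", "linear"):
        raise NCAError(f"unknown AUC method {method!r}")
    t, c = profile.arrays()
    total = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if method == "lin_up_log_down" and 0 < c2 < c1:
            total += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            total += dt * 0.5 * (c1 + c2)
    if not extrapolate:
        return total, None
    if lambda_z is None:
        lambda_z, _, _ = fit_lambda_z(profile)
    if lambda_z <= 0:
        raise NCAError("extrapolation requires lambda_z > 0")
    c_last = next((x for x in reversed(c) if x > 0), 0.0)
    return total, total + c_last / lambda_z


def run_nca(profile: ConcProfile, auc_method: str = "lin_up_log_down",
            lloq: float | None = None) -> NCAResult:
    """Full NCA: Cmax/tmax, AUCs, lambda_z, half-life, clearance, Vz.

    Samples below ``lloq`` (ng/mL) are dropped before analysis when a limit
    is given.  Dose is taken from the profile (mg/kg), so CL comes out in
    mL/h/kg and Vz in L/kg.
    """
    if lloq is not None:
        profile, _ = profile.censored(lloq)
    t, c = profile.arrays()
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    lambda_z, r2_adj, n_pts = fit_lambda_z(profile)
    auc_0_t, auc_0_inf = auc(profile, method=auc_method, extrapolate=True,
                             lambda_z=lambda_z)
    if not profile.dose > 0:
        raise NCAError("dose must be > 0 for clearance and volume terms")
    dose_ng_per_kg = profile.dose * 1.0e6
    cl = dose_ng_per_kg / auc_0_inf           # mL/h/kg
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        auc_0_t=float(auc_0_t),
        auc_0_inf=float(auc_0_inf),
        lambda_z=lambda_z,
        t_half=math.log(2.0) / lambda_z,
        cl=cl,
        vz=cl / lambda_z / 1000.0,            # L/kg
        n_lambda_points=n_pts,
        r2_adj=r2_adj,
    )


# -- tidy tabular I/O ---------------------------------------------------------

def write_profiles(profiles: list[ConcProfile], path: str) -> None:
    """Write profiles as tidy TSV: subject, time_h, conc_ng_ml, dose_mg_kg, route."""
    rows = [
        {"subject": p.subject, "time_h": t, "conc_ng_ml": c,
         "dose_mg_kg": p.dose, "route": p.route}
        for p in profiles for t, c in zip(p.times, p.conc)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles(path: str) -> list[ConcProfile]:
    """Read profiles from the tidy TSV format written by :func:`write_profiles`."""
    table = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for subject, grp in table.groupby("subject", sort=False):
        out.append(ConcProfile(
            times=tuple(grp["time_h"]),
            conc=tuple(grp["conc_ng_ml"]),
            dose=float(grp["dose_mg_kg"].iloc[0]),
            route=str(grp["route"].iloc[0]),
            subject=str(subject),
        ))
    return out
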