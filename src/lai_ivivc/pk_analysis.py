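"""Non-compartmental analysis and biexponential unit-impulse-response fitting.

The disposition of the drug after an IV bolus is summarised by the unit
impulse response (UIR)

    C_delta(t) = A exp(-alpha t) + B exp(-beta t)   [ng/mL per microgram]

from a two-compartment, first-order-elimination fit to the mean IV profile.
The per-microgram dose basis is explicit: a dose in mg/kg times body weight
in g equals the dose in micrograms, so C(0) = dose_ug * (A + B).  Note the
macro-constant naming keeps alpha as the *slow* (terminal) rate here,
matching how the constants are reported for this dataset.

NCA follows standard practice: Cmax/tmax from the observed maximum, linear
trapezoidal AUC (a linear-up/log-down variant is available), terminal slope
lambda_z by best-adjusted-R^2 log-linear regression over candidate terminal
windows, and partial AUCs at fixed cut times by interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "ConcProfile",
    "UIR",
    "NCAResult",
    "nca",
    "fit_uir",
    "eval_uir",
    "mean_profile",
]

DEFAULT_PARTIAL_TIMES = (48.0, 168.0, 672.0, 2016.0)


@dataclass
class ConcProfile:
    """Plasma concentration-time profile for one subject (or a group mean).

    conc is in ng/mL; non-positive or missing observations may be NaN.
    ``dose`` is in mg/kg and ``body_weight`` in g, so ``dose_ug`` is their
    product (1 mg/kg in a 269 g rat = 269 ug).
    """

    subject_id: str
    times: np.ndarray
    conc: np.ndarray
    route: str = "SC"
    dose: float = math.nan          # mg/kg
    body_weight: float = math.nan   # g

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.conc = np.asarray(self.conc, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.shape != self.conc.shape:
            raise ValueError("times and conc must align")
        if self.route not in ("IV", "SC"):
            raise ValueError("route must be 'IV' or 'SC'")
        with np.errstate(invalid="ignore"):
            if np.any(self.conc[np.isfinite(self.conc)] < 0):
                raise ValueError("concentrations must be >= 0 or missing")

    @property
    def dose_ug(self) -> float:
        return self.dose * self.body_weight


@dataclass(frozen=True)
class UIR:
    """Biexponential unit impulse response, per-microgram dose basis.

    ``alpha`` is the slow (terminal) macro-rate and ``beta`` the fast one in
    this parameterisation; both must be positive, amplitudes non-negative.
    """

    A: float
    B: float
    alpha: float
    beta: float
    dose_basis: str = "ug"

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise ValueError("A and B must be >= 0")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")

    def evaluate(self, t):
        """ng/mL per unit dose at time(s) t >= 0."""
        t = np.asarray(t, float)
        out = self.A * np.exp(-self.alpha * t) + self.B * np.exp(-self.beta * t)
        return out if out.ndim else float(out)

    def cumulative(self, s):
        """Running integral g(s) = int_0^s C_delta(u) du (closed form)."""
        s = np.maximum(np.asarray(s, float), 0.0)
        out = (self.A / self.alpha * (1.0 - np.exp(-self.alpha * s))
               + self.B / self.beta * (1.0 - np.exp(-self.beta * s)))
        return out if out.ndim else float(out)

    @property
    def auc_inf_per_unit(self) -> float:
        """AUC(0, inf) per unit dose: A/alpha + B/beta."""
        return self.A / self.alpha + self.B / self.beta


def eval_uir(uir: UIR, t, dose_ug: float):
    """Concentration (ng/mL) at time(s) t for a bolus of ``dose_ug``."""
    out = np.asarray(uir.evaluate(t)) * dose_ug
    return out if out.ndim else float(out)


@dataclass
class NCAResult:
    """Non-compartmental PK summary of one profile."""

    cmax: float
    tmax: float
    tlast: float
    auc_last: float
    auc_partial: dict[float, float] = field(default_factory=dict)
    c0: float = math.nan            # IV back-extrapolated
    auc_inf: float = math.nan
    lambda_z: float = math.nan
    t_half: float = math.nan
    lambda_z_n_points: int = 0
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {"Cmax": self.cmax, "tmax": self.tmax, "tlast": self.tlast,
             "AUC_last": self.auc_last, "C0": self.c0, "AUC_inf": self.auc_inf,
             "lambda_z": self.lambda_z, "t_half": self.t_half}
        for k, v in self.auc_partial.items():
            d[f"AUC_{k:g}h"] = v
        return d


def _auc_linear(t, c):
    return float(np.trapezoid(c, t))


def _auc_linlog(t, c):
    """Linear-up/log-down trapezoid."""
    total = 0.0
    for i in range(1, t.size):
        c0, c1 = c[i - 1], c[i]
        dt = t[i] - t[i - 1]
        if c1 < c0 and c1 > 0 and c0 > 0:
            total += dt * (c0 - c1) / math.log(c0 / c1)
        else:
            total += dt * (c0 + c1) / 2.0
    return total


def _terminal_slope(t, c, tmax_idx):
    """lambda_z by log-linear OLS; window chosen by max adjusted R^2.

    Candidate windows end at tlast and contain >= 3 positive observations
    after (and excluding) Cmax.  Ties in adjusted R^2 go to the window with
    more points.
    """
    idx = np.nonzero((c > 0) & (np.arange(t.size) > tmax_idx))[0]
    if idx.size < 3:
        return math.nan, 0
    x = t[idx]
    y = np.log(c[idx])
    # suffix regressions in one backward pass via running sums
    best = None
    Sx = Sy = Sxx = Syy = Sxy = 0.0
    n = 0
    for i in range(x.size - 1, -1, -1):
        xi, yi = float(x[i]), float(y[i])
        Sx += xi; Sy += yi; Sxx += xi * xi; Syy += yi * yi; Sxy += xi * yi
        n += 1
        if n < 3:
            continue
        sxx = Sxx - Sx * Sx / n
        sxy = Sxy - Sx * Sy / n
        syy = Syy - Sy * Sy / n
        if sxx <= 0 or syy <= 0:
            continue
        slope = sxy / sxx
        if slope >= 0:
            continue
        r2 = sxy * sxy / (sxx * syy)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        key = (round(adj, 10), n)
        if best is None or key > best[0]:
            best = (key, -slope, n)
    if best is None:
        return math.nan, 0
    return float(best[1]), int(best[2])


def nca(profile: ConcProfile,
        partial_times: Sequence[float] = DEFAULT_PARTIAL_TIMES,
        auc_method: str = "linear") -> NCAResult:
    """Non-compartmental analysis of a single concentration-time profile.

    Missing (NaN) observations are dropped (below-quantification handling is
    the caller's choice; by default such values should be passed as NaN).
    Partial AUCs at cut times beyond tlast are reported as AUC to tlast and
    flagged as truncated rather than extrapolated.
    """
    ok = np.isfinite(profile.conc)
    t = profile.times[ok]
    c = profile.conc[ok]
    if t.size < 3:
        raise ValueError("need at least 3 observations")
    flags: list[str] = []

    # prepend t=0: C(0)=0 for extravascular input; for IV back-extrapolate
    c0 = math.nan
    if profile.route == "IV":
        if t[0] > 0:
            pos = np.nonzero(c > 0)[0]
            if pos.size >= 2 and c[pos[0]] > c[pos[1]]:
                i, j = pos[0], pos[1]
                slope = (math.log(c[j]) - math.log(c[i])) / (t[j] - t[i])
                c0 = float(math.exp(math.log(c[i]) - slope * t[i]))
            else:
                c0 = float(c[0])
                flags.append("C0 fallback: first observed concentration")
            t = np.concatenate([[0.0], t])
            c = np.concatenate([[c0], c])
        else:
            c0 = float(c[0])
    elif t[0] > 0:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[0.0], c])

    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])
    tlast = float(t[-1])
    auc_fun = _auc_linear if auc_method == "linear" else _auc_linlog
    auc_last = auc_fun(t, c)

    partial = {}
    for cut in partial_times:
        if cut >= tlast:
            partial[float(cut)] = auc_last
            if cut > tlast:
                flags.append(f"AUC_{cut:g}h truncated at tlast={tlast:g}")
            continue
        ci = float(np.interp(cut, t, c))
        mask = t <= cut
        tt = np.concatenate([t[mask], [cut]])
        cc = np.concatenate([c[mask], [ci]])
        partial[float(cut)] = auc_fun(tt, cc)

    lam, npts = _terminal_slope(t, c, imax)
    if math.isnan(lam):
        flags.append("lambda_z not estimable")
        t_half = math.nan
        auc_inf = math.nan
    else:
        t_half = math.log(2.0) / lam
        auc_inf = auc_last + float(c[-1]) / lam if c[-1] > 0 else auc_last

    return NCAResult(cmax=cmax, tmax=tmax, tlast=tlast, auc_last=auc_last,
                     auc_partial=partial, c0=c0, auc_inf=auc_inf,
                     lambda_z=lam, t_half=t_half, lambda_z_n_points=npts,
                     flags=flags)


def mean_profile(profiles: Sequence[ConcProfile],
                 subject_id: str = "mean") -> ConcProfile:
    """Point-wise mean profile across subjects sharing one time grid."""
    t0 = profiles[0].times
    for p in profiles[1:]:
        if not np.array_equal(p.times, t0):
            raise ValueError("profiles must share one sampling schedule")
    conc = np.nanmean(np.vstack([p.conc for p in profiles]), axis=0)
    return ConcProfile(subject_id=subject_id, times=t0.copy(), conc=conc,
                       route=profiles[0].route, dose=profiles[0].dose,
                       body_weight=float(np.mean([p.body_weight
                                                  for p in profiles])))


def _strip_biexponential(t, cn):
    """Curve-stripping initial estimates (terminal log-linear + residuals)."""
    k = max(t.size // 2, 2)
    xs, ys = t[-k:], np.log(cn[-k:])
    slope, intercept = np.polyfit(xs, ys, 1)
    alpha0 = max(-slope, 1e-6)
    A0 = math.exp(intercept)
    resid = cn - A0 * np.exp(-alpha0 * t)
    early = resid[: max(t.size - k, 2)]
    te = t[: max(t.size - k, 2)]
    good = early > 0
    if good.sum() >= 2:
        slope2, intercept2 = np.polyfit(te[good], np.log(early[good]), 1)
        beta0 = max(-slope2, alpha0 * 3)
        B0 = math.exp(intercept2)
    else:
        beta0, B0 = alpha0 * 10.0, A0 / 3.0
    return A0, B0, alpha0, beta0


def fit_uir(profile: ConcProfile) -> UIR:
    """Fit ``C(t)/dose_ug = A e^{-alpha t} + B e^{-beta t}`` to an IV profile.

    Initialisation is by curve stripping; the refinement is unweighted least
    squares on the concentration scale.  A mono-exponential profile yields a
    degenerate second phase (B ~ 0), which is tolerated.
    """
    if profile.route != "IV":
        raise ValueError("UIR is estimated from IV data")
    ok = np.isfinite(profile.conc) & (profile.conc > 0)
    t = profile.times[ok]
    c = profile.conc[ok]
    if t.size < 4:
        raise ValueError("need at least 4 positive observations")
    dose_ug = profile.dose_ug
    if not math.isfinite(dose_ug) or dose_ug <= 0:
        raise ValueError("dose and body weight must give a positive dose_ug")
    cn = c / dose_ug

    A0, B0, alpha0, beta0 = _strip_biexponential(t, cn)

    def resid(p):
        A, B, la, lb = p
        return A * np.exp(-la * t) + B * np.exp(-lb * t) - cn

    # amplitude/rate bounds keep the weakly identified fast phase physical:
    # nothing decays much faster than ~10/t_first (no data would see it), and
    # back-extrapolated C(0) cannot plausibly exceed 10x the first observation
    amp_ub = 10.0 * float(np.max(cn))
    rate_ub = 10.0 / float(t[0])
    x0 = [min(A0, amp_ub * 0.9), min(B0, amp_ub * 0.9),
          min(alpha0, rate_ub * 0.9), min(beta0, rate_ub * 0.9)]
    res = optimize.least_squares(
        resid, x0=x0,
        bounds=([0.0, 0.0, 1e-9, 1e-9], [amp_ub, amp_ub, rate_ub, rate_ub]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=10000)
    if not res.success:
        raise RuntimeError(
            f"UIR fit did not converge (stripped start {A0, B0, alpha0, beta0})")
    A, B, la, lb = res.x
    if la > lb:  # keep alpha as the slow macro-rate
        A, B, la, lb = B, A, lb, la
    return UIR(A=float(A), B=float(B), alpha=float(la), beta=float(lb))
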