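"""Empirical drug-release models for depot formulations.

The workhorse is the Korsmeyer-Peppas power law ``F(t) = K * t**n`` (fraction of
dose released at time ``t``), fitted piecewise: an initial burst, a slower
diffusion-controlled phase, and -- for slowly eroding polymer grades -- a late
accelerated phase driven by polymer erosion.  Phases combine *additively*; each
phase stops growing at the end of its window and its contribution is frozen
there; the total is capped at complete release.

Conventions for a triphasic profile (validated against published release
summaries for in situ gel depots):

* burst: anchored at t = 0, grows on [0, t_burst_end], frozen after;
* second phase: anchored at t = 0 (in vitro), co-growing with the burst,
  frozen at the end of its window;
* third phase: anchored at its own start time.

Higuchi is the power law with ``n`` fixed at 0.5; the Peppas-Sahlin two-term
form is provided as an alternative model, without a phase/window structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PowerLawPhase",
    "PeppasSahlinModel",
    "CompositeReleaseModel",
    "FitResult",
    "higuchi",
    "eval_power_law",
    "eval_composite",
    "fit_power_law",
    "fit_composite",
    "goodness_of_fit_pearson",
    "classify_mechanism",
    "regress_K_on_solubility",
]


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerLawPhase:
    """One power-law release phase ``K * (t - anchor)**n`` active on a window.

    Parameters
    ----------
    K : float
        Release rate constant, units h^-n (on the fraction scale).
    n : float
        Release exponent (dimensionless); diagnoses the mechanism.
    t_start, t_end : float
        Growth window in hours.  The contribution is zero before the anchor,
        grows until ``t_end`` and stays frozen at its ``t_end`` value after.
    anchor : float
        Time origin of the power law (0 for burst/second phase, the phase
        start for a late erosion phase).  Must satisfy ``anchor <= t_start``.
    """

    K: float
    n: float
    t_start: float = 0.0
    t_end: float = math.inf
    anchor: float = 0.0

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError(f"K must be >= 0, got {self.K}")
        if self.n <= 0:
            raise ValueError(f"n must be > 0, got {self.n}")
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.anchor > self.t_start:
            raise ValueError("anchor must be <= t_start")

    def contribution(self, t):
        """Frozen-at-window-end contribution of this phase at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        tt = np.minimum(t, self.t_end)
        out = np.where(tt > self.anchor,
                       self.K * np.maximum(tt - self.anchor, 0.0) ** self.n,
                       0.0)
        return out if out.ndim else float(out)

    def rate(self, t):
        """d(contribution)/dt; zero outside (anchor, t_end)."""
        t = np.asarray(t, dtype=float)
        active = (t > self.anchor) & (t <= self.t_end)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.K * self.n * np.maximum(t - self.anchor, 0.0) ** (self.n - 1.0)
        out = np.where(active, r, 0.0)
        return out if out.ndim else float(out)


def higuchi(K: float, t_start: float = 0.0, t_end: float = math.inf,
            anchor: float = 0.0) -> PowerLawPhase:
    """Higuchi square-root-of-time release: power law with n = 0.5."""
    return PowerLawPhase(K=K, n=0.5, t_start=t_start, t_end=t_end, anchor=anchor)


@dataclass(frozen=True)
class PeppasSahlinModel:
    """Two-mechanism release ``F(t) = K1*t**n1 + K2*t**n2``.

    The first term is conventionally the Fickian contribution and the second
    the relaxational one.  Provided as an alternative fit form; the piecewise
    power law is the primary model here.
    """

    K1: float
    K2: float
    n1: float
    n2: float

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.K2 < 0:
            raise ValueError("K1 and K2 must be >= 0")

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        out = self.K1 * t ** self.n1 + self.K2 * t ** self.n2
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class CompositeReleaseModel:
    """Ordered additive power-law phases, capped at complete release."""

    phases: tuple[PowerLawPhase, ...]
    cap: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        if not self.phases:
            raise ValueError("at least one phase required")
        if self.cap <= 0:
            raise ValueError("cap must be positive")

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        total = np.zeros_like(t)
        for ph in self.phases:
            total = total + ph.contribution(t)
        out = np.minimum(total, self.cap)
        return out if out.ndim else float(out)

    def evaluate_uncapped(self, t):
        t = np.asarray(t, dtype=float)
        total = np.zeros_like(t)
        for ph in self.phases:
            total = total + ph.contribution(t)
        return total if total.ndim else float(total)

    def rate(self, t):
        """Release rate (fraction/h); zero once the cap has been reached."""
        t = np.asarray(t, dtype=float)
        r = np.zeros_like(t)
        for ph in self.phases:
            r = r + ph.rate(t)
        ct = self.cap_time()
        if ct is not None:
            r = np.where(t > ct, 0.0, r)
        return r if r.ndim else float(r)

    def cap_time(self) -> Optional[float]:
        """First time the uncapped sum reaches the cap, or None if never."""
        hi = max(ph.t_end for ph in self.phases if np.isfinite(ph.t_end))
        if self.evaluate_uncapped(hi) < self.cap:
            return None
        lo = 0.0
        f = lambda t: self.evaluate_uncapped(t) - self.cap
        return float(optimize.brentq(f, lo, hi, xtol=1e-10))

    def scaled(self, factors: Sequence[float],
               windows: Optional[Sequence[tuple]] = None,
               anchors: Optional[Sequence[float]] = None) -> "CompositeReleaseModel":
        """Return a copy with each phase K multiplied by a factor.

        ``windows``/``anchors`` optionally re-map the phase windows and time
        origins (used when translating in vitro fits to in vivo release).
        Entries of ``factors`` set to None drop the phase.
        """
        new = []
        for i, ph in enumerate(self.phases):
            if factors[i] is None:
                continue
            kw = {"K": ph.K * factors[i]}
            if windows is not None and windows[i] is not None:
                kw["t_start"], kw["t_end"] = windows[i]
            if anchors is not None and anchors[i] is not None:
                kw["anchor"] = anchors[i]
            new.append(replace(ph, **kw))
        return CompositeReleaseModel(phases=tuple(new), cap=self.cap)

    def time_to_fraction(self, q: float, t_max: float = 1e6) -> Optional[float]:
        """Solve ``evaluate(t) == q`` by root finding; None if never reached."""
        hi = max((ph.t_end for ph in self.phases if np.isfinite(ph.t_end)),
                 default=t_max)
        hi = min(max(hi, 1.0), t_max)
        if self.evaluate(hi) < q:
            return None
        f = lambda t: self.evaluate(t) - q
        return float(optimize.brentq(f, 0.0, hi, xtol=1e-9))


@dataclass
class FitResult:
    """Outcome of a release-model fit."""

    model: CompositeReleaseModel | PowerLawPhase
    sse: float
    pearson_r: float = math.nan
    windows: tuple = ()
    converged: bool = True
    message: str = ""
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# evaluation (functional wrappers)
# ---------------------------------------------------------------------------

def eval_power_law(phase: PowerLawPhase, t):
    """Fraction contributed by one phase at time(s) ``t`` (frozen past t_end)."""
    return phase.contribution(t)


def eval_composite(model: CompositeReleaseModel, t):
    """Total fraction released at time(s) ``t``, capped."""
    return model.evaluate(t)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _profile_arrays(profile):
    """Accept a ReleaseProfile-like object or a (times, fractions) pair."""
    if hasattr(profile, "times") and hasattr(profile, "mean"):
        return np.asarray(profile.times, float), np.asarray(profile.mean, float)
    times, frac = profile
    return np.asarray(times, float), np.asarray(frac, float)


def _best_K_fixed_n(x_pow, y):
    """Optimal K for F = K * x_pow by linear least squares, clipped to >= 0."""
    denom = float(x_pow @ x_pow)
    if denom == 0.0:
        return 0.0
    return max(float(x_pow @ y) / denom, 0.0)


def fit_power_law(profile, window: Optional[tuple] = None,
                  fixed_n: Optional[float] = None,
                  anchor: float = 0.0,
                  max_fraction: float = 0.85) -> FitResult:
    """Least-squares fit of a single power-law phase on the fraction scale.

    Points inside ``window`` (and, when ``window`` covers the whole profile,
    with observed mean fraction <= ``max_fraction``) enter an unweighted SSE.
    For fixed ``n`` the optimal K is linear-algebraic; otherwise a 1-D search
    over n (with the analytic K nested inside) is run from several starts.
    """
    t, y = _profile_arrays(profile)
    mask = np.isfinite(y) & (t > anchor) & (y <= max_fraction)
    if window is not None:
        mask &= (t >= window[0]) & (t <= window[1])
    t, y = t[mask], y[mask]
    if t.size < (1 if fixed_n is not None else 3):
        raise ValueError("need at least 3 points in the fitting window "
                         "(1 when n is fixed)")

    warnings: list[str] = []
    if t.size > 1 and np.ptp(y) == 0.0:
        warnings.append("degenerate window: all fractions equal; K set to 0")
        ph = PowerLawPhase(K=0.0, n=fixed_n if fixed_n else 1.0, t_start=float(t[0]),
                           t_end=float(t[-1]), anchor=anchor)
        return FitResult(model=ph, sse=float(np.sum((y - y.mean()) ** 2)),
                         windows=((float(t[0]), float(t[-1])),),
                         warnings=warnings)

    x = t - anchor

    def sse_for_n(n):
        xp = x ** n
        K = _best_K_fixed_n(xp, y)
        return float(np.sum((K * xp - y) ** 2)), K

    if fixed_n is not None:
        sse, K = sse_for_n(fixed_n)
        n_hat = fixed_n
        converged, msg = True, "fixed-n linear solution"
    else:
        best = None
        for n0 in (0.3, 0.6, 1.2):
            res = optimize.minimize_scalar(
                lambda n: sse_for_n(n)[0],
                bounds=(1e-3, 3.0), method="bounded",
                options={"xatol": 1e-12})
            # bounded scalar search is global enough here; keep the best of
            # a few restarts on perturbed brackets for safety
            if best is None or res.fun < best.fun:
                best = res
            res = optimize.minimize_scalar(
                lambda n: sse_for_n(n)[0],
                bounds=(max(1e-3, n0 / 3), min(3.0, n0 * 3)), method="bounded",
                options={"xatol": 1e-12})
            if res.fun < best.fun:
                best = res
        n_hat = float(best.x)
        sse, K = sse_for_n(n_hat)
        converged, msg = bool(best.success), str(best.message)

    wstart = float(t[0]) if window is None else float(window[0])
    wend = float(t[-1]) if window is None else float(window[1])
    ph = PowerLawPhase(K=K, n=n_hat, t_start=max(wstart, anchor), t_end=wend,
                       anchor=anchor)
    return FitResult(model=ph, sse=sse, windows=((wstart, wend),),
                     converged=converged, message=msg, warnings=warnings)


def _composite_from_params(Ks, ns, windows, anchors, cap=1.0):
    phases = [PowerLawPhase(K=max(K, 0.0), n=n, t_start=w[0] if w[0] > a else a,
                            t_end=w[1], anchor=a)
              for K, n, w, a in zip(Ks, ns, windows, anchors)]
    # PowerLawPhase requires t_start < t_end and anchor <= t_start; windows
    # here always satisfy this by construction
    return CompositeReleaseModel(phases=tuple(phases), cap=cap)


def _phase_layout(times, breakpoints):
    """Windows/anchors for 2- or 3-phase composites from breakpoints.

    ``breakpoints = [burst_end]`` gives a biphasic layout; a second entry adds
    the accelerated third phase anchored at that breakpoint.  The burst and
    the second phase are both anchored at 0; the second phase grows up to the
    second breakpoint (or the last observed time).
    """
    t_last = float(np.max(times))
    b1 = float(breakpoints[0])
    if len(breakpoints) > 1 and breakpoints[1] is not None and breakpoints[1] < t_last:
        b2 = float(breakpoints[1])
        windows = [(0.0, b1), (0.0, b2), (b2, t_last)]
        anchors = [0.0, 0.0, b2]
    else:
        windows = [(0.0, b1), (0.0, t_last)]
        anchors = [0.0, 0.0]
    return windows, anchors


def _select_fit_points(t, y, windows, max_fraction):
    """Windowing rule for composite fits: burst points up to the burst end;
    later points up to the plateau onset (first point with F >= 0.95,
    included) or the last point if no plateau.  Points at effectively
    complete release (F >= 0.999, where the cap makes the additive model
    uninformative) are dropped.  For biphasic profiles only points with
    F <= ``max_fraction`` enter the late-phase fit."""
    b1 = windows[0][1]
    triphasic = len(windows) == 3
    mask = np.isfinite(y)
    if not triphasic:
        mask &= (t <= b1) | (y <= max_fraction)
    plateau = y >= 0.95
    if plateau.any():
        first = np.argmax(plateau)
        keep = np.zeros_like(mask)
        keep[: first + 1] = True
        mask &= keep
    mask &= y < 0.999
    return mask


def fit_composite(profile, breakpoints: Sequence[float],
                  ties: Optional[dict] = None,
                  fixed_n: Optional[Sequence[Optional[float]]] = None,
                  cap: float = 1.0,
                  max_fraction: float = 0.85) -> FitResult | list[FitResult]:
    """Fit a piecewise power-law composite by joint least squares.

    Parameters
    ----------
    profile : ReleaseProfile-like, (times, fractions), or a list of those
        When a list is given together with ``ties={'n': True}`` the release
        exponents are shared across profiles (one n per phase, jointly fit).
    breakpoints : sequence of h
        ``[burst_end]`` or ``[burst_end, third_phase_start]``.
    fixed_n : optional sequence
        Per-phase fixed exponents (None entries stay free).

    The exponents are optimised by nonlinear least squares with the phase
    rate constants profiled out by non-negative linear least squares at each
    step, which makes noise-free recovery exact.
    """
    # a plain list means "several profiles, fit jointly"; anything else
    # (ReleaseProfile-like object or a (times, fractions) tuple) is single
    single = not isinstance(profile, list)
    profiles = [profile] if single else list(profile)
    tie_n = bool(ties and ties.get("n"))

    data = []
    for p in profiles:
        t, y = _profile_arrays(p)
        windows, anchors = _phase_layout(t, breakpoints)
        mask = _select_fit_points(t, y, windows, max_fraction)
        data.append((t[mask], y[mask], windows, anchors))

    n_phases = len(data[0][2])
    if fixed_n is None:
        fixed_n = [None] * n_phases
    free_idx = [i for i in range(n_phases) if fixed_n[i] is None]

    def design(t, windows, anchors, ns):
        cols = []
        for (w, a, n) in zip(windows, anchors, ns):
            tt = np.minimum(t, w[1])
            cols.append(np.where(tt > a, np.maximum(tt - a, 0.0) ** n, 0.0))
        return np.column_stack(cols)

    def solve_Ks(ns_per_profile):
        """Profile out K >= 0 per profile; return total SSE and the Ks."""
        sse = 0.0
        Ks = []
        for (t, y, windows, anchors), ns in zip(data, ns_per_profile):
            X = design(t, windows, anchors, ns)
            K, rnorm = optimize.nnls(X, y)
            Ks.append(K)
            sse += rnorm ** 2
        return sse, Ks

    def unpack(theta):
        if tie_n:
            ns = [fixed_n[i] if fixed_n[i] is not None else None for i in range(n_phases)]
            it = iter(theta)
            ns = [ns[i] if ns[i] is not None else next(it) for i in range(n_phases)]
            return [ns] * len(data)
        out = []
        k = 0
        for _ in data:
            ns = []
            for i in range(n_phases):
                if fixed_n[i] is not None:
                    ns.append(fixed_n[i])
                else:
                    ns.append(theta[k])
                    k += 1
            out.append(ns)
        return out

    n_free = len(free_idx) * (1 if tie_n else len(data))
    if n_free == 0:
        sse, Ks = solve_Ks(unpack(np.empty(0)))
        theta_hat = np.empty(0)
        converged, msg = True, "all exponents fixed"
    else:
        def objective(theta):
            # keep exponents in a physical range even for unbounded searches
            return solve_Ks(unpack(np.clip(theta, 1e-3, 3.0)))[0]

        starts = []
        for base in (0.45, 0.8):
            s = []
            for i in free_idx:
                s.append(1.2 if i == 2 else base)
            starts.append(np.tile(s, 1 if tie_n else len(data)))
        # a third start from per-phase log-log slopes of the first profile
        starts.append(np.full(n_free, 0.6))

        best = None
        for x0 in starts:
            res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-20,
                                             "maxiter": 4000, "maxfev": 6000})
            if best is None or res.fun < best.fun:
                best = res
        # polish with a bounded local search
        res = optimize.minimize(objective, best.x, method="Powell",
                                bounds=[(1e-3, 3.0)] * n_free,
                                options={"xtol": 1e-12, "ftol": 1e-15})
        if res.fun <= best.fun:
            best = res
        theta_hat = np.clip(np.atleast_1d(best.x), 1e-3, 3.0)
        sse, Ks = solve_Ks(unpack(theta_hat))
        converged, msg = bool(best.success), str(best.message)

    ns_all = unpack(theta_hat)
    results = []
    for (t, y, windows, anchors), K, ns in zip(data, Ks, ns_all):
        model = _composite_from_params(K, ns, windows, anchors, cap=cap)
        fit = FitResult(model=model,
                        sse=float(np.sum((model.evaluate(t) - y) ** 2)),
                        windows=tuple(windows), converged=converged, message=msg)
        fit.pearson_r = goodness_of_fit_pearson(fit, (t, y))
        results.append(fit)
    return results[0] if single else results


def goodness_of_fit_pearson(fit: FitResult | CompositeReleaseModel | PowerLawPhase,
                            profile) -> float:
    """Pearson r between fitted and observed fractions.

    The range is truncated at the first time point where the *fitted* value
    exceeds 0.95 (plateau onset); if no plateau, the full profile is used.
    Returns NaN (flagged) when fewer than two points remain or the fitted
    values are constant.
    """
    model = fit.model if isinstance(fit, FitResult) else fit
    t, y = _profile_arrays(profile)
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    yhat = (model.evaluate(t) if hasattr(model, "evaluate")
            else model.contribution(t))
    over = np.nonzero(yhat > 0.95)[0]
    if over.size:
        end = over[0] + 1  # include the first point past the plateau onset
        t, y, yhat = t[:end], y[:end], yhat[:end]
    if t.size < 2 or np.ptp(yhat) == 0.0 or np.ptp(y) == 0.0:
        return math.nan
    return float(stats.pearsonr(yhat, y)[0])


# ---------------------------------------------------------------------------
# interpretation
# ---------------------------------------------------------------------------

def classify_mechanism(n: float, atol: float = 1e-9) -> str:
    """Release mechanism implied by the power-law exponent.

    n <= 0.5 : (pseudo-)Fickian diffusion; 0.5 < n < 1 : anomalous transport;
    n = 1 : case II (relaxation-controlled); n > 1 : super-case II (erosion/
    swelling/dissolution-driven).
    """
    if n <= 0:
        raise ValueError("exponent must be positive")
    if n <= 0.5:
        return "pseudo-Fickian"
    if abs(n - 1.0) <= atol:
        return "case II"
    if n < 1.0:
        return "anomalous"
    return "super-case II"


def regress_K_on_solubility(K_values: Sequence[float],
                            solubilities: Sequence[float]):
    """OLS line of release rate constant against drug solubility (mg/mL).

    Returns ``(slope, intercept, r_squared)``.  Raises on a singular design
    (fewer than 2 points or constant solubility).
    """
    K = np.asarray(K_values, float)
    s = np.asarray(solubilities, float)
    if K.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(s) == 0.0:
        raise ValueError("singular design: solubilities are constant")
    res = stats.linregress(s, K)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
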