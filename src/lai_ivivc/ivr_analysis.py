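"""In vitro release (IVR) analysis with withdrawal/replacement correction.

A depot is injected into a fixed volume of medium; at each sampling time an
aliquot is withdrawn for assay and replaced with fresh buffer.  The measured
medium concentration therefore understates cumulative release: the mass
removed in earlier withdrawals must be added back,

    mass(t_i) = C_i * V_medium + sum_{j<i} C_j * V_withdrawal,

and the fraction dissolved is mass / dose-in-vessel.  The module also provides
the standard profile summaries: time to a target fraction by linear
interpolation, the regulatory f1 difference / f2 similarity factors on mean
percent-dissolved profiles, and Welch's unequal-variance t-test used for
group comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReleaseProfile",
    "SimilarityResult",
    "TimeToFraction",
    "cumulative_release",
    "time_to_fraction",
    "f1_difference",
    "f2_similarity",
    "welch_t_test",
    "ivr_summary",
]


@dataclass
class ReleaseProfile:
    """Fraction-dissolved profiles for one formulation (one row per vessel).

    Attributes
    ----------
    times : (n_times,) array, hours (strictly increasing)
    fractions : (n_vessels, n_times) array of F_diss in [0, ~1]
    dose_mg : drug dose per vessel, mg
    vessel_ids : labels for the rows of ``fractions``
    """

    times: np.ndarray
    fractions: np.ndarray
    dose_mg: float = math.nan
    vessel_ids: tuple = ()
    warnings: list[str] = field(default_factory=list)

    OVERSHOOT_TOL = 1.05  # assay noise may push F slightly past 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.fractions = np.atleast_2d(np.asarray(self.fractions, float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.fractions.shape[1] != self.times.size:
            raise ValueError("fractions must have one column per time point")
        if np.nanmax(self.fractions, initial=0.0) > self.OVERSHOOT_TOL:
            self.warnings.append(
                f"F_diss exceeds {self.OVERSHOOT_TOL}: "
                f"max {np.nanmax(self.fractions):.3f}")
        if not self.vessel_ids:
            self.vessel_ids = tuple(range(1, self.fractions.shape[0] + 1))

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.fractions, axis=0)

    @property
    def sd(self) -> np.ndarray:
        return np.nanstd(self.fractions, axis=0, ddof=1)

    @property
    def n_vessels(self) -> int:
        return self.fractions.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: vessel_id, time_h, f_diss."""
        rows = []
        for vid, row in zip(self.vessel_ids, self.fractions):
            for t, f in zip(self.times, row):
                rows.append((vid, t, f))
        return pd.DataFrame(rows, columns=["vessel_id", "time_h", "f_diss"])


@dataclass(frozen=True)
class SimilarityResult:
    """f1 difference and f2 similarity factors for two mean profiles."""

    f1: float
    f2: float
    n_points: int


@dataclass
class TimeToFraction:
    """Per-vessel interpolated times to a target fraction with mean/SD.

    ``censored`` marks vessels that never reached the target; their entries
    in ``per_vessel`` are NaN and they are excluded from mean/SD.
    """

    q: float
    per_vessel: np.ndarray
    censored: np.ndarray
    t_last: float

    @property
    def mean(self) -> float:
        vals = self.per_vessel[~self.censored]
        return float(np.mean(vals)) if vals.size else math.nan

    @property
    def sd(self) -> float:
        vals = self.per_vessel[~self.censored]
        return float(np.std(vals, ddof=1)) if vals.size > 1 else math.nan

    @property
    def any_censored(self) -> bool:
        return bool(self.censored.any())

    def __str__(self) -> str:  # Table-style rendering, e.g. ">480"
        if self.censored.all():
            return f">{self.t_last:g}"
        return f"{self.mean:.3g} ({self.sd:.3g})"


def cumulative_release(raw: pd.DataFrame, design) -> ReleaseProfile:
    """Convert measured medium concentrations to cumulative fraction dissolved.

    Parameters
    ----------
    raw : DataFrame with columns ``vessel_id, time_h, conc_mg_per_ml``
    design : object with ``medium_volume`` (mL), ``withdrawal_volume`` (mL)
        and ``dose_mg`` (drug mass per vessel, mg) attributes.

    A vessel missing any time point present in the others is excluded from
    the profile (with a warning recorded on the result).
    """
    req = {"vessel_id", "time_h", "conc_mg_per_ml"}
    if not req.issubset(raw.columns):
        raise ValueError(f"raw table must have columns {sorted(req)}")
    V = float(design.medium_volume)
    Vs = float(design.withdrawal_volume)
    dose = float(design.dose_mg)

    times = np.unique(raw["time_h"].to_numpy(float))
    warnings: list[str] = []
    rows, ids = [], []
    for vid, grp in raw.groupby("vessel_id", sort=True):
        grp = grp.sort_values("time_h")
        t = grp["time_h"].to_numpy(float)
        if t.size != times.size or not np.array_equal(t, times):
            warnings.append(f"vessel {vid!r} missing time points; excluded")
            continue
        c = grp["conc_mg_per_ml"].to_numpy(float)
        if np.any(c < 0):
            raise ValueError(f"vessel {vid!r}: negative concentrations")
        removed = np.concatenate([[0.0], np.cumsum(c[:-1] * Vs)])
        mass = c * V + removed
        rows.append(mass / dose)
        ids.append(vid)
    if not rows:
        raise ValueError("no complete vessels in input")
    prof = ReleaseProfile(times=times, fractions=np.vstack(rows),
                          dose_mg=dose, vessel_ids=tuple(ids))
    prof.warnings.extend(warnings)
    return prof


def time_to_fraction(profile: ReleaseProfile, q: float) -> TimeToFraction:
    """Time for each vessel to reach fraction ``q``, by linear interpolation.

    The first bracketing pair of observed points is used.  Vessels whose
    profile never reaches ``q`` are censored (cf. a ">480 h" table entry).
    """
    if not 0 < q < ReleaseProfile.OVERSHOOT_TOL:
        raise ValueError("q must be in (0, 1]")
    out = np.full(profile.n_vessels, math.nan)
    cens = np.ones(profile.n_vessels, bool)
    for i, row in enumerate(profile.fractions):
        idx = np.nonzero(row >= q)[0]
        if idx.size == 0:
            continue
        k = idx[0]
        cens[i] = False
        if row[k] == q:
            out[i] = profile.times[k]
        elif k == 0:
            # nothing released before the first sample: interpolate from (0, 0)
            out[i] = profile.times[0] * q / row[0]
        else:
            t0, t1 = profile.times[k - 1], profile.times[k]
            f0, f1 = row[k - 1], row[k]
            out[i] = t0 + (q - f0) / (f1 - f0) * (t1 - t0)
    return TimeToFraction(q=q, per_vessel=out, censored=cens,
                          t_last=float(profile.times[-1]))


def _check_grids(reference, test):
    r = np.asarray(reference, float)
    t = np.asarray(test, float)
    if r.shape != t.shape or r.ndim != 1 or r.size < 1:
        raise ValueError("reference and test must be equal-length 1-D arrays "
                         "on the same time grid (no silent resampling)")
    return r, t


def f1_difference(reference, test) -> float:
    """f1 = sum|R_t - T_t| / sum R_t * 100 on mean percent-dissolved profiles."""
    r, t = _check_grids(reference, test)
    denom = float(np.sum(r))
    if denom == 0.0:
        raise ZeroDivisionError("f1 undefined: reference sums to zero")
    return float(np.sum(np.abs(r - t)) / denom * 100.0)


def f2_similarity(reference, test) -> float:
    """f2 = 50 * log10{ [1 + (1/n) sum (R_t-T_t)^2]^-0.5 * 100 }.

    100 for identical profiles; ~50 at a uniform 10-percentage-point gap.
    """
    r, t = _check_grids(reference, test)
    msd = float(np.mean((r - t) ** 2))
    return float(50.0 * math.log10((1.0 + msd) ** -0.5 * 100.0))


def similarity(reference, test) -> SimilarityResult:
    r, t = _check_grids(reference, test)
    return SimilarityResult(f1=f1_difference(r, t), f2=f2_similarity(r, t),
                            n_points=r.size)


def welch_t_test(group_a, group_b):
    """Two-tailed heteroscedastic (Welch) t-test.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom.
    Two identical zero-variance groups give p = 1 by convention.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.inf, float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def ivr_summary(profile: ReleaseProfile, at_time: float = 48.0) -> dict:
    """Release summary for one formulation: %IVR at ``at_time``, t50, t80."""
    i = np.searchsorted(profile.times, at_time)
    if i < profile.times.size and profile.times[i] == at_time:
        pct = profile.fractions[:, i] * 100.0
        pct_mean, pct_sd = float(np.mean(pct)), float(np.std(pct, ddof=1))
    else:  # interpolate each vessel
        pct = np.array([np.interp(at_time, profile.times, row) * 100.0
                        for row in profile.fractions])
        pct_mean, pct_sd = float(np.mean(pct)), float(np.std(pct, ddof=1))
    t50 = time_to_fraction(profile, 0.5)
    t80 = time_to_fraction(profile, 0.8)
    return {"pct_ivr": pct_mean, "pct_ivr_sd": pct_sd,
            "t50": t50, "t80": t80}
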