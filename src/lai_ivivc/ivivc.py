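"""Point-to-point in vitro - in vivo correlation for depot formulations.

The in vivo cumulative fraction absorbed is modelled by re-scaling each phase
of the in vitro piecewise power-law fit,

    F_abs,phase(t) = A_phase * K_phase * (t - anchor)^n_phase,

with phase-specific scaling factors A shared ("tied") across formulations and
phases where the data support it.  The scaled composite is convolved with the
biexponential unit impulse response to predict the plasma profile, and the
prediction is validated internally by percent prediction errors against the
observed non-compartmental parameters.

In vivo phase conventions (they differ from the in vitro ones, where the
second phase co-grows with the burst from t = 0): the burst is anchored at 0
and frozen at the burst end; the second phase is anchored at the *burst end*;
a late accelerated phase, when present in vivo, is anchored at its own start.
For the slow-eroding polymer grade, which shows no in vivo third phase, the
second-phase law is carried through the end of the study window.

Convolution is performed through the same staircase machinery used for
deconvolution: the modelled F_abs is tabulated on an input grid and the
staircase input is convolved with the UIR in closed form.  With a dense input
grid this converges to the continuous convolution; with the study's
absorption tabulation grid (first node at the first in vivo sampling time) it
reproduces the published workflow, where all absorption before the first
sample enters as a single step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .release_models import CompositeReleaseModel
from .pk_analysis import ConcProfile, UIR, NCAResult
from .deconvolution import DeconvResult

__all__ = [
    "PhaseScaling",
    "ScalingFit",
    "PredictionErrors",
    "segment_phases",
    "fit_scaling",
    "apply_scaling",
    "modeled_fabs",
    "convolve_release",
    "convolve_model",
    "prediction_errors",
    "levy_pairs",
    "default_output_grid",
    "dense_input_grid",
    "absorption_tabulation_grid",
]


# ---------------------------------------------------------------------------
# scaling structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseScaling:
    """In vivo translation of one in vitro phase.

    ``A`` multiplies the in vitro K; ``window``/``anchor`` override the phase
    growth window and time origin in vivo (None keeps the in vitro value).
    ``drop=True`` removes the phase from the in vivo model (e.g. no third
    phase in vivo).
    """

    A: float = 1.0
    window: Optional[tuple[float, float]] = None
    anchor: Optional[float] = None
    drop: bool = False


@dataclass
class ScalingFit:
    """Phase-specific in vivo scaling factors, with tie structure.

    ``per_formulation`` maps formulation -> list of PhaseScaling (one per in
    vitro phase).  ``ties`` lists the groups of (formulation, phase_index)
    that share one A.  ``pearson_r`` is the modelled-vs-deconvoluted F_abs
    correlation per formulation.
    """

    per_formulation: dict[str, list[PhaseScaling]]
    ties: list[list[tuple[str, int]]] = field(default_factory=list)
    pearson_r: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for form, phases in self.per_formulation.items():
            for ps in phases:
                if not ps.drop and ps.A <= 0:
                    raise ValueError(f"A must be > 0 ({form})")
        for group in self.ties:
            a_vals = {self.per_formulation[f][i].A for f, i in group
                      if not self.per_formulation[f][i].drop}
            if len(a_vals) > 1:
                raise ValueError(f"tied group {group} has unequal A values")


def apply_scaling(in_vitro: CompositeReleaseModel,
                  phases: Sequence[PhaseScaling]) -> CompositeReleaseModel:
    """Build the in vivo composite from an in vitro model and phase scalings."""
    if len(phases) != len(in_vitro.phases):
        raise ValueError("one PhaseScaling per in vitro phase required")
    factors = [None if p.drop else p.A for p in phases]
    windows = [p.window for p in phases]
    anchors = [p.anchor for p in phases]
    return in_vitro.scaled(factors, windows=windows, anchors=anchors)


def modeled_fabs(in_vitro: CompositeReleaseModel,
                 scaling: Sequence[PhaseScaling] | ScalingFit,
                 t, formulation: Optional[str] = None):
    """Modelled in vivo fraction absorbed at time(s) ``t`` (capped at 1)."""
    if isinstance(scaling, ScalingFit):
        if formulation is None:
            if len(scaling.per_formulation) != 1:
                raise ValueError("formulation required with a multi-entry ScalingFit")
            formulation = next(iter(scaling.per_formulation))
        scaling = scaling.per_formulation[formulation]
    return apply_scaling(in_vitro, scaling).evaluate(t)


# ---------------------------------------------------------------------------
# phase segmentation
# ---------------------------------------------------------------------------

def segment_phases(times, values, breakpoints: Optional[Sequence[float]] = None,
                   burst_end: float = 24.0) -> list[tuple[float, float]]:
    """Split a release/absorption profile into phase windows.

    The burst window is fixed at [0, burst_end].  The boundary between the
    slower and the accelerated phase is either supplied explicitly or chosen
    as the observed time (>= 4 points on each side) minimising the total SSE
    of independent power-law fits to the two segments.  If no candidate
    improves on a single-segment fit (or there are too few points), a
    biphasic layout is returned.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    t_last = float(t[-1])
    if breakpoints is not None:
        bps = [float(b) for b in breakpoints]
        wins = [(0.0, bps[0])]
        for a, b in zip(bps, bps[1:] + [t_last]):
            wins.append((a, b))
        return wins

    # plateaued points carry no information about the phase laws
    late = (t > burst_end) & np.isfinite(y) & (y < 0.95)
    tl, yl = t[late], y[late]

    def seg_sse(tt, yy, anchor):
        """SSE of c + K*(t-anchor)^n (intercept absorbs frozen earlier
        phases; K and c profiled out by linear least squares, n searched)."""
        x = tt - anchor

        def f(n):
            X = np.column_stack([x ** n, np.ones_like(x)])
            coef, res_, *_ = np.linalg.lstsq(X, yy, rcond=None)
            return float(np.sum((X @ coef - yy) ** 2))

        res = optimize.minimize_scalar(f, bounds=(1e-3, 3.0), method="bounded")
        return float(res.fun)

    if tl.size >= 8:
        single = seg_sse(tl, yl, 0.0)
        best = (single, None)
        for k in range(4, tl.size - 3):
            b = tl[k - 1]
            sse = seg_sse(tl[:k], yl[:k], 0.0) + seg_sse(tl[k:], yl[k:], b)
            if sse < best[0] - 1e-12:
                best = (sse, b)
        if best[1] is not None:
            b = float(best[1])
            return [(0.0, burst_end), (burst_end, b), (b, t_last)]
    return [(0.0, burst_end), (burst_end, t_last)]


# ---------------------------------------------------------------------------
# scaling-factor estimation
# ---------------------------------------------------------------------------

def _phase_regressors(in_vitro: CompositeReleaseModel,
                      phases: Sequence[PhaseScaling], t: np.ndarray) -> np.ndarray:
    """Unscaled phase contributions under the in vivo windows/anchors."""
    cols = []
    for ph, ps in zip(in_vitro.phases, phases):
        if ps.drop:
            cols.append(np.zeros_like(t))
            continue
        kw = {}
        if ps.window is not None:
            kw["t_start"], kw["t_end"] = ps.window
        if ps.anchor is not None:
            kw["anchor"] = ps.anchor
            if "t_start" in kw and kw["t_start"] < ps.anchor:
                kw["t_start"] = ps.anchor
        cols.append(replace(ph, **kw).contribution(t))
    return np.column_stack(cols)


def fit_scaling(in_vitro: CompositeReleaseModel | dict,
                fabs: DeconvResult | dict,
                ties: Optional[list[list[tuple[str, int]]]] = None,
                vivo_layout: Optional[dict] = None,
                max_fabs: float = 0.95) -> ScalingFit:
    """Estimate phase-specific scaling factors A against deconvoluted F_abs.

    Parameters
    ----------
    in_vitro : composite model, or {formulation: composite}
    fabs : DeconvResult, or {formulation: DeconvResult}
    ties : groups of (formulation, phase_index) constrained to share one A.
        Unlisted phases each get their own A.
    vivo_layout : {formulation: [PhaseScaling template, ...]} fixing in vivo
        windows / anchors / dropped phases (A values in the template are
        ignored).  Defaults to the in vitro layout.

    Because the modelled F_abs is linear in the A's (additive phases), the
    estimate is a non-negative linear least-squares solve on the pooled
    observations with F_abs <= ``max_fabs`` (points past the plateau carry no
    information about the phase laws).
    """
    if not isinstance(in_vitro, dict):
        in_vitro = {"_": in_vitro}
        fabs = {"_": fabs}
        if vivo_layout is not None and not isinstance(vivo_layout, dict):
            vivo_layout = {"_": vivo_layout}
        if ties is not None:
            ties = [[("_", i) for (_, i) in g] for g in ties]
    forms = list(in_vitro)

    layout = {}
    for f in forms:
        if vivo_layout and f in vivo_layout:
            layout[f] = list(vivo_layout[f])
        else:
            layout[f] = [PhaseScaling() for _ in in_vitro[f].phases]

    # group index for every active (formulation, phase)
    group_of: dict[tuple[str, int], int] = {}
    groups: list[list[tuple[str, int]]] = []
    if ties:
        for g in ties:
            gi = len(groups)
            groups.append([(f, i) for f, i in g])
            for f, i in g:
                group_of[(f, i)] = gi
    for f in forms:
        for i, ps in enumerate(layout[f]):
            if ps.drop or (f, i) in group_of:
                continue
            group_of[(f, i)] = len(groups)
            groups.append([(f, i)])

    rows_X, rows_y = [], []
    for f in forms:
        d = fabs[f]
        mask = (d.times > 0) & (d.fabs <= max_fabs)
        t = d.times[mask]
        y = d.fabs[mask]
        reg = _phase_regressors(in_vitro[f], layout[f], t)
        X = np.zeros((t.size, len(groups)))
        for i, ps in enumerate(layout[f]):
            if ps.drop:
                continue
            X[:, group_of[(f, i)]] += reg[:, i]
        rows_X.append(X)
        rows_y.append(y)
    Xall = np.vstack(rows_X)
    yall = np.concatenate(rows_y)
    empty = [gi for gi in range(len(groups)) if not np.any(Xall[:, gi])]
    if empty:
        raise ValueError("non-identifiable tie groups (no data in window): "
                         f"{[groups[gi] for gi in empty]}")
    A_groups, _ = optimize.nnls(Xall, yall)

    per_form = {}
    pearson = {}
    for f in forms:
        phases = []
        for i, ps in enumerate(layout[f]):
            if ps.drop:
                phases.append(ps)
            else:
                A = float(A_groups[group_of[(f, i)]])
                phases.append(replace(ps, A=max(A, 1e-12)))
        per_form[f] = phases
        model = apply_scaling(in_vitro[f], phases)
        d = fabs[f]
        keep = d.times > 0
        yhat = model.evaluate(d.times[keep])
        yobs = d.fabs[keep]
        over = np.nonzero(yhat > max_fabs)[0]
        if over.size:
            yhat, yobs = yhat[: over[0] + 1], yobs[: over[0] + 1]
        if yhat.size >= 2 and np.ptp(yhat) > 0 and np.ptp(yobs) > 0:
            pearson[f] = float(stats.pearsonr(yhat, yobs)[0])
        else:
            pearson[f] = math.nan

    return ScalingFit(per_formulation=per_form,
                      ties=[g for g in groups if len(g) > 1],
                      pearson_r=pearson)


# ---------------------------------------------------------------------------
# convolution to predicted plasma profiles
# ---------------------------------------------------------------------------

def default_output_grid(t_end: float = 2016.0) -> np.ndarray:
    """Dense output grid: 0.1 h steps to 72 h, then 1 h steps to ``t_end``."""
    head = np.arange(0.0, min(72.0, t_end) + 1e-9, 0.1)
    if t_end <= 72.0:
        return head
    tail = np.arange(73.0, t_end + 1e-9, 1.0)
    return np.unique(np.concatenate([head, tail, [t_end]]))


def absorption_tabulation_grid(first_sample_h: float = 4.0,
                               t_end: float = 2016.0,
                               step_h: float = 1.0) -> np.ndarray:
    """Input grid reproducing the deconvolution-based workflow.

    F_abs is only observed from the first in vivo sampling time onward, so
    the tabulated modelled F_abs starts there and all absorption before the
    first sample enters the convolution as a single staircase step.  After
    the first sample the tabulation is fine (``step_h``), approaching the
    continuous convolution.
    """
    tail = np.arange(first_sample_h, t_end + 1e-9, step_h)
    return np.unique(np.concatenate([[0.0], tail, [t_end]]))


def dense_input_grid(model: CompositeReleaseModel,
                     t_end: float = 2016.0) -> np.ndarray:
    """Input grid refined geometrically after each phase anchor.

    The release rate has an integrable (t - anchor)^(n-1) singularity at each
    phase start; geometric refinement there makes the staircase input
    converge to the continuous convolution.
    """
    parts = [np.array([0.0]), default_output_grid(t_end)]
    for ph in model.phases:
        if ph.anchor < t_end:
            parts.append(ph.anchor + np.geomspace(1e-6, 1.0, 40))
    g = np.unique(np.concatenate(parts))
    return g[g <= t_end]


def convolve_release(model: CompositeReleaseModel, uir: UIR, dose_ug: float,
                     input_grid: Optional[np.ndarray] = None,
                     output_grid: Optional[np.ndarray] = None,
                     t_end: float = 2016.0,
                     mass_tol: float = 5e-3) -> ConcProfile:
    """Predicted plasma profile for a release model given the UIR and dose.

    The model's F_abs is tabulated on ``input_grid`` (default: a dense graded
    grid approximating the continuous convolution) and the resulting staircase
    input is convolved with the UIR exactly (closed-form interval integrals,
    O(N) recursion).  ``output_grid`` defaults to 0.1 h steps to 72 h then
    1 h steps.  A mass-balance check compares the staircase input against the
    model's F_abs on the output grid and raises if the grid is too coarse.
    """
    if output_grid is None:
        output_grid = default_output_grid(t_end)
    output_grid = np.asarray(output_grid, float)
    if input_grid is None:
        input_grid = dense_input_grid(model, t_end=float(output_grid[-1]))
    input_grid = np.asarray(input_grid, float)
    if input_grid[0] != 0.0:
        input_grid = np.concatenate([[0.0], input_grid])

    grid = np.unique(np.concatenate([input_grid, output_grid]))
    F_in = model.evaluate(input_grid)
    # staircase rate on each input interval, broadcast onto the union grid
    rates_in = np.diff(F_in) / np.diff(input_grid)
    interval_idx = np.searchsorted(input_grid, grid[1:], side="left") - 1
    interval_idx = np.clip(interval_idx, 0, rates_in.size - 1)
    r = rates_in[interval_idx]

    dt = np.diff(grid)
    C = np.zeros_like(grid)
    for coef, lam in ((uir.A, uir.alpha), (uir.B, uir.beta)):
        decay = np.exp(-lam * dt)
        gain = coef * (1.0 - decay) / lam
        x = 0.0
        comp = np.zeros_like(grid)
        for k in range(dt.size):
            x = x * decay[k] + r[k] * gain[k]
            comp[k + 1] = x
        C += comp

    C *= dose_ug

    # mass balance: the staircase cumulative input must track the model's
    # F_abs.  The check starts at the second input node: everything before the
    # first tabulation point deliberately enters as one step (see
    # ``absorption_tabulation_grid``), which is a workflow choice, not a
    # discretisation error.
    F_grid = np.concatenate([[F_in[0]], F_in[0] + np.cumsum(r * dt)])
    chk = grid >= input_grid[1]
    err = float(np.max(np.abs(F_grid[chk] - model.evaluate(grid[chk]))))
    if err > mass_tol:
        raise ValueError(f"input grid too coarse: staircase F_abs deviates "
                         f"from the model by {err:.3g} (> {mass_tol})")

    sel = np.searchsorted(grid, output_grid)
    return ConcProfile(subject_id="model", times=output_grid, conc=C[sel],
                       route="SC")


def convolve_model(in_vitro: CompositeReleaseModel,
                   scaling: Sequence[PhaseScaling] | ScalingFit,
                   uir: UIR, dose_ug: float,
                   formulation: Optional[str] = None,
                   **kwargs) -> ConcProfile:
    """Scale the in vitro model to in vivo release and convolve with the UIR."""
    if isinstance(scaling, ScalingFit):
        if formulation is None:
            if len(scaling.per_formulation) != 1:
                raise ValueError("formulation required with a multi-entry ScalingFit")
            formulation = next(iter(scaling.per_formulation))
        scaling = scaling.per_formulation[formulation]
    model = apply_scaling(in_vitro, scaling)
    return convolve_release(model, uir, dose_ug, **kwargs)


# ---------------------------------------------------------------------------
# prediction errors and Levy pairing
# ---------------------------------------------------------------------------

@dataclass
class PredictionErrors:
    """%PE table: (observed - modeled)/observed * 100, per cell and averaged."""

    table: pd.DataFrame           # index: formulation; columns: parameter
    mean_absolute: pd.Series      # per parameter

    def __str__(self) -> str:
        return self.table.to_string()


def prediction_errors(observed: dict[str, dict[str, float]] | dict[str, NCAResult],
                      modeled: dict[str, dict[str, float]] | dict[str, NCAResult]
                      ) -> PredictionErrors:
    """Internal prediction errors for matching formulations and parameters."""

    def as_map(d):
        return {f: (v.as_dict() if isinstance(v, NCAResult) else dict(v))
                for f, v in d.items()}

    obs = as_map(observed)
    mod = as_map(modeled)
    forms = [f for f in obs if f in mod]
    if not forms:
        raise ValueError("no matching formulations")
    params = [p for p in obs[forms[0]] if p in mod[forms[0]]]

    rows = {}
    for f in forms:
        row = {}
        for p in params:
            o, m = obs[f].get(p), mod[f].get(p)
            if o is None or m is None or not np.isfinite(o) or not np.isfinite(m):
                row[p] = math.nan
                continue
            if o == 0:
                raise ZeroDivisionError(f"%PE undefined: observed {p} is 0 ({f})")
            row[p] = (o - m) / o * 100.0
        rows[f] = row
    table = pd.DataFrame(rows).T[params]
    return PredictionErrors(table=table, mean_absolute=table.abs().mean(axis=0))


def levy_pairs(fabs: DeconvResult, fdiss) -> pd.DataFrame:
    """Pair in vivo F_abs with in vitro F_diss at matched times.

    The denser series is interpolated onto the sparser one over the
    overlapping time range (a Levy-type plot substrate).
    """
    ta = fabs.times
    ya = fabs.fabs
    td = np.asarray(fdiss.times, float)
    yd = np.asarray(fdiss.mean, float)
    lo, hi = max(ta.min(), td.min()), min(ta.max(), td.max())
    if lo >= hi:
        raise ValueError("no overlapping time range")
    if ta.size >= td.size:  # interpolate the denser (absorption) onto dissolution
        base_t = td[(td >= lo) & (td <= hi)]
        f_d = yd[(td >= lo) & (td <= hi)]
        f_a = np.interp(base_t, ta, ya)
    else:
        base_t = ta[(ta >= lo) & (ta <= hi)]
        f_a = ya[(ta >= lo) & (ta <= hi)]
        f_d = np.interp(base_t, td, yd)
    return pd.DataFrame({"time_h": base_t, "F_diss": f_d, "F_abs": f_a})
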