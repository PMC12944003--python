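"""Synthetic study generation and transcribed study parameter fixtures.

Two things live here:

1. Simulators that reproduce the statistical structure the analysis assumes:
   quadruplicate dissolution vessels with withdrawal/replacement bookkeeping
   and multiplicative assay noise, and small rat PK groups with biexponential
   disposition and multiplicative residual error.  Identical ``RandomSpec``
   inputs give bit-identical outputs.

2. ``study_fixtures()`` — the published parameter sets for the five model
   drugs (paracetamol, theophylline, felbinac, indomethacin, celecoxib) in
   four PLGA in situ gel formulations: piecewise Korsmeyer-Peppas fits, the
   celecoxib in vivo scaling factors and phase windows, the biexponential UIR
   macro-constants from the IV arm, the observed PK summary used for internal
   prediction errors, and the reconstructed sampling schedules.  These are
   data, not estimates made here; they are the inputs to the reproduction
   pipeline and tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .release_models import CompositeReleaseModel, PowerLawPhase
from .pk_analysis import ConcProfile, UIR, eval_uir
from .ivivc import PhaseScaling, ScalingFit, apply_scaling, convolve_release

__all__ = [
    "IVRDesign",
    "PKDesign",
    "RandomSpec",
    "simulate_ivr_study",
    "simulate_iv_pk",
    "simulate_sc_pk",
    "study_fixtures",
    "StudyFixtures",
]


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IVRDesign:
    """Dissolution vessel design with withdrawal/replacement sampling.

    Defaults mirror the study setup: 50 mL phosphate buffer, 4 mL withdrawn
    and replaced at each sampling time, 0.3 g of formulation injected at a
    drug load of 10 mg/g (3 mg dose per vessel), quadruplicate vessels.  The
    assay error magnitude is not reported; a 5% CV is the configurable
    default.
    """

    schedule: tuple[float, ...]
    medium_volume: float = 50.0      # mL
    withdrawal_volume: float = 4.0   # mL
    injected_mass: float = 0.3       # g of formulation
    drug_load: float = 10.0          # mg drug / g formulation
    n_vessels: int = 4
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        sched = tuple(float(t) for t in self.schedule)
        object.__setattr__(self, "schedule", sched)
        if not sched or sched[0] <= 0 or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing and > 0")
        if not 0 < self.withdrawal_volume < self.medium_volume:
            raise ValueError("need 0 < withdrawal_volume < medium_volume")
        if self.n_vessels < 1:
            raise ValueError("n_vessels must be >= 1")
        if self.dose_mg <= 0:
            raise ValueError("dose per vessel must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @property
    def dose_mg(self) -> float:
        """Drug dose per vessel, mg."""
        return self.injected_mass * self.drug_load


@dataclass(frozen=True)
class PKDesign:
    """Rat PK group design.

    Body weights are drawn uniformly on ``body_weight_range`` (the at-dosing
    range of the study animals); the residual error CV on plasma
    concentration defaults to 10%.
    """

    schedule: tuple[float, ...]
    route: str = "SC"
    n_subjects: int = 4
    dose: float = 10.0                       # mg/kg
    body_weight_range: tuple[float, float] = (248.0, 294.0)  # g
    residual_cv: float = 0.10

    def __post_init__(self) -> None:
        sched = tuple(float(t) for t in self.schedule)
        object.__setattr__(self, "schedule", sched)
        if not sched or sched[0] <= 0 or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing and > 0")
        if self.route not in ("IV", "SC"):
            raise ValueError("route must be 'IV' or 'SC'")
        lo, hi = self.body_weight_range
        if not 0 < lo <= hi:
            raise ValueError("body weights must be positive, min <= max")
        if self.residual_cv < 0:
            raise ValueError("residual_cv must be >= 0")


@dataclass(frozen=True)
class RandomSpec:
    """Seeded noise specification; same seed + design => identical output."""

    seed: int = 0
    error_model: str = "multiplicative-lognormal"

    def __post_init__(self) -> None:
        if self.error_model not in ("multiplicative-lognormal",
                                    "additive-gaussian"):
            raise ValueError("unknown error model")

    def generator(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _perturb(values: np.ndarray, cv: float, rng: np.random.Generator,
             model: str, scale_ref: Optional[float] = None):
    """Apply the noise model; returns (noisy values, n_clamped)."""
    if cv == 0:
        return values.copy(), 0
    if model == "multiplicative-lognormal":
        sigma = math.sqrt(math.log1p(cv ** 2))
        fac = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                            size=values.shape)
        return values * fac, 0
    sd = cv * (scale_ref if scale_ref is not None else np.mean(values))
    noisy = values + rng.normal(0.0, sd, size=values.shape)
    clamped = int(np.sum(noisy < 0))
    return np.maximum(noisy, 0.0), clamped


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_ivr_study(truth: CompositeReleaseModel, design: IVRDesign,
                       rng: RandomSpec) -> pd.DataFrame:
    """Simulate measured vessel concentrations under withdrawal/replacement.

    For each vessel the true released mass at t_i is ``truth(t_i) * dose``;
    the medium concentration an analyst measures is

        C(t_i) = [released(t_i) - mass removed in earlier withdrawals] / V.

    Earlier withdrawals remove *true* concentration times the withdrawal
    volume (the vessel contents do not know about assay noise); noise is then
    applied to the measured concentration only.  Returns a long table
    ``vessel_id, time_h, conc_mg_per_ml``.
    """
    times = np.asarray(design.schedule, float)
    F = np.asarray(truth.evaluate(times), float)
    if np.any(~np.isfinite(F)):
        raise ValueError("truth not evaluable on the schedule")
    dose = design.dose_mg
    V, Vs = design.medium_volume, design.withdrawal_volume

    true_conc = np.empty_like(times)
    removed = 0.0
    for i, t in enumerate(times):
        c = (F[i] * dose - removed) / V
        true_conc[i] = c
        removed += c * Vs

    gen = rng.generator()
    rows = []
    n_clamped = 0
    for v in range(1, design.n_vessels + 1):
        meas, nc = _perturb(true_conc, design.noise_cv, gen, rng.error_model,
                            scale_ref=float(np.mean(true_conc)))
        n_clamped += nc
        for t, c in zip(times, meas):
            rows.append((f"V{v}", t, c))
    df = pd.DataFrame(rows, columns=["vessel_id", "time_h", "conc_mg_per_ml"])
    df.attrs["n_clamped"] = n_clamped
    return df


def _draw_weights(design: PKDesign, gen: np.random.Generator) -> np.ndarray:
    lo, hi = design.body_weight_range
    return gen.uniform(lo, hi, size=design.n_subjects)


def simulate_iv_pk(uir_truth: UIR, design: PKDesign,
                   rng: RandomSpec) -> list[ConcProfile]:
    """Simulate an IV-bolus group: C(t) = dose_ug * UIR(t) * noise."""
    if design.route != "IV":
        raise ValueError("design route must be IV")
    gen = rng.generator()
    weights = _draw_weights(design, gen)
    times = np.asarray(design.schedule, float)
    out = []
    for i, bw in enumerate(weights, start=1):
        dose_ug = design.dose * bw
        c = eval_uir(uir_truth, times, dose_ug)
        c, _ = _perturb(np.asarray(c, float), design.residual_cv, gen,
                        rng.error_model, scale_ref=float(np.mean(c)))
        out.append(ConcProfile(subject_id=f"R{i}", times=times.copy(), conc=c,
                               route="IV", dose=design.dose, body_weight=float(bw)))
    return out


def simulate_sc_pk(release_truth: CompositeReleaseModel,
                   scaling_truth: Sequence[PhaseScaling] | ScalingFit,
                   uir: UIR, design: PKDesign, rng: RandomSpec,
                   input_grid: Optional[np.ndarray] = None) -> list[ConcProfile]:
    """Simulate an SC depot group from a known in vivo release truth.

    The in vitro truth is scaled to in vivo release, convolved with the UIR
    per subject dose, sampled at the design schedule and perturbed with the
    residual error model.

    By default the absorption input is the truth's F_abs tabulated at the
    observation schedule (staircase), mirroring the deconvolution-based
    workflow: staircase deconvolution of noise-free output then recovers the
    truth's F_abs at the sample times exactly.  Pass a dense ``input_grid``
    to simulate a continuous-time absorption truth instead (deconvolution on
    a sparse schedule then carries genuine discretisation error, because the
    disposition washes out within one sampling interval).
    """
    if design.route != "SC":
        raise ValueError("design route must be SC")
    if isinstance(scaling_truth, ScalingFit):
        if len(scaling_truth.per_formulation) != 1:
            raise ValueError("pass the PhaseScaling list for one formulation")
        scaling_truth = next(iter(scaling_truth.per_formulation.values()))
    model = apply_scaling(release_truth, scaling_truth)
    times = np.asarray(design.schedule, float)
    dF = np.diff(model.evaluate(np.concatenate([[0.0], times])))
    if np.any(dF < -1e-12):
        raise ValueError("modeled F_abs must be non-decreasing")

    gen = rng.generator()
    weights = _draw_weights(design, gen)
    if input_grid is None:
        input_grid = np.concatenate([[0.0], times])
    base = convolve_release(model, uir, 1.0, input_grid=input_grid,
                            output_grid=times, t_end=float(times[-1]))
    out = []
    for i, bw in enumerate(weights, start=1):
        dose_ug = design.dose * bw
        c = base.conc * dose_ug
        c, _ = _perturb(c, design.residual_cv, gen, rng.error_model,
                        scale_ref=float(np.mean(c)))
        out.append(ConcProfile(subject_id=f"R{i}", times=times.copy(), conc=c,
                               route="SC", dose=design.dose, body_weight=float(bw)))
    return out


# ---------------------------------------------------------------------------
# transcribed study fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseFit:
    """One published phase: in vitro power-law fit plus in vivo translation.

    ``A_scale`` / ``vivo_*`` are None when the phase has no in vivo
    counterpart (the formulation's absorption is carried by another phase).
    """

    K: float
    n: float
    t_start: float
    t_end: float
    anchor: float
    A_scale: Optional[float] = None
    vivo_start: Optional[float] = None
    vivo_end: Optional[float] = None
    vivo_anchor: Optional[float] = None


FORMULATIONS = ("F1", "F2", "F3", "F4")
FORMULATION_LABELS = {
    "F1": "30% PLGA50:50", "F2": "30% PLGA85:15",
    "F3": "40% PLGA50:50", "F4": "40% PLGA85:15",
}

# sampling schedules (hours).  The exact grids are not published; these are
# reconstructed once, consistent with the reported window boundaries, the
# observed tmax range (4-7 h), tlast values and the secondary-peak timing.
IVR_SCHEDULE_SHORT = (1, 2, 4, 8, 24, 48, 72, 96, 168, 240, 312, 360, 432, 480)
IVR_SCHEDULE_LONG = (1, 2, 4, 8, 24, 48, 72, 96, 168, 240, 312, 360, 408, 480,
                     576, 648, 816, 1008, 1176, 1344, 1512, 1656, 1824, 2016,
                     2184, 2352, 2568)
SC_PK_SCHEDULE = (4, 7, 24, 48, 72, 96, 168, 240, 336, 504, 672, 840, 1008,
                  1176, 1344, 1512, 1680, 1848, 2016)
# the IV arm reports a measured concentration at nominal time zero, so the
# schedule includes an immediate (5 min) post-dose sample
IV_PK_SCHEDULE = (0.083, 1, 2, 4, 7, 24, 48, 72)

# body weight used to convert mg/kg doses for the reproduction (mid of the
# reported 268-270 g group means)
REFERENCE_BODY_WEIGHT_G = 269.0
SC_DOSE_MG_PER_KG = 10.0
IV_DOSE_MG_PER_KG = 1.0


def _biphasic(K, n=0.406, t_end=480.0):
    return {"main": PhaseFit(K=K, n=n, t_start=0.0, t_end=t_end, anchor=0.0)}


def _triphasic(K, K3, t_end2, t3_start, t3_end, n=0.406, n3=1.22):
    return {
        "main": PhaseFit(K=K, n=n, t_start=0.0, t_end=t_end2, anchor=0.0),
        "phase3": PhaseFit(K=K3, n=n3, t_start=t3_start, t_end=t3_end,
                           anchor=t3_start),
    }


# Korsmeyer-Peppas fits for the five model drugs (combined burst+diffusion
# phase at the shared average exponent n = 0.406; erosion phase n = 1.22)
KP_FITS = {
    "paracetamol": {
        "F1": _biphasic(0.207), "F2": _biphasic(0.196),
        "F3": _biphasic(0.174), "F4": _biphasic(0.121),
    },
    "theophylline": {
        "F1": _biphasic(0.207), "F2": _biphasic(0.186),
        "F3": _biphasic(0.174), "F4": _biphasic(0.133),
    },
    "felbinac": {
        "F1": _biphasic(0.183), "F2": _biphasic(0.125),
        "F3": _biphasic(0.0977), "F4": _biphasic(0.0796),
    },
    "indomethacin": {
        "F1": _biphasic(0.146), "F2": _biphasic(0.0928),
        "F3": _triphasic(0.0649, 1.20e-3, 312.0, 312.0, 480.0),
        "F4": _biphasic(0.0529),
    },
    "celecoxib": {
        "F1": _triphasic(0.0652, 0.30e-3, 312.0, 312.0, 2568.0),
        "F2": _biphasic(0.0527, t_end=2568.0),
        "F3": _triphasic(0.0417, 0.45e-3, 312.0, 312.0, 2568.0),
        "F4": _triphasic(0.0342, 0.25e-3, 1656.0, 1656.0, 2568.0),
    },
}

KP_PEARSON = {
    "paracetamol": {"F1": 0.957, "F2": 0.963, "F3": 0.954, "F4": 0.964},
    "theophylline": {"F1": 0.957, "F2": 0.962, "F3": 0.982, "F4": 0.963},
    "felbinac": {"F1": 0.976, "F2": 0.992, "F3": 0.990, "F4": 0.990},
    "indomethacin": {"F1": 0.978, "F2": 0.996, "F3": 0.971, "F4": 0.992},
    "celecoxib": {"F1": 0.968, "F2": 0.988, "F3": 0.977, "F4": 0.991},
}

# drug solubility in the respective dissolution medium, mg/mL (celecoxib in
# 3% SLS-supplemented buffer)
SOLUBILITY_MG_PER_ML = {
    "paracetamol": 11.8, "theophylline": 18.4, "felbinac": 4.31,
    "indomethacin": 2.98, "celecoxib": 1.35,
}


def _cele(burst_K, p2_K, p2_n, p2_end, p2_A, p3_K=None, p3_window=None,
          burst_A=2.0, p3_in_vivo=True):
    """Celecoxib piecewise in vitro fit + in vivo scaling per formulation.

    In vivo conventions: burst on [0, 24] anchored at 0; second phase
    anchored at the burst end (24 h); the slow-eroding polymer grade shows no
    in vivo third phase (its in vitro third phase, when present, is dropped
    in vivo and the second-phase law carries through 2016 h), whereas the
    fast grade's third phase is anchored at its in vivo start with the
    second-phase scaling factor.
    """
    vivo_p3 = p3_K is not None and p3_in_vivo
    d = {
        "burst": PhaseFit(K=burst_K, n=0.471, t_start=0.0, t_end=24.0,
                          anchor=0.0, A_scale=burst_A, vivo_start=0.0,
                          vivo_end=24.0, vivo_anchor=0.0),
        "phase2": PhaseFit(K=p2_K, n=p2_n, t_start=0.0, t_end=p2_end,
                           anchor=0.0, A_scale=p2_A, vivo_anchor=24.0,
                           vivo_start=24.0,
                           vivo_end=312.0 if vivo_p3 else 2016.0),
    }
    if p3_K is not None:
        d["phase3"] = PhaseFit(
            K=p3_K, n=1.22, t_start=p3_window[0], t_end=p3_window[1],
            anchor=p3_window[0],
            A_scale=p2_A if vivo_p3 else None,
            vivo_start=312.0 if vivo_p3 else None,
            vivo_end=1656.0 if vivo_p3 else None,
            vivo_anchor=312.0 if vivo_p3 else None)
    return d


CELECOXIB_IVIVC = {
    "F1": _cele(0.0485, 0.0125, 0.616, 312.0, 0.72,
                p3_K=0.30e-3, p3_window=(312.0, 2568.0), burst_A=2.0),
    "F2": _cele(0.0485, 0.0190, 0.521, 2568.0, 0.45, burst_A=2.0),
    "F3": _cele(0.0308, 9.12e-3, 0.616, 312.0, 0.72,
                p3_K=0.45e-3, p3_window=(312.0, 2568.0), burst_A=1.7),
    "F4": _cele(0.0220, 0.0127, 0.521, 1656.0, 0.45, burst_A=1.7,
                p3_K=0.25e-3, p3_window=(1656.0, 2568.0), p3_in_vivo=False),
}

CELECOXIB_IVIVC_PEARSON = {
    "in_vitro": {"F1": 0.969, "F2": 0.988, "F3": 0.978, "F4": 0.991},
    "in_vivo": {"F1": 0.997, "F2": 0.999, "F3": 0.994, "F4": 0.999},
}

# biexponential UIR macro-constants from the two-compartment IV fit
# (per-microgram dose basis; alpha is the slow macro-rate)
UIR_CONSTANTS = UIR(A=1.78, B=0.563, alpha=0.201, beta=3.10)

# observed NCA summary, mean (SD) per SC formulation and the IV arm
OBSERVED_PK = {
    "F1": {"Cmax": 670.0, "AUC_48h": 13661.0, "AUC_168h": 16520.0,
           "AUC_672h": 25710.0, "AUC_last": 26045.0, "AUC_2016h": 26045.0},
    "F2": {"Cmax": 636.0, "AUC_48h": 12157.0, "AUC_168h": 14998.0,
           "AUC_672h": 18736.0, "AUC_last": 23909.0, "AUC_2016h": 23909.0},
    "F3": {"Cmax": 354.0, "AUC_48h": 7243.0, "AUC_168h": 9540.0,
           "AUC_672h": 24406.0, "AUC_last": 26254.0, "AUC_2016h": 26254.0},
    "F4": {"Cmax": 274.0, "AUC_48h": 5131.0, "AUC_168h": 6406.0,
           "AUC_672h": 8465.0, "AUC_last": 11640.0, "AUC_2016h": 11640.0},
    "IV": {"C0": 626.0, "AUC_48h": 2853.0, "AUC_168h": 2854.0,
           "AUC_672h": 2854.0, "AUC_last": 2836.0, "AUC_inf": 2854.0,
           "t_half": 3.34},
}

# observed IVR summary for the celecoxib formulations: %IVR at 48 h and
# interpolated t50/t80, mean (SD)
OBSERVED_IVR_CELECOXIB = {
    "F1": {"pct_ivr_48h": (29.5, 10.4), "t50": (161.0, 95.0), "t80": (456.0, 117.0)},
    "F2": {"pct_ivr_48h": (28.2, 5.2), "t50": (240.0, 69.0), "t80": (710.0, 120.0)},
    "F3": {"pct_ivr_48h": (19.8, 1.2), "t50": (370.0, 43.0), "t80": (539.0, 89.0)},
    "F4": {"pct_ivr_48h": (14.6, 1.1), "t50": (741.0, 136.0), "t80": (1787.0, 82.0)},
}

# published modeled PK parameters and internal prediction errors
MODELED_PK = {
    "F1": {"Cmax": 635.0, "AUC_48h": 11867.0, "AUC_168h": 15115.0,
           "AUC_672h": 24308.0, "AUC_2016h": 24318.0},
    "F2": {"Cmax": 640.0, "AUC_48h": 11569.0, "AUC_168h": 13359.0,
           "AUC_672h": 16705.0, "AUC_2016h": 21576.0},
    "F3": {"Cmax": 346.0, "AUC_48h": 6711.0, "AUC_168h": 9108.0,
           "AUC_672h": 21278.0, "AUC_2016h": 24641.0},
    "F4": {"Cmax": 245.0, "AUC_48h": 4698.0, "AUC_168h": 5882.0,
           "AUC_672h": 8102.0, "AUC_2016h": 11332.0},
}
MODELED_PE = {
    "F1": {"Cmax": 5, "AUC_48h": 13, "AUC_168h": 9, "AUC_672h": 5, "AUC_2016h": 7},
    "F2": {"Cmax": -1, "AUC_48h": 5, "AUC_168h": 11, "AUC_672h": 11, "AUC_2016h": 10},
    "F3": {"Cmax": 2, "AUC_48h": 7, "AUC_168h": 5, "AUC_672h": 13, "AUC_2016h": 6},
    "F4": {"Cmax": 11, "AUC_48h": 8, "AUC_168h": 8, "AUC_672h": 4, "AUC_2016h": 3},
}
MEAN_ABS_PE = {"Cmax": 5, "AUC_48h": 8, "AUC_168h": 8, "AUC_672h": 8,
               "AUC_2016h": 6}


class StudyFixtures(dict):
    """Dict-like fixture bundle with model-building helpers."""

    @staticmethod
    def _build(phases: dict) -> CompositeReleaseModel:
        plist = [PowerLawPhase(K=p.K, n=p.n, t_start=max(p.t_start, p.anchor),
                               t_end=p.t_end, anchor=p.anchor)
                 for p in phases.values()]
        return CompositeReleaseModel(phases=tuple(plist))

    def in_vitro_model(self, formulation: str) -> CompositeReleaseModel:
        """Three-phase celecoxib in vitro model (IVIVC parameterisation)."""
        return self._build(self["celecoxib"][formulation])

    def release_model(self, drug: str, formulation: str) -> CompositeReleaseModel:
        """Release-screening model (shared-exponent fits) for any model drug."""
        return self._build(self["kp_fits"][drug][formulation])

    def vivo_scaling(self, formulation: str) -> list[PhaseScaling]:
        """PhaseScaling list translating the celecoxib in vitro model in vivo."""
        out = []
        for p in self["celecoxib"][formulation].values():
            if p.A_scale is None:
                out.append(PhaseScaling(drop=True))
            else:
                out.append(PhaseScaling(
                    A=p.A_scale,
                    window=(max(p.vivo_start, p.vivo_anchor), p.vivo_end),
                    anchor=p.vivo_anchor))
        return out

    def in_vivo_model(self, formulation: str) -> CompositeReleaseModel:
        return apply_scaling(self.in_vitro_model(formulation),
                             self.vivo_scaling(formulation))

    def scaling_fit(self) -> ScalingFit:
        """The published tie structure over all four formulations."""
        per_form = {f: self.vivo_scaling(f) for f in FORMULATIONS}
        ties = [
            [("F1", 0), ("F2", 0)],                        # burst, 30% gels
            [("F3", 0), ("F4", 0)],                        # burst, 40% gels
            [("F1", 1), ("F3", 1), ("F1", 2), ("F3", 2)],  # fast grade, A=0.72
            [("F2", 1), ("F4", 1)],                        # slow grade, A=0.45
        ]
        return ScalingFit(per_formulation=per_form, ties=ties,
                          pearson_r=dict(self["celecoxib_pearson"]["in_vivo"]))

    def to_json(self, path=None) -> str:
        def enc(o):
            if isinstance(o, PhaseFit):
                return asdict(o)
            if isinstance(o, UIR):
                return asdict(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))
        s = json.dumps(self, default=enc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def study_fixtures() -> StudyFixtures:
    """Transcribed parameter sets of the source study (see module docstring)."""
    return StudyFixtures({
        "kp_fits": KP_FITS,
        "kp_pearson": KP_PEARSON,
        "celecoxib": CELECOXIB_IVIVC,
        "celecoxib_pearson": CELECOXIB_IVIVC_PEARSON,
        "uir": UIR_CONSTANTS,
        "solubility": SOLUBILITY_MG_PER_ML,
        "observed_pk": OBSERVED_PK,
        "observed_ivr_celecoxib": OBSERVED_IVR_CELECOXIB,
        "modeled_pk": MODELED_PK,
        "modeled_pe": MODELED_PE,
        "mean_abs_pe": MEAN_ABS_PE,
        "schedules": {
            "ivr_short": IVR_SCHEDULE_SHORT,
            "ivr_long": IVR_SCHEDULE_LONG,
            "sc_pk": SC_PK_SCHEDULE,
            "iv_pk": IV_PK_SCHEDULE,
        },
        "reference_body_weight_g": REFERENCE_BODY_WEIGHT_G,
        "sc_dose_mg_per_kg": SC_DOSE_MG_PER_KG,
        "iv_dose_mg_per_kg": IV_DOSE_MG_PER_KG,
    })
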