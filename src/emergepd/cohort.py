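"""Virtual VATS/TIVA cohort generator.

Emulates the study design the downstream analysis assumes: adult patients
under total intravenous anesthesia for video-assisted thoracoscopic surgery,
induced with a fentanyl bolus (3-5 µg/kg, converted to remifentanil
equivalents at the 1:1.2 potency ratio) and maintained on a propofol
effect-site target-controlled infusion; per-case concentration records on a
fine uniform grid; OAA/S scored every 20 s during emergence; regained
response (RR) defined as two consecutive scores >= 4 and observation
sustained 10 min past RR.

Ground truth for responsiveness is a Greco interaction surface: each OAA/S
observation is a Bernoulli draw of "responsive" with probability P(RR) at
the instantaneous concentration pair (or a deterministic 0.5-threshold in
the noise-free variant), mapped to the score dichotomy 4 vs 3.  Propofol
dosing uses the exact constant-target (bolus-elimination-transfer) infusion
profile for the linear mammillary model, so the plasma concentration holds
the target exactly — an idealized TCI pump.

The generator emulates the statistical structure the analysis consumes.  It
does not emulate surgical stimulus, BIS feedback titration, hemodynamics,
or inter-patient pharmacodynamic variability beyond the PK covariate models.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import labels as labels_mod
from .exceptions import InvalidParameterError
from .greco import PRESETS, GrecoResponseSurface
from .pk import (
    ConcentrationTrajectory,
    DoseSchedule,
    PkParams,
    emergence_decay,
    fentanyl_to_remifentanil,
    schnider_propofol,
    scott_fentanyl,
    simulate_compartments,
)

__all__ = ["CohortConfig", "Patient", "Cohort", "generate_cohort", "make_null_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the virtual cohort.

    Defaults reproduce the modeled study conditions: 29 patients, age
    54.6 ± 11.6 y, weight 60.6 ± 12.2 kg, height 159.5 ± 8.8 cm, operation
    time 198 ± 43 min, fentanyl induction bolus 3-5 µg/kg, propofol
    effect-site maintenance target drawn from 4-6 µg/mL (within the stated
    4-10 µg/mL titration band and the observed concentration envelope).

    ``dt_min`` is the concentration/label grid (0.1 min, i.e. ten records
    per minute — the resolution that reproduces the >57,000 pooled
    concentration sets of a 29-patient cohort); OAA/S is scored every
    ``oaas_dt_s`` seconds (20 s) during emergence.  ``cer_mode`` selects
    whether the remifentanil-equivalent concentration decays with fentanyl
    kinetics ("decay", default) or is held at its induction peak
    ("constant").
    """

    n_patients: int = 29
    seed: int = 0
    age_mean_sd: tuple = (54.6, 11.6)
    weight_mean_sd: tuple = (60.6, 12.2)
    height_mean_sd: tuple = (159.5, 8.8)
    frac_male: float = 11.0 / 29.0
    op_time_mean_sd: tuple = (198.0, 43.0)
    fentanyl_bolus_ugkg: tuple = (3.0, 5.0)
    propofol_target_range: tuple = (4.0, 6.0)
    potency_factor: float = 1.2
    dt_min: float = 0.1
    oaas_dt_s: float = 20.0
    emergence_horizon_min: float = 90.0
    post_rr_window_min: float = 10.0
    greco_params: dict = field(default_factory=lambda: dict(PRESETS["oaas_lt4"]))
    observation_noise: bool = True
    cer_mode: str = "decay"
    labeling_scheme: str = "interval"

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidParameterError("n_patients must be >= 1")
        for name in ("age_mean_sd", "weight_mean_sd", "height_mean_sd", "op_time_mean_sd"):
            mean, sd = getattr(self, name)
            if sd < 0 or mean <= 0:
                raise InvalidParameterError(f"{name} must have positive mean and sd >= 0")
        lo, hi = self.fentanyl_bolus_ugkg
        if not (0 < lo <= hi):
            raise InvalidParameterError("fentanyl bolus range must satisfy 0 < lo <= hi")
        lo, hi = self.propofol_target_range
        if not (0 < lo <= hi <= 12):
            raise InvalidParameterError("propofol target range must lie within (0, 12] µg/mL")
        if not (0 <= self.frac_male <= 1):
            raise InvalidParameterError("frac_male must be in [0, 1]")
        if self.dt_min <= 0 or self.oaas_dt_s <= 0:
            raise InvalidParameterError("grid intervals must be positive")
        if self.emergence_horizon_min <= 0 or self.post_rr_window_min < 0:
            raise InvalidParameterError("horizon must be positive, post-RR window >= 0")
        if self.potency_factor <= 0:
            raise InvalidParameterError("potency_factor must be positive")
        if self.cer_mode not in ("decay", "constant"):
            raise InvalidParameterError("cer_mode must be 'decay' or 'constant'")
        if self.labeling_scheme not in ("interval", "endpoints"):
            raise InvalidParameterError("labeling_scheme must be 'interval' or 'endpoints'")


@dataclass
class Patient:
    patient_id: str
    age: float
    weight: float
    height: float
    sex: str
    op_time: float
    fentanyl_dose_ug: float
    propofol_target: float


@dataclass
class Cohort:
    """Everything the downstream stages consume, plus ground truth."""

    config: CohortConfig
    patients: list
    trajectories: list  # per-patient ConcentrationTrajectory on the dt_min grid
    oaas: pd.DataFrame  # columns patient_id, time_min, oaas (emergence, 20-s grid)
    lor_times: dict  # patient_id -> LOR time (min)
    rr_observed: dict  # patient_id -> RR detected from the OAA/S stream, or None
    rr_predicted: dict  # patient_id -> 50%-P(RR) time from the truth surface, or None
    emergence_trajectories: list  # 20-s-grid trajectories over the emergence window

    def labeled_dataset(self, scheme: Optional[str] = None) -> pd.DataFrame:
        """Binary-labeled concentration sets between LOR and RR + window."""
        return labels_mod.build_dataset(
            self.trajectories,
            self.lor_times,
            self.rr_observed,
            post_rr_window=self.config.post_rr_window_min,
            scheme=scheme or self.config.labeling_scheme,
        )

    def manifest(self) -> dict:
        """Per-patient ground truth and the full generator config, for reproducibility."""
        cfg = dataclasses.asdict(self.config)
        return {
            "config": cfg,
            "patients": [
                {
                    **dataclasses.asdict(p),
                    "lor_time_min": self.lor_times[p.patient_id],
                    "rr_observed_min": self.rr_observed[p.patient_id],
                    "rr_predicted_min": self.rr_predicted[p.patient_id],
                }
                for p in self.patients
            ],
        }


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    if sd == 0:
        return np.full(size, mean) if size else float(mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _bet_infusion_segments(target: float, params: PkParams, t_stop: float) -> list:
    """Per-minute constant-target infusion rates for the mammillary model.

    Holding plasma concentration at ``target`` exactly requires rate
    ``r(t) = target * v1 * (k10 + k12 e^{-k21 t} + k13 e^{-k31 t})`` after an
    initial bolus ``target * v1``; each 1-min segment uses the rate's exact
    average over the segment so the discretized profile stays within a hair
    of the target.
    """
    segments = []
    n_min = int(round(t_stop))
    for k in range(n_min):
        a, b = float(k), float(k + 1)

        def seg_mean(kk, rate_const):
            if rate_const == 0.0:
                return kk
            return kk * (np.exp(-rate_const * a) - np.exp(-rate_const * b)) / (rate_const * (b - a))

        r = target * params.v1 * (
            params.k10 + seg_mean(params.k12, params.k21) + seg_mean(params.k13, params.k31)
        )
        segments.append((a, b, r))
    return segments


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a virtual cohort; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    surface = GrecoResponseSurface(**config.greco_params).fit()
    dt = config.dt_min
    dt_oaas = config.oaas_dt_s / 60.0

    patients, trajectories, em_trajectories = [], [], []
    oaas_frames = []
    lor_times, rr_observed, rr_predicted = {}, {}, {}

    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        age = _truncated_normal(rng, *config.age_mean_sd, 20.0, 80.0)
        weight = _truncated_normal(rng, *config.weight_mean_sd, 35.0, 120.0)
        height = _truncated_normal(rng, *config.height_mean_sd, 130.0, 195.0)
        sex = "M" if rng.random() < config.frac_male else "F"
        op_time = float(np.round(_truncated_normal(rng, *config.op_time_mean_sd, 60.0, 360.0)))
        fent_ugkg = rng.uniform(*config.fentanyl_bolus_ugkg)
        target = rng.uniform(*config.propofol_target_range)
        patient = Patient(pid, age, weight, height, sex, op_time, fent_ugkg * weight, target)

        prop_params = schnider_propofol(age, weight, height, sex)
        fent_params = scott_fentanyl()
        duration = op_time + config.emergence_horizon_min

        prop_schedule = DoseSchedule(
            boluses=((0.0, target * prop_params.v1),),
            infusions=tuple(_bet_infusion_segments(target, prop_params, op_time)),
        )
        prop = simulate_compartments(prop_params, prop_schedule, dt=dt, duration=duration)

        fent_schedule = DoseSchedule(boluses=((0.0, patient.fentanyl_dose_ug),))
        fent = simulate_compartments(fent_params, fent_schedule, dt=dt, duration=duration)
        cer = fentanyl_to_remifentanil(fent.ce, config.potency_factor)
        if config.cer_mode == "constant":
            cer = np.full_like(cer, cer.max())

        traj = ConcentrationTrajectory(pid, prop.times, prop.ce, cer)

        # LOR: first grid time at which the truth surface says P(LOR) >= 0.5.
        p_lor = np.asarray(surface.p_lor(traj.cep, traj.cer))
        lor_idx = np.flatnonzero(p_lor >= 0.5)
        lor_times[pid] = float(traj.times[lor_idx[0]]) if lor_idx.size else None

        # Emergence: continue both drugs from the stop-time state on the 20-s grid.
        k_stop = int(round(op_time / dt))
        prop_em = emergence_decay(
            prop.states[k_stop], prop_params, config.emergence_horizon_min, dt=dt_oaas
        )
        fent_em = emergence_decay(
            fent.states[k_stop], fent_params, config.emergence_horizon_min, dt=dt_oaas
        )
        cer_em = fentanyl_to_remifentanil(fent_em.ce, config.potency_factor)
        if config.cer_mode == "constant":
            cer_em = np.full_like(cer_em, cer.max())
        times_em = op_time + prop_em.times
        em_traj = ConcentrationTrajectory(pid, times_em, prop_em.ce, cer_em)

        p_rr = np.asarray(surface.p_rr(em_traj.cep, em_traj.cer))
        if config.observation_noise:
            responsive = rng.random(p_rr.size) < p_rr
        else:
            responsive = p_rr >= 0.5
        scores = np.where(responsive, 4, 3)
        oaas_frames.append(
            pd.DataFrame({"patient_id": pid, "time_min": times_em, "oaas": scores})
        )
        rr_observed[pid] = labels_mod.detect_rr(times_em, scores)
        rr_predicted[pid] = surface.predict_rr_time(em_traj)

        patients.append(patient)
        trajectories.append(traj)
        em_trajectories.append(em_traj)

    oaas = pd.concat(oaas_frames, ignore_index=True)
    return Cohort(
        config=config,
        patients=patients,
        trajectories=trajectories,
        oaas=oaas,
        lor_times=lor_times,
        rr_observed=rr_observed,
        rr_predicted=rr_predicted,
        emergence_trajectories=em_trajectories,
    )


def make_null_cohort(config: CohortConfig) -> pd.DataFrame:
    """Negative control: the cohort's concentration rows with labels that
    ignore the concentrations entirely (fair-coin Bernoulli per row).

    Any model scored against such labels should show AUC near 0.5, and
    forward selection should usually admit no term.
    """
    cohort = generate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6E756C6C]))
    frames = []
    for traj in cohort.trajectories:
        lor = cohort.lor_times[traj.patient_id]
        if lor is None:
            continue
        keep = traj.times >= lor
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": traj.patient_id,
                    "time_min": traj.times[keep],
                    "cep_ugml": traj.cep[keep],
                    "cer_ngml": traj.cer[keep],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["label"] = rng.integers(0, 2, size=len(out))
    return out
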