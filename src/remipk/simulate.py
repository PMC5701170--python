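"""Synthetic study generator emulating the VA-ECMO remifentanil design.

Emulated design: 15 adult VA-ECMO patients on open-ended constant-rate
remifentanil infusion; sparse sampling in three windows (T1 uniform on
8-12 h, T2 at 24 h, T3 uniform on 36-48 h) plus an optional serial
post-discontinuation series at 5/10/15/25/30/40 min after the infusion
stops; log-normal between-subject variability on clearance; combined
proportional + additive residual error; assay LLOQ 0.05 ng/mL.

Continuous covariates (age, weight, BMI, total protein) and infusion rates
are resampled with replacement from the published 15-patient baseline table
(the only individual-level data in print).  ECMO pump speed was published
only as a cohort median (2350 RPM) with IQR (2302, 2532); it is drawn from a
log-normal calibrated to those summaries.  Serum creatinine, temperature and
ECMO flow were not tabulated per patient; they are drawn from plausible ICU
distributions and are marked synthetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import PUMP_SPEED_IQR, PUMP_SPEED_MEDIAN, table1_fixture
from .data import (LLOQ, CovariateRecord, InfusionEvent, Observation,
                   StudyDataset, SubjectRecord)
from .structural import PopulationModel, final_2017, individual_params, concentration

__all__ = ["StudyDesign", "generate_covariates", "generate_study",
           "paper_like_study", "rich_design"]

# log-normal pump-speed scale matched to the published IQR ratio:
# exp(2 * 0.6745 * sigma) = q75/q25
_PUMP_SIGMA = math.log(PUMP_SPEED_IQR[1] / PUMP_SPEED_IQR[0]) / (2 * 0.674489750196082)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling and covariate design of a synthetic study.

    Defaults reproduce the emulated study's conditions; ``rich_times``
    replaces the sparse windows by a fixed dense grid (for estimation
    experiments).  ``n_disc_subjects`` subjects stop their infusion at
    ``disc_stop_time`` and contribute the serial post-discontinuation series.
    """

    n_subjects: int = 15
    t1_window: tuple = (8.0, 12.0)
    t2: float = 24.0
    t3_window: tuple = (36.0, 48.0)
    disc_offsets_min: tuple = (5.0, 10.0, 15.0, 25.0, 30.0, 40.0)
    n_disc_subjects: int = 0
    disc_stop_time: float = 44.0
    infusion_duration: float = 48.0
    p_male: float = 0.67
    p_crrt: float = 9.0 / 15.0
    pump_median: float = PUMP_SPEED_MEDIAN
    pump_sigma: float = _PUMP_SIGMA
    lloq: float = LLOQ
    rich_times: Optional[tuple] = None
    rate_change: bool = False  # one mid-study rate step to exercise superposition

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (self.t1_window[0] < self.t1_window[1] <= self.t2
                <= self.t3_window[0] < self.t3_window[1]):
            raise ValueError("sampling windows must be ordered")


def rich_design(n_subjects: int = 200,
                times: Sequence[float] = (0.05, 0.15, 0.3, 0.6, 12, 24, 36, 48)) -> StudyDesign:
    """Rich-sampling design for simulation-estimation experiments.

    Half the default times sit in the onset phase (first ~40 min): with an
    elimination half-life of a few minutes, volume of distribution is only
    identifiable before steady state is reached.
    """
    return StudyDesign(n_subjects=n_subjects, rich_times=tuple(float(t) for t in times))


def generate_covariates(n: int, design: StudyDesign = StudyDesign(),
                        seed=None) -> list[CovariateRecord]:
    """Draw ``n`` subjects' covariates from the design distributions."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n == 0:
        return []
    t1 = table1_fixture()
    cols = {c: t1[c].to_numpy(float) for c in ("age", "weight", "bmi", "total_protein")}
    out = []
    for _ in range(n):
        sex = int(rng.random() < design.p_male)
        pump = float(design.pump_median * np.exp(rng.normal(0.0, design.pump_sigma)))
        out.append(CovariateRecord(
            sex=sex,
            pump_speed=pump,
            age=float(rng.choice(cols["age"])),
            weight=float(rng.choice(cols["weight"])),
            bmi=float(rng.choice(cols["bmi"])),
            total_protein=float(rng.choice(cols["total_protein"])),
            crrt=int(rng.random() < design.p_crrt),
            # not tabulated per patient -- synthetic stand-ins:
            ecmo_flow=float(np.clip(rng.normal(3.5, 0.4), 2.0, 6.0)),
            scr=float(np.exp(rng.normal(np.log(1.2), 0.4))),
            temperature=float(rng.normal(36.5, 0.6)),
        ))
    return out


def _sample_times(design: StudyDesign, rng, disc: bool) -> tuple[np.ndarray, float]:
    """Observation times and infusion stop time for one subject."""
    stop = design.disc_stop_time if disc else design.infusion_duration
    if design.rich_times is not None:
        times = [t for t in design.rich_times if t <= stop + 2.0]
    else:
        t3_hi = min(design.t3_window[1], stop)
        times = [rng.uniform(*design.t1_window), design.t2,
                 rng.uniform(design.t3_window[0], t3_hi)]
    if disc:
        times += [stop + m / 60.0 for m in design.disc_offsets_min]
    return np.array(sorted(times)), stop


def generate_study(design: StudyDesign, generating_model: PopulationModel,
                   seed=None, metadata: str = "synthetic study") -> StudyDataset:
    """Simulate a full study: covariates, etas, infusion schedules, sampled
    concentrations with combined residual error, and LLOQ censor flags."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    covs = generate_covariates(design.n_subjects, design, seed=rng)
    rates = table1_fixture()["rate"].to_numpy(float)
    omega = generating_model.omega_cl
    subjects = []
    for i, cov in enumerate(covs):
        disc = i < design.n_disc_subjects
        times, stop = _sample_times(design, rng, disc)
        rate = float(rng.choice(rates))
        if design.rate_change:
            mid = stop / 2.0
            doses = (InfusionEvent(0.0, rate, mid),
                     InfusionEvent(mid, rate * 1.5, stop - mid))
        else:
            doses = (InfusionEvent(0.0, rate, stop),)
        eta = rng.normal(0.0, omega) if omega > 0 else 0.0
        params = individual_params(generating_model, cov, eta_cl=eta)
        f = concentration(params, doses, times)
        eps_p = (rng.normal(0.0, generating_model.sigma_prop, f.size)
                 if generating_model.sigma_prop else np.zeros(f.size))
        eps_a = (rng.normal(0.0, generating_model.sigma_add, f.size)
                 if generating_model.sigma_add else np.zeros(f.size))
        y = f * (1.0 + eps_p) + eps_a
        obs = [Observation(time=float(t), concentration=float(max(yi, 0.0)),
                           blq_flag=bool(yi < design.lloq))
               for t, yi in zip(times, y)]
        subjects.append(SubjectRecord(id=f"S{i + 1:03d}", covariates=cov,
                                      doses=doses, observations=obs))
    return StudyDataset(subjects=tuple(subjects), metadata=metadata)


def paper_like_study(seed=None) -> StudyDataset:
    """A study emulating the published one: 15 subjects generated from the
    final published model, sparse sampling, two subjects contributing the
    post-discontinuation series (>= 3 samples per subject, ~55 total)."""
    design = StudyDesign(n_subjects=15, n_disc_subjects=2)
    return generate_study(design, final_2017(), seed=seed,
                          metadata="synthetic 15-subject study, final_2017 generating model")
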