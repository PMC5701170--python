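"""One-compartment infusion model with covariate clearance and combined error.

Structural model: a single compartment with zero-order (constant-rate) input
and first-order elimination.  For an infusion segment of rate R (mg/h) active
on [t0, t1], with clearance CL (L/h) and volume V (L), k = CL/V, the
contribution to the plasma concentration at time t >= t0 is

    C(t) = 1000 * (R / CL) * (1 - exp(-k * (min(t, t1) - t0)))
                          * exp(-k * max(0, t - t1))        [ng/mL]

and the full profile is the superposition over segments.  The factor 1000
converts mg/L to ng/mL.

Typical clearance is the product of a reference value and multiplicative
covariate factors; the published final model is

    CL (L/h) = 366 * 0.502^sex * (pump_speed / 2350)^2.04,   V (L) = 41

with female = 0, male = 1.  Between-subject variability is log-normal on CL
only (CL_i = TVCL_i * exp(eta_i), eta ~ N(0, omega^2)); the residual model is
combined proportional + additive: y = f*(1 + eps_p) + eps_a.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .covariates import CovariateEffect
from .data import CovariateRecord, InfusionEvent

__all__ = [
    "PopulationModel", "IndividualParams", "final_2017", "base_model",
    "typical_clearance", "individual_params", "concentration", "residual_sd",
    "random_effect_sd",
]


def random_effect_sd(omega2: float) -> float:
    """Standard deviation of the log-normal between-subject random effect.

    The published random-effect table reports omega_CL = 0.124; following the
    NONMEM convention that OMEGA entries are variances this is interpreted as
    omega^2, giving SD sqrt(0.124) ~= 0.352.  This function is the single
    place where that convention lives.
    """
    return math.sqrt(omega2)


@dataclass(frozen=True)
class IndividualParams:
    """Subject-level PK parameters."""

    cl: float       # L/h
    v: float        # L
    eta_cl: float

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v > 0):
            raise ValueError("cl and v must be positive")

    @property
    def k(self) -> float:
        """First-order elimination rate constant, 1/h."""
        return self.cl / self.v


@dataclass(frozen=True)
class PopulationModel:
    """Population PK parameter set: fixed effects, covariate effects,
    between-subject variance, and residual-error SDs.

    ``tvcl``/``tvv`` are the typical clearance (L/h) and volume (L) for a
    reference subject (all covariate factors equal to one).  ``omega2_cl`` is
    the variance of the log-normal clearance random effect; ``sigma_prop``
    (unitless) and ``sigma_add`` (ng/mL) are the residual-error SDs.
    """

    tvcl: float
    tvv: float
    omega2_cl: float = 0.0
    sigma_prop: float = 0.0
    sigma_add: float = 0.0
    effects: tuple[CovariateEffect, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", tuple(self.effects))
        if not (self.tvcl > 0 and self.tvv > 0):
            raise ValueError("tvcl and tvv must be positive")
        if self.omega2_cl < 0 or self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("variance components must be non-negative")
        # both residual components may be zero only for noise-free simulation;
        # estimation raises on zero residual variance at evaluation time

    # -- parameter-vector plumbing -------------------------------------------------

    @property
    def param_names(self) -> list[str]:
        return (["tvcl", "tvv"] + [e.name for e in self.effects]
                + ["omega2_cl", "sigma_prop", "sigma_add"])

    @property
    def params(self) -> dict[str, float]:
        out = {"tvcl": self.tvcl, "tvv": self.tvv}
        for e in self.effects:
            out[e.name] = e.coef
        out.update(omega2_cl=self.omega2_cl, sigma_prop=self.sigma_prop,
                   sigma_add=self.sigma_add)
        return out

    def param_positive(self, name: str) -> bool:
        """Whether a parameter is constrained positive (estimated on log scale)."""
        if name in ("tvcl", "tvv", "omega2_cl", "sigma_prop", "sigma_add"):
            return True
        return self.get_effect(name).positive

    def get_effect(self, name: str) -> CovariateEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def with_params(self, **updates: float) -> "PopulationModel":
        """Return a copy with named parameters replaced."""
        fields = {k: v for k, v in updates.items()
                  if k in ("tvcl", "tvv", "omega2_cl", "sigma_prop", "sigma_add")}
        effects = list(self.effects)
        for i, e in enumerate(effects):
            if e.name in updates:
                effects[i] = replace(e, coef=updates[e.name])
        unknown = set(updates) - set(fields) - {e.name for e in self.effects}
        if unknown:
            raise KeyError(f"unknown parameters {sorted(unknown)}")
        return replace(self, effects=tuple(effects), **fields)

    def add_effect(self, effect: CovariateEffect) -> "PopulationModel":
        if any(e.name == effect.name for e in self.effects):
            raise ValueError(f"effect {effect.name} already present")
        return replace(self, effects=self.effects + (effect,))

    @property
    def omega_cl(self) -> float:
        return random_effect_sd(self.omega2_cl)

    # -- model evaluation ----------------------------------------------------------

    def typical_cl(self, cov: CovariateRecord) -> float:
        return typical_clearance(self, cov)

    def typical_v(self, cov: CovariateRecord) -> float:
        v = self.tvv
        for e in self.effects:
            if e.parameter == "v":
                v *= e.factor(cov.get(e.covariate))
        return v

    def residual_sd(self, f):
        return residual_sd(f, self.sigma_prop, self.sigma_add)


def typical_clearance(model: PopulationModel, cov: CovariateRecord) -> float:
    """Typical (pre-random-effect) clearance for a subject's covariates, L/h."""
    if not cov.pump_speed > 0:
        raise ValueError("pump_speed must be positive")
    cl = model.tvcl
    for e in model.effects:
        if e.parameter == "cl":
            value = cov.get(e.covariate)
            if value is None:
                raise ValueError(f"covariate {e.covariate} missing for clearance model")
            cl *= e.factor(value)
    return float(cl)


def individual_params(model: PopulationModel, cov: CovariateRecord,
                      eta_cl: float = 0.0) -> IndividualParams:
    """Subject-level parameters: CL = typical CL * exp(eta); V carries no
    random effect."""
    return IndividualParams(cl=typical_clearance(model, cov) * math.exp(eta_cl),
                            v=model.typical_v(cov), eta_cl=eta_cl)


def _dose_arrays(doses: Sequence[InfusionEvent]):
    r = np.array([d.rate for d in doses], dtype=float)
    t0 = np.array([d.start_time for d in doses], dtype=float)
    t1 = np.array([d.end_time for d in doses], dtype=float)
    return r, t0, t1


def concentration(params: IndividualParams, doses: Sequence[InfusionEvent], t,
                  grad: bool = False):
    """Plasma concentration (ng/mL) at time(s) ``t`` by closed-form
    superposition over infusion segments.

    With ``grad=True`` also returns d(conc)/d(CL) (for the conditional-mode
    Newton steps of the estimation module).
    """
    cl, v = params.cl, params.v
    if not (cl > 0 and v > 0):
        raise ValueError("cl and v must be positive")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    r, t0, t1 = _dose_arrays(doses)
    k = cl / v
    # tau_a: active-infusion exposure time; tau_b: decay time after segment end
    tau_a = np.clip(np.minimum(t_arr[:, None], t1[None, :]) - t0[None, :], 0.0, None)
    tau_b = np.clip(t_arr[:, None] - t1[None, :], 0.0, None)
    ea = np.exp(-k * tau_a)
    eb = np.exp(-k * tau_b)
    amp = 1000.0 * r[None, :] / cl
    contrib = amp * (1.0 - ea) * eb
    c = contrib.sum(axis=1)
    if not grad:
        return c if np.ndim(t) else float(c[0])
    dcontrib = -contrib / cl + (amp / v) * (tau_a * ea * eb - tau_b * (1.0 - ea) * eb)
    dc = dcontrib.sum(axis=1)
    if np.ndim(t):
        return c, dc
    return float(c[0]), float(dc[0])


def residual_sd(f, sigma_prop: float, sigma_add: float):
    """SD of the combined residual-error model at model prediction ``f``:
    sqrt(sigma_prop^2 * f^2 + sigma_add^2), ng/mL."""
    f = np.asarray(f, dtype=float)
    out = np.sqrt(sigma_prop ** 2 * f ** 2 + sigma_add ** 2)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------

def final_2017() -> PopulationModel:
    """The published final model: CL = 366 * 0.502^sex * (pump/2350)^2.04 L/h,
    V = 41 L, omega^2_CL = 0.124, sigma_prop = 0.387, sigma_add = 0.111 ng/mL."""
    return PopulationModel(
        tvcl=366.0, tvv=41.0, omega2_cl=0.124,
        sigma_prop=0.387, sigma_add=0.111,
        effects=(
            CovariateEffect("cl", "sex", "power", 0.502, categorical=True),
            CovariateEffect("cl", "pump_speed", "power", 2.04, center=2350.0),
        ),
    )


def base_model() -> PopulationModel:
    """Covariate-free companion of the final model (same structural and
    random-effect components, no covariate terms)."""
    return PopulationModel(tvcl=300.0, tvv=41.0, omega2_cl=0.124,
                           sigma_prop=0.387, sigma_add=0.111)


#: Registry of named model presets for config files and the CLI.
PRESETS = {"final_2017": final_2017, "base": base_model}
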