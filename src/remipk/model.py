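"""Model / Results objects for population PK estimation.

:class:`PopPKModel` binds a :class:`~remipk.data.StudyDataset` to a
:class:`~remipk.structural.PopulationModel` parameter specification and a set
of free parameters; ``fit()`` maximises the FOCE-I approximate marginal
likelihood and returns a :class:`PKFitResults` carrying estimates, standard
errors, empirical Bayes etas, shrinkage, per-observation diagnostics and a
``summary()`` table.  Validation (bootstrap, pcVPC) and simulation hang off
the results object.

Positive parameters (typical values, variance components, power-form
categorical coefficients) are estimated on the log scale; the outer optimiser
is L-BFGS-B with numerical gradients, warm-starting each inner conditional-
mode search from the previous one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import StudyDataset
from .foce import (PackedData, EstimationError, compute_diagnostics,
                   eta_shrinkage, foce_objective)
from .structural import PopulationModel

__all__ = ["PopPKModel", "PKFitResults"]


class PopPKModel:
    """Nonlinear mixed-effects population PK model bound to a dataset.

    Parameters
    ----------
    dataset : StudyDataset
        Event-record data; BLQ observations are excluded from the likelihood.
    spec : PopulationModel
        Parameter specification.  Its values serve as default initial
        estimates.
    free : sequence of str, optional
        Names of parameters to estimate; all of ``spec.param_names`` by
        default.  The rest stay fixed at their spec values.
    """

    def __init__(self, dataset: StudyDataset, spec: PopulationModel,
                 free: Optional[Sequence[str]] = None):
        self.dataset = dataset
        self.spec = spec
        self.packed = PackedData.from_dataset(dataset)
        self.free = list(free) if free is not None else list(spec.param_names)
        unknown = set(self.free) - set(spec.param_names)
        if unknown:
            raise ValueError(f"unknown free parameters {sorted(unknown)}")
        if self.packed.n_obs <= len(self.free) + 2:
            raise EstimationError(
                f"{len(self.free)} free parameters cannot be identified from "
                f"{self.packed.n_obs} observations")

    # -- transforms ---------------------------------------------------------------

    def _to_x(self, params: dict) -> np.ndarray:
        x = []
        for name in self.free:
            val = params[name]
            if self.spec.param_positive(name):
                if not val > 0:
                    raise ValueError(f"parameter {name} must be positive, got {val}")
                x.append(np.log(val))
            else:
                x.append(val)
        return np.asarray(x, float)

    def _from_x(self, x: np.ndarray) -> dict:
        out = {}
        for name, xi in zip(self.free, x):
            out[name] = float(np.exp(xi)) if self.spec.param_positive(name) else float(xi)
        return out

    # -- objective ----------------------------------------------------------------

    def ofv(self, params: Optional[dict] = None,
            eta0: Optional[np.ndarray] = None) -> float:
        """FOCE-I objective function value at the given (or spec) parameters."""
        spec = self.spec.with_params(**params) if params else self.spec
        return foce_objective(self.packed, spec, eta0=eta0)

    def fit(self, inits: Optional[dict] = None, compute_se: bool = True,
            ftol: float = 1e-9, gtol: float = 1e-5, maxiter: int = 400) -> "PKFitResults":
        """Maximise the FOCE-I approximate likelihood over the free parameters.

        ``inits`` overrides initial estimates by name.  The fit is
        deterministic: repeated calls with the same inits give identical
        results.
        """
        start = dict(self.spec.params)
        if inits:
            start.update(inits)
        x0 = self._to_x(start)
        eta_cache = {"eta": None}

        def objective(x: np.ndarray) -> float:
            params = self._from_x(x)
            try:
                spec = self.spec.with_params(**params)
                val, eta = foce_objective(self.packed, spec,
                                          eta0=eta_cache["eta"], return_etas=True)
            except (EstimationError, FloatingPointError, ValueError):
                return 1e12
            if not np.isfinite(val):
                return 1e12
            eta_cache["eta"] = eta
            return val

        with np.errstate(over="ignore", invalid="ignore"):
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B",
                options={"ftol": ftol, "gtol": gtol, "maxiter": maxiter})
        params = self._from_x(res.x)
        spec = self.spec.with_params(**params)
        ofv, eta = foce_objective(self.packed, spec, return_etas=True)
        se = rse = None
        if compute_se:
            se, rse = self._standard_errors(res.x, ofv)
        ebes = pd.Series(eta, index=pd.Index(self.packed.subject_ids, name="id"),
                         name="eta_cl")
        return PKFitResults(
            model=self, spec=spec, params=pd.Series(spec.params)[self.free + [
                n for n in spec.param_names if n not in self.free]],
            free=list(self.free), ofv=float(ofv), converged=bool(res.success),
            message=str(res.message), n_iter=int(res.nit),
            se=se, rse=rse, ebes=ebes,
        )

    def _standard_errors(self, x_opt: np.ndarray, ofv_opt: float):
        """Asymptotic SEs from a central-difference Hessian of the OFV with
        respect to the natural-scale free parameters; RSE% = 100*SE/|estimate|.
        Returns (None, None) when the Hessian is not positive definite."""
        params_opt = self._from_x(x_opt)
        names = self.free
        p0 = np.array([params_opt[n] for n in names])
        steps = 1e-3 * np.maximum(np.abs(p0), 1e-6)

        def f(p: np.ndarray) -> float:
            d = dict(zip(names, p))
            try:
                return foce_objective(self.packed, self.spec.with_params(**d))
            except (EstimationError, ValueError):
                return np.nan
        n = len(names)
        H = np.empty((n, n))
        f0 = f(p0)
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = steps[i]
                ej = np.zeros(n); ej[j] = steps[j]
                if i == j:
                    H[i, i] = (f(p0 + ei) - 2 * f0 + f(p0 - ei)) / steps[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(p0 + ei + ej) - f(p0 + ei - ej)
                        - f(p0 - ei + ej) + f(p0 - ei - ej)
                    ) / (4 * steps[i] * steps[j])
        try:
            cov = 2.0 * np.linalg.inv(H)  # OFV = -2 logL, so Cov = 2 H^-1
            diag = np.diag(cov)
            if np.any(~np.isfinite(diag)) or np.any(diag <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn("OFV Hessian not positive definite; standard errors "
                          "unavailable", RuntimeWarning)
            return None, None
        se = pd.Series(np.sqrt(diag), index=names, name="se")
        rse = pd.Series(100.0 * se.to_numpy() / np.abs(p0), index=names, name="rse_pct")
        return se, rse

    # -- simulation on the design --------------------------------------------------

    def simulate_observations(self, rng: np.random.Generator,
                              spec: Optional[PopulationModel] = None,
                              residual: bool = True) -> np.ndarray:
        """Draw one replicate of the packed observation vector on the original
        design (same subjects, doses, times, covariates; fresh etas and,
        optionally, residual errors)."""
        from .foce import subject_typicals, _predict

        spec = spec or self.spec
        packed = self.packed
        typcl, v = subject_typicals(packed, spec)
        eta = rng.normal(0.0, spec.omega_cl, packed.n_subjects) \
            if spec.omega2_cl > 0 else np.zeros(packed.n_subjects)
        f, _ = _predict(packed, typcl * np.exp(eta), v)
        if not residual:
            return f
        eps_p = rng.normal(0.0, spec.sigma_prop, packed.n_obs) if spec.sigma_prop else 0.0
        eps_a = rng.normal(0.0, spec.sigma_add, packed.n_obs) if spec.sigma_add else 0.0
        return f * (1.0 + eps_p) + eps_a


@dataclass
class PKFitResults:
    """Results of a FOCE-I fit.

    Attributes mirror the usual population-PK fit report: parameter estimates
    with SE and RSE%, the objective function value, per-subject empirical
    Bayes etas, eta shrinkage, and lazily computed per-observation
    diagnostics (PRED / IPRED / CWRES).
    """

    model: PopPKModel
    spec: PopulationModel
    params: pd.Series
    free: list
    ofv: float
    converged: bool
    message: str
    n_iter: int
    se: Optional[pd.Series]
    rse: Optional[pd.Series]
    ebes: pd.Series
    _diagnostics: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def n_obs(self) -> int:
        return self.model.packed.n_obs

    @property
    def n_subjects(self) -> int:
        return self.model.packed.n_subjects

    @property
    def shrinkage_cl(self) -> float:
        """Eta shrinkage for clearance, percent."""
        return eta_shrinkage(self.ebes.to_numpy(), self.spec.omega_cl)

    def diagnostics(self) -> pd.DataFrame:
        """Per-observation PRED, IPRED and CWRES at the final estimates."""
        if self._diagnostics is None:
            self._diagnostics = compute_diagnostics(
                self.model.packed, self.spec, eta=self.ebes.to_numpy())
        return self._diagnostics

    def prediction_correlations(self) -> dict:
        """Pearson r of observations against PRED and against IPRED."""
        d = self.diagnostics()
        return {
            "pred": float(stats.pearsonr(d["dv"], d["pred"]).statistic),
            "ipred": float(stats.pearsonr(d["dv"], d["ipred"]).statistic),
        }

    # -- downstream analyses -------------------------------------------------------

    def bootstrap(self, n_reps: int = 200, seed: int = 0, **kwargs):
        """Nonparametric bootstrap of this fit; see
        :func:`remipk.validation.bootstrap`."""
        from .validation import bootstrap
        return bootstrap(self.model.dataset, self.spec, free=self.free,
                         n_reps=n_reps, seed=seed,
                         inits=dict(self.params), **kwargs)

    def vpc(self, n_sim: int = 1000, seed: int = 0, bins=None, **kwargs):
        """Prediction-corrected visual predictive check of this fit; see
        :func:`remipk.validation.pcvpc`."""
        from .validation import pcvpc
        return pcvpc(self.model.dataset, self.spec, n_sim=n_sim, seed=seed,
                     bins=bins, **kwargs)

    def summary(self) -> str:
        """Fit report: estimates, RSE%, shrinkage, OFV and data counts."""
        lines = []
        lines.append("Population PK model fit (FOCE-I)")
        lines.append("=" * 58)
        lines.append(f"Subjects: {self.n_subjects}    Observations: {self.n_obs}")
        lines.append(f"OFV: {self.ofv:.3f}    Converged: {self.converged}")
        lines.append("-" * 58)
        lines.append(f"{'Parameter':<16}{'Estimate':>12}{'RSE %':>10}{'Shrink %':>12}")
        for name in self.params.index:
            est = self.params[name]
            rse = ("" if self.rse is None or name not in self.rse.index
                   else f"{self.rse[name]:.0f}")
            shr = f"{self.shrinkage_cl:.0f}" if name == "omega2_cl" else ""
            fixed = "" if name in self.free else "  (fixed)"
            lines.append(f"{name:<16}{est:>12.4g}{rse:>10}{shr:>12}{fixed}")
        lines.append("-" * 58)
        return "\n".join(lines)
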