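"""Covariate effect forms, likelihood-ratio testing, and forward selection.

Covariate effects enter PK parameters as composable multiplicative factors.
Continuous covariates are centred at their cohort median and may act through
a power, exponential, or linear form; categorical (0/1) covariates through a
power, exponential, or proportional form.  A candidate effect is kept when it
drops the objective function value (-2 log-likelihood) by more than 3.84,
the 95% point of chi-square with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONTINUOUS_FORMS", "CATEGORICAL_FORMS", "LRT_THRESHOLD",
    "CovariateEffect", "CovariateCandidate", "covariate_factor",
    "apply_covariate", "lrt_significant", "forward_select", "SelectionResult",
]

CONTINUOUS_FORMS = ("power", "exponential", "linear")
CATEGORICAL_FORMS = ("power", "exponential", "proportional")

#: OFV drop considered significant at p < 0.05 with 1 degree of freedom.
LRT_THRESHOLD = 3.84


@dataclass(frozen=True)
class CovariateEffect:
    """A single multiplicative covariate effect on a PK parameter.

    ``parameter`` is the PK parameter acted on ("cl" or "v"); ``covariate``
    the canonical covariate field name; ``center`` the centring constant for
    continuous forms (ignored for categorical ones).
    """

    parameter: str
    covariate: str
    form: str
    coef: float
    center: Optional[float] = None
    categorical: bool = False

    def __post_init__(self) -> None:
        allowed = CATEGORICAL_FORMS if self.categorical else CONTINUOUS_FORMS
        if self.form not in allowed:
            raise ValueError(
                f"form {self.form!r} not valid for "
                f"{'categorical' if self.categorical else 'continuous'} covariate")
        if not self.categorical and self.form == "power" and not (self.center or 0) > 0:
            raise ValueError("power form on a continuous covariate needs a positive center")

    @property
    def name(self) -> str:
        return f"{self.covariate}_{self.parameter}"

    @property
    def null_coef(self) -> float:
        """Coefficient value at which the effect is the identity."""
        return 1.0 if (self.categorical and self.form == "power") else 0.0

    @property
    def positive(self) -> bool:
        """Whether the coefficient is constrained positive (log-estimated)."""
        return self.categorical and self.form == "power"

    def factor(self, value):
        return covariate_factor(self.form, self.coef, value,
                                center=self.center, categorical=self.categorical)


def covariate_factor(form: str, coef: float, value, center: Optional[float] = None,
                     categorical: bool = False):
    """Multiplicative factor contributed by one covariate effect.

    Continuous: power ``(x/c)^coef``, exponential ``exp(coef*(x-c))``, linear
    ``1 + coef*(x-c)``.  Categorical (flag in {0,1}): power ``coef^flag``,
    exponential ``exp(coef*flag)``, proportional ``1 + coef*flag``.
    """
    x = np.asarray(value, dtype=float)
    if categorical:
        if form == "power":
            out = np.power(float(coef), x)
        elif form == "exponential":
            out = np.exp(coef * x)
        elif form == "proportional":
            out = 1.0 + coef * x
        else:
            raise ValueError(f"invalid categorical form {form!r}")
    else:
        if form == "power":
            if center is None or center <= 0:
                raise ValueError("power form requires a positive center")
            out = np.power(x / center, coef)
        elif form == "exponential":
            out = np.exp(coef * (x - center))
        elif form == "linear":
            out = 1.0 + coef * (x - center)
        else:
            raise ValueError(f"invalid continuous form {form!r}")
    return out if out.ndim else float(out)


def apply_covariate(base_value, form: str, coef: float, covariate_value,
                    center: Optional[float] = None, categorical: bool = False):
    """Apply one covariate effect to a base parameter value."""
    return base_value * covariate_factor(form, coef, covariate_value,
                                         center=center, categorical=categorical)


def lrt_significant(delta_ofv: float, df: int = 1) -> bool:
    """Likelihood-ratio significance of an OFV reduction at p < 0.05.

    With one degree of freedom the published rule is a strict drop of more
    than 3.84; other df fall back to the chi-square 95% quantile.
    """
    if not np.isfinite(delta_ofv):
        raise ValueError("delta_ofv must be finite")
    if df == 1:
        return delta_ofv > LRT_THRESHOLD
    return delta_ofv > stats.chi2.ppf(0.95, df)


@dataclass(frozen=True)
class CovariateCandidate:
    """A covariate under evaluation: which parameter it may act on, its kind,
    and the functional forms to try.  ``center`` must equal the dataset median
    for continuous candidates."""

    parameter: str
    covariate: str
    kind: str  # "continuous" | "categorical"
    forms: tuple[str, ...] = ()
    center: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"kind must be continuous or categorical, got {self.kind!r}")
        default = CONTINUOUS_FORMS if self.kind == "continuous" else CATEGORICAL_FORMS
        forms = tuple(self.forms) or default
        bad = set(forms) - set(default)
        if bad:
            raise ValueError(f"forms {sorted(bad)} not allowed for {self.kind} covariate")
        object.__setattr__(self, "forms", forms)

    def effect(self, form: str) -> CovariateEffect:
        eff = CovariateEffect(parameter=self.parameter, covariate=self.covariate,
                              form=form, coef=0.0, center=self.center,
                              categorical=self.kind == "categorical")
        return replace(eff, coef=eff.null_coef)


def candidates_from_dataset(dataset, covariates: Sequence[str],
                            parameter: str = "cl") -> list[CovariateCandidate]:
    """Build candidates for the named covariates, centring continuous ones at
    the per-dataset median (subjects with the covariate missing are ignored
    for centring)."""
    frame = dataset.covariate_frame()
    out = []
    for cov in covariates:
        vals = frame[cov].dropna()
        if vals.empty:
            continue
        categorical = cov in ("sex", "crrt") or set(vals.unique()) <= {0, 1}
        if categorical:
            out.append(CovariateCandidate(parameter, cov, "categorical"))
        else:
            out.append(CovariateCandidate(parameter, cov, "continuous",
                                          center=float(vals.median())))
    return out


@dataclass
class SelectionResult:
    """Outcome of forward covariate selection."""

    model: "object"           # fitted PopulationModel spec (final)
    fit: "object"             # PKFitResults of the final model
    trace: pd.DataFrame       # every tested (round, covariate, form, delta)
    included: list[CovariateEffect]


def forward_select(dataset, base_spec, candidates: Sequence[CovariateCandidate],
                   free: Optional[Sequence[str]] = None, **fit_kwargs) -> SelectionResult:
    """Greedy forward covariate selection by the ΔOFV > 3.84 rule.

    At each round every remaining (candidate, form) pair is added to the
    current model and refit; the pair with the largest significant OFV drop is
    included (ties broken lexicographically by covariate then form name), and
    the search repeats until no pair is significant.  Candidate fits that fail
    are recorded in the trace and skipped.
    """
    from .model import PopPKModel  # deferred to avoid an import cycle

    fit_kwargs.setdefault("compute_se", False)
    current_spec = base_spec
    current_fit = PopPKModel(dataset, current_spec, free=free).fit(**fit_kwargs)
    trace_rows = []
    included: list[CovariateEffect] = []
    remaining = list(candidates)
    round_no = 0
    while remaining:
        round_no += 1
        results = []
        for cand in remaining:
            for form in cand.forms:
                eff = cand.effect(form)
                spec = current_spec.add_effect(eff)
                cand_free = None if free is None else list(free) + [eff.name]
                row = {"round": round_no, "covariate": cand.covariate, "form": form,
                       "ofv_base": current_fit.ofv, "ofv_candidate": np.nan,
                       "delta_ofv": np.nan, "included": False, "error": ""}
                try:
                    fit = PopPKModel(dataset, spec, free=cand_free).fit(
                        inits=dict(current_fit.params, **{eff.name: eff.null_coef}),
                        **fit_kwargs)
                    row["ofv_candidate"] = fit.ofv
                    row["delta_ofv"] = current_fit.ofv - fit.ofv
                    results.append((cand, form, fit, row))
                except Exception as exc:  # candidate failure: record and continue
                    row["error"] = str(exc)
                trace_rows.append(row)
        significant = [r for r in results if lrt_significant(r[3]["delta_ofv"])]
        if not significant:
            break
        best = max(significant,
                   key=lambda r: (r[3]["delta_ofv"], r[0].covariate, r[1]))
        # deterministic tie-break: largest delta, then lexicographic name/form
        ties = [r for r in significant
                if abs(r[3]["delta_ofv"] - best[3]["delta_ofv"]) < 1e-9]
        best = min(ties, key=lambda r: (r[0].covariate, r[1]))
        cand, form, fit, row = best
        row["included"] = True
        included.append(fit.spec.get_effect(cand.effect(form).name))
        current_spec = fit.spec
        current_fit = fit
        if free is not None:
            free = list(free) + [cand.effect(form).name]
        remaining = [c for c in remaining if c.covariate != cand.covariate
                     or c.parameter != cand.parameter]
    trace = pd.DataFrame(trace_rows,
                         columns=["round", "covariate", "form", "ofv_base",
                                  "ofv_candidate", "delta_ofv", "included", "error"])
    return SelectionResult(model=current_spec, fit=current_fit,
                           trace=trace, included=included)
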