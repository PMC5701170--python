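"""FOCE-I marginal likelihood, conditional modes, shrinkage and diagnostics.

The marginal likelihood of a nonlinear mixed-effects model with a single
log-normal random effect per subject is a one-dimensional integral per
subject.  It is approximated here in the first-order-conditional-with-
interaction (FOCE-I) manner: a Laplace expansion about each subject's
conditional mode eta_hat with the residual variance evaluated at the
individual prediction.  Writing l(eta) for the subject's joint -2 log
density (data plus prior), the contribution is

    -2 log L_i  ~=  l(eta_hat) + log l''(eta_hat) - log(4 pi)

which is exact when the model is linear in eta with additive Gaussian error.
An adaptive Gauss-Hermite quadrature of the same integral is provided as an
independent reference (:func:`agq_objective`).

Below-LLOQ observations are excluded from the likelihood (the "M1" policy);
their flags are preserved in datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .data import StudyDataset
from .structural import PopulationModel

__all__ = [
    "PackedData", "foce_objective", "agq_objective", "conditional_modes",
    "empirical_bayes_etas", "eta_shrinkage", "compute_diagnostics",
    "EstimationError",
]

_LOG_2PI = math.log(2.0 * math.pi)
#: below this, omega^2 is treated as the degenerate (no-random-effect) limit
_OMEGA2_FLOOR = 1e-12
_VAR_FLOOR = 1e-290


class EstimationError(RuntimeError):
    """Raised when an inner or outer estimation step cannot proceed."""


@dataclass
class PackedData:
    """Flat-array view of a :class:`StudyDataset` for vectorised likelihood
    evaluation.  Observations flagged BLQ are dropped at packing time.

    Segment rows pair every usable observation with every infusion segment of
    its subject, so the superposition sum is a single ``bincount``.
    """

    subject_ids: list
    y: np.ndarray          # (n_obs,) observed concentrations
    t: np.ndarray          # (n_obs,) observation times
    obs_subj: np.ndarray   # (n_obs,) subject index per observation
    n_per_subject: np.ndarray
    seg_obs: np.ndarray    # (n_rows,) observation index per segment row
    seg_r: np.ndarray
    seg_t0: np.ndarray
    seg_t1: np.ndarray
    cov: dict              # covariate name -> (n_subjects,) array (nan = missing)

    @classmethod
    def from_dataset(cls, dataset: StudyDataset, drop_blq: bool = True) -> "PackedData":
        from .data import CovariateRecord

        ids, y, t, obs_subj = [], [], [], []
        seg_obs, seg_r, seg_t0, seg_t1 = [], [], [], []
        cov: dict[str, list] = {f: [] for f in CovariateRecord.__dataclass_fields__}
        n_per = []
        for si, subj in enumerate(dataset.subjects):
            ids.append(subj.id)
            for f in cov:
                val = subj.covariates.get(f)
                cov[f].append(np.nan if val is None else float(val))
            count = 0
            for obs in subj.observations:
                if drop_blq and obs.blq_flag:
                    continue
                oi = len(y)
                y.append(obs.concentration)
                t.append(obs.time)
                obs_subj.append(si)
                count += 1
                for d in subj.doses:
                    seg_obs.append(oi)
                    seg_r.append(d.rate)
                    seg_t0.append(d.start_time)
                    seg_t1.append(d.end_time)
            n_per.append(count)
        if min(n_per) == 0:
            bad = ids[int(np.argmin(n_per))]
            raise EstimationError(f"subject {bad} has no usable (non-BLQ) observations")
        return cls(
            subject_ids=ids,
            y=np.asarray(y, float), t=np.asarray(t, float),
            obs_subj=np.asarray(obs_subj, np.intp),
            n_per_subject=np.asarray(n_per, np.intp),
            seg_obs=np.asarray(seg_obs, np.intp), seg_r=np.asarray(seg_r, float),
            seg_t0=np.asarray(seg_t0, float), seg_t1=np.asarray(seg_t1, float),
            cov={k: np.asarray(v, float) for k, v in cov.items()},
        )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> int:
        return self.y.size


def subject_typicals(packed: PackedData, spec: PopulationModel):
    """Per-subject typical clearance and volume under the covariate model."""
    S = packed.n_subjects
    cl = np.full(S, spec.tvcl)
    v = np.full(S, spec.tvv)
    for e in spec.effects:
        vals = packed.cov[e.covariate]
        if np.isnan(vals).any():
            raise EstimationError(f"covariate {e.covariate} missing for some subjects")
        factor = e.factor(vals)
        if e.parameter == "cl":
            cl = cl * factor
        else:
            v = v * factor
    if np.any(~np.isfinite(cl)) or np.any(cl <= 0) or np.any(v <= 0):
        raise EstimationError("covariate model produced non-positive typical parameters")
    return cl, v


def _predict(packed: PackedData, cl_s: np.ndarray, v_s: np.ndarray):
    """Concentration and d(conc)/d(CL) at every packed observation."""
    cl_obs = cl_s[packed.obs_subj]
    v_obs = v_s[packed.obs_subj]
    cl_row = cl_obs[packed.seg_obs]
    v_row = v_obs[packed.seg_obs]
    t_row = packed.t[packed.seg_obs]
    k = cl_row / v_row
    tau_a = np.clip(np.minimum(t_row, packed.seg_t1) - packed.seg_t0, 0.0, None)
    tau_b = np.clip(t_row - packed.seg_t1, 0.0, None)
    ea = np.exp(-k * tau_a)
    eb = np.exp(-k * tau_b)
    amp = 1000.0 * packed.seg_r / cl_row
    contrib = amp * (1.0 - ea) * eb
    dcontrib = -contrib / cl_row + (amp / v_row) * (tau_a * ea * eb
                                                   - tau_b * (1.0 - ea) * eb)
    f = np.bincount(packed.seg_obs, weights=contrib, minlength=packed.n_obs)
    df = np.bincount(packed.seg_obs, weights=dcontrib, minlength=packed.n_obs)
    return f, df


def _joint_neg2(packed, eta, typcl_s, v_s, omega2, sp, sa, with_grad=True):
    """Per-subject joint -2 log density l(eta), gradient, and Gauss-Newton
    curvature (always positive).  Vectorised over subjects."""
    cl_s = typcl_s * np.exp(eta)
    f, dfdcl = _predict(packed, cl_s, v_s)
    var = sp * sp * f * f + sa * sa
    if np.any(var < _VAR_FLOOR):
        raise EstimationError("zero residual variance at an observation")
    r = packed.y - f
    obs_terms = np.log(var) + r * r / var + _LOG_2PI
    l = np.bincount(packed.obs_subj, weights=obs_terms, minlength=packed.n_subjects)
    l = l + math.log(2.0 * math.pi * omega2) + eta * eta / omega2
    if not with_grad:
        return l, None, None
    fp = dfdcl * cl_s[packed.obs_subj]  # df/deta by the chain rule
    varp = 2.0 * sp * sp * f * fp
    g_terms = (varp / var) * (1.0 - r * r / var) - 2.0 * r * fp / var
    g = np.bincount(packed.obs_subj, weights=g_terms, minlength=packed.n_subjects)
    g = g + 2.0 * eta / omega2
    h_terms = fp * fp / var
    h = 2.0 * (np.bincount(packed.obs_subj, weights=h_terms,
                           minlength=packed.n_subjects) + 1.0 / omega2)
    return l, g, h


def _subject_scalar_joint(packed, si, typcl, v, omega2, sp, sa):
    """Scalar l(eta) for one subject (fallback path and quadrature nodes)."""
    mask = packed.obs_subj == si
    y = packed.y[mask]
    t = packed.t[mask]
    obs_idx = np.flatnonzero(mask)
    seg_mask = np.isin(packed.seg_obs, obs_idx)
    seg_r = packed.seg_r[seg_mask]
    seg_t0 = packed.seg_t0[seg_mask]
    seg_t1 = packed.seg_t1[seg_mask]
    seg_local = np.searchsorted(obs_idx, packed.seg_obs[seg_mask])

    def l_of(eta: float) -> float:
        cl = typcl * math.exp(eta)
        k = cl / v
        t_row = t[seg_local]
        tau_a = np.clip(np.minimum(t_row, seg_t1) - seg_t0, 0.0, None)
        tau_b = np.clip(t_row - seg_t1, 0.0, None)
        contrib = 1000.0 * seg_r / cl * (1.0 - np.exp(-k * tau_a)) * np.exp(-k * tau_b)
        f = np.bincount(seg_local, weights=contrib, minlength=y.size)
        var = sp * sp * f * f + sa * sa
        r = y - f
        out = float(np.sum(np.log(var) + r * r / var + _LOG_2PI))
        return out + math.log(2.0 * math.pi * omega2) + eta * eta / omega2

    return l_of


def conditional_modes(packed: PackedData, spec: PopulationModel,
                      eta0: Optional[np.ndarray] = None,
                      tol: float = 1e-8, max_iter: int = 80):
    """Locate each subject's conditional mode of eta by safeguarded Newton.

    Steps use the (always positive) Gauss-Newton curvature with backtracking;
    subjects that fail to converge fall back to bounded scalar minimisation.
    Returns ``(eta_hat, l_at_mode)``.
    """
    omega2, sp, sa = spec.omega2_cl, spec.sigma_prop, spec.sigma_add
    typcl, v = subject_typicals(packed, spec)
    S = packed.n_subjects
    if omega2 < _OMEGA2_FLOOR:
        raise EstimationError("conditional modes undefined for omega2 ~ 0")
    eta = np.zeros(S) if eta0 is None else np.array(eta0, float)
    l, g, h = _joint_neg2(packed, eta, typcl, v, omega2, sp, sa)
    for _ in range(max_iter):
        active = np.abs(g) > tol * (1.0 + np.abs(l))
        if not active.any():
            break
        step = np.where(active, -np.clip(g / h, -2.0, 2.0), 0.0)
        alpha = np.ones(S)
        for _bt in range(12):
            trial = eta + alpha * step
            l_new, g_new, h_new = _joint_neg2(packed, trial, typcl, v, omega2, sp, sa)
            worse = active & (l_new > l + 1e-12) & (np.abs(alpha * step) > 1e-14)
            if not worse.any():
                break
            alpha[worse] *= 0.5
        accept = active & (l_new <= l + 1e-12)
        eta = np.where(accept, trial, eta)
        l = np.where(accept, l_new, l)
        g = np.where(accept, g_new, g)
        h = np.where(accept, h_new, h)
        if not accept.any():
            break
    bad = np.abs(g) > 100 * tol * (1.0 + np.abs(l))
    for si in np.flatnonzero(bad):  # rare: robust scalar fallback
        l_of = _subject_scalar_joint(packed, si, typcl[si], v[si], omega2, sp, sa)
        res = optimize.minimize_scalar(l_of, bounds=(-12.0, 12.0), method="bounded",
                                       options={"xatol": 1e-11})
        if l_of(res.x) <= l[si]:
            eta[si] = res.x
            l[si] = l_of(res.x)
    return eta, l


def _mode_curvature(packed, eta, typcl, v, omega2, sp, sa, h_gn):
    """Second derivative of l at the mode by central differences of the
    analytic gradient; Gauss-Newton curvature where the FD value is not
    usable (non-positive or non-finite)."""
    h = 1e-4 * (1.0 + np.abs(eta))
    _, g_plus, _ = _joint_neg2(packed, eta + h, typcl, v, omega2, sp, sa)
    _, g_minus, _ = _joint_neg2(packed, eta - h, typcl, v, omega2, sp, sa)
    lpp = (g_plus - g_minus) / (2.0 * h)
    bad = ~np.isfinite(lpp) | (lpp <= 0)
    return np.where(bad, h_gn, lpp)


def foce_objective(packed, spec: PopulationModel,
                   eta0: Optional[np.ndarray] = None, return_etas: bool = False):
    """FOCE-I objective function value (-2 log approximate marginal
    likelihood) for the whole dataset.

    Accepts a :class:`PackedData` or a :class:`StudyDataset`.  In the
    degenerate omega^2 -> 0 limit the fixed-effects -2 log-likelihood at
    eta = 0 is returned (the analytic limit of the Laplace expression).
    """
    if isinstance(packed, StudyDataset):
        packed = PackedData.from_dataset(packed)
    omega2, sp, sa = spec.omega2_cl, spec.sigma_prop, spec.sigma_add
    typcl, v = subject_typicals(packed, spec)
    if omega2 < _OMEGA2_FLOOR:
        f, _ = _predict(packed, typcl, v)
        var = sp * sp * f * f + sa * sa
        if np.any(var < _VAR_FLOOR):
            raise EstimationError("zero residual variance at an observation")
        r = packed.y - f
        ofv = float(np.sum(np.log(var) + r * r / var + _LOG_2PI))
        eta = np.zeros(packed.n_subjects)
        return (ofv, eta) if return_etas else ofv
    eta, l_mode = conditional_modes(packed, spec, eta0=eta0)
    _, g, h_gn = _joint_neg2(packed, eta, typcl, v, omega2, sp, sa)
    lpp = _mode_curvature(packed, eta, typcl, v, omega2, sp, sa, h_gn)
    contrib = l_mode + np.log(lpp) - math.log(4.0 * math.pi)
    ofv = float(np.sum(contrib))
    return (ofv, eta) if return_etas else ofv


def agq_objective(dataset, spec: PopulationModel, n_nodes: int = 64) -> float:
    """Reference -2 log marginal likelihood by adaptive Gauss-Hermite
    quadrature (nodes centred and scaled at each subject's conditional mode).

    Intended as an accuracy oracle on small instances; cost grows linearly in
    subjects times nodes.
    """
    packed = (PackedData.from_dataset(dataset)
              if isinstance(dataset, StudyDataset) else dataset)
    omega2, sp, sa = spec.omega2_cl, spec.sigma_prop, spec.sigma_add
    typcl, v = subject_typicals(packed, spec)
    if omega2 < _OMEGA2_FLOOR:
        return foce_objective(packed, spec)
    eta, _ = conditional_modes(packed, spec)
    _, g, h_gn = _joint_neg2(packed, eta, typcl, v, omega2, sp, sa)
    lpp = _mode_curvature(packed, eta, typcl, v, omega2, sp, sa, h_gn)
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    logw = np.log(w)
    total = 0.0
    for si in range(packed.n_subjects):
        l_of = _subject_scalar_joint(packed, si, typcl[si], v[si], omega2, sp, sa)
        scale = 2.0 / math.sqrt(lpp[si])  # sqrt(2) * quadratic-approx SD
        nodes = eta[si] + scale * x
        l_vals = np.array([l_of(e) for e in nodes])
        log_terms = logw + x * x - 0.5 * l_vals
        m = log_terms.max()
        log_int = m + math.log(np.sum(np.exp(log_terms - m))) + math.log(scale)
        total += -2.0 * log_int
    return float(total)


def empirical_bayes_etas(dataset, spec: PopulationModel) -> pd.Series:
    """Conditional modes (empirical Bayes estimates) of eta_CL per subject."""
    packed = (PackedData.from_dataset(dataset)
              if isinstance(dataset, StudyDataset) else dataset)
    eta, _ = conditional_modes(packed, spec)
    return pd.Series(eta, index=pd.Index(packed.subject_ids, name="id"), name="eta_cl")


def eta_shrinkage(ebes, omega_sd: float) -> float:
    """Eta shrinkage in percent: 100 * (1 - SD(EBE)/omega), population (n)
    SD denominator.  Requires omega > 0 and at least two subjects."""
    ebes = np.asarray(ebes, float)
    if ebes.size < 2:
        raise ValueError("shrinkage needs at least two subjects")
    if not omega_sd > 0:
        raise ValueError("shrinkage undefined for omega = 0")
    return 100.0 * (1.0 - ebes.std(ddof=0) / omega_sd)


def compute_diagnostics(packed, spec: PopulationModel,
                        eta: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-observation PRED, IPRED and CWRES.

    PRED is the population prediction (eta = 0); IPRED the prediction at the
    empirical Bayes eta.  CWRES decorrelates the residual about the FOCE
    linearisation at the mode: with G = df/deta at eta_hat, the subject's
    marginal mean is f(eta_hat) - G*eta_hat and covariance
    diag(residual var at IPRED) + omega^2 * G G'; CWRES is the inverse
    matrix-square-root of that covariance applied to (y - mean).
    """
    if isinstance(packed, StudyDataset):
        packed = PackedData.from_dataset(packed)
    omega2, sp, sa = spec.omega2_cl, spec.sigma_prop, spec.sigma_add
    typcl, v = subject_typicals(packed, spec)
    pred, _ = _predict(packed, typcl, v)
    if eta is None:
        if omega2 < _OMEGA2_FLOOR:
            eta = np.zeros(packed.n_subjects)
        else:
            eta, _ = conditional_modes(packed, spec)
    cl_s = typcl * np.exp(eta)
    ipred, dfdcl = _predict(packed, cl_s, v)
    fp = dfdcl * cl_s[packed.obs_subj]
    var = sp * sp * ipred * ipred + sa * sa
    cwres = np.empty(packed.n_obs)
    for si in range(packed.n_subjects):
        mask = packed.obs_subj == si
        gi = fp[mask]
        mean_i = ipred[mask] - gi * eta[si]
        cov = np.diag(var[mask]) + omega2 * np.outer(gi, gi)
        evals, evecs = np.linalg.eigh(cov)
        if np.any(evals <= 0):
            raise EstimationError(f"singular residual covariance for subject "
                                  f"{packed.subject_ids[si]}")
        inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T
        cwres[mask] = inv_sqrt @ (packed.y[mask] - mean_i)
    return pd.DataFrame({
        "id": np.asarray(packed.subject_ids, object)[packed.obs_subj],
        "time": packed.t, "dv": packed.y,
        "pred": pred, "ipred": ipred, "cwres": cwres,
    })
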