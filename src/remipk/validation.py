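"""Model validation: nonparametric bootstrap and prediction-corrected VPC.

The bootstrap resamples subjects with replacement (to the original subject
count), refits the model on each replicate, and summarises the estimates by
their median and 2.5-97.5 percentile interval.  The prediction-corrected
visual predictive check (pcVPC) simulates replicate datasets on the original
design, normalises observed and simulated values by the bin-median population
prediction, and compares observed percentile curves with the simulated 95%
confidence bands of those percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import LLOQ, StudyDataset
from .foce import PackedData, subject_typicals, _predict
from .structural import PopulationModel

__all__ = ["BootstrapResult", "VPCResult", "bootstrap", "prediction_correct", "pcvpc"]


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Per-replicate estimates and percentile summaries of a bootstrap run."""

    replicates: pd.DataFrame      # one row per replicate incl. 'converged'
    summary: pd.DataFrame         # median, ci_lo, ci_hi per free parameter
    n_requested: int
    n_converged: int
    seed: int


def _resample(dataset: StudyDataset, rng: np.random.Generator) -> StudyDataset:
    idx = rng.integers(0, len(dataset), size=len(dataset))
    subjects = tuple(
        dc_replace(dataset.subjects[i], id=f"{dataset.subjects[i].id}~b{j}")
        for j, i in enumerate(idx))
    return StudyDataset(subjects=subjects, metadata="bootstrap replicate")


def bootstrap(dataset: StudyDataset, spec: PopulationModel,
              free: Optional[Sequence[str]] = None, n_reps: int = 200,
              seed: int = 0, inits: Optional[dict] = None,
              **fit_kwargs) -> BootstrapResult:
    """Nonparametric bootstrap of a model fit.

    Each replicate draws ``len(dataset)`` subjects with replacement and
    refits ``spec`` (free parameters ``free``) starting from ``inits``.
    Replicates whose optimiser does not converge are counted and excluded
    from the percentile summaries.  Fully reproducible given ``seed``.
    """
    from .model import PopPKModel

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    fit_kwargs.setdefault("compute_se", False)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_reps):
        ds = _resample(dataset, rng)
        row = {"converged": False}
        try:
            fit = PopPKModel(ds, spec, free=free).fit(inits=inits, **fit_kwargs)
            row.update(fit.params[fit.free].to_dict())
            row["ofv"] = fit.ofv
            row["converged"] = bool(fit.converged)
        except Exception as exc:
            row["error"] = str(exc)
        rows.append(row)
    reps = pd.DataFrame(rows)
    ok = reps[reps["converged"]]
    n_conv = int(len(ok))
    if n_conv == 0:
        raise RuntimeError("all bootstrap replicates failed to converge")
    param_cols = [c for c in reps.columns if c not in ("converged", "ofv", "error")]
    summary = pd.DataFrame({
        "median": ok[param_cols].quantile(0.5),
        "ci_lo": ok[param_cols].quantile(0.025),
        "ci_hi": ok[param_cols].quantile(0.975),
    })
    return BootstrapResult(replicates=reps, summary=summary,
                           n_requested=n_reps, n_converged=n_conv, seed=seed)


# ---------------------------------------------------------------------------
# Prediction-corrected VPC
# ---------------------------------------------------------------------------

def prediction_correct(values: np.ndarray, preds: np.ndarray,
                       bin_assignment: np.ndarray) -> np.ndarray:
    """Prediction-correct values: pcY_ij = Y_ij * median(PRED in bin) / PRED_ij.

    Observations with non-positive PRED are excluded (NaN) with a warning.
    """
    values = np.asarray(values, float)
    preds = np.asarray(preds, float)
    bins = np.asarray(bin_assignment)
    out = np.full(values.shape, np.nan)
    bad = ~(preds > 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} observations with non-positive PRED "
                      "excluded from prediction correction", RuntimeWarning)
    for b in np.unique(bins):
        mask = (bins == b) & ~bad
        if not mask.any():
            continue
        med = np.median(preds[mask])
        out[mask] = values[mask] * med / preds[mask]
    return out


@dataclass
class VPCResult:
    """pcVPC summary: observed percentile curves and simulated 95% bands."""

    table: pd.DataFrame           # bin, stat, observed, sim_lo, sim_hi
    bin_edges: list
    n_simulations: int
    seed: int

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells whose observed value lies
        inside the simulated band."""
        t = self.table.dropna(subset=["observed"])
        inside = (t["observed"] >= t["sim_lo"]) & (t["observed"] <= t["sim_hi"])
        return float(inside.mean())

    def plot(self, ax=None):
        """Observed percentile curves over the simulated confidence bands."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for stat, grp in self.table.groupby("stat"):
            ax.fill_between(grp["t_mid"], grp["sim_lo"], grp["sim_hi"], alpha=0.25)
            ax.plot(grp["t_mid"], grp["observed"], marker="o",
                    label=f"observed p{stat}")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("prediction-corrected concentration (ng/mL)")
        ax.legend()
        return ax


def _assign_bins(packed: PackedData, dataset: StudyDataset, bins):
    """Bin observations by time; ``bins`` is a sequence of edges, an integer
    (quantile bins), or None for the design windows [0,12], (12,30], (30,48]
    plus a post-discontinuation bin."""
    t = packed.t
    infusion_end = np.array([s.infusion_end for s in dataset.subjects])
    post = t > infusion_end[packed.obs_subj] + 1e-9
    if bins is None:
        edges = [0.0, 12.0, 30.0, 48.0]
    elif np.isscalar(bins):
        qs = np.linspace(0, 1, int(bins) + 1)
        edges = np.unique(np.quantile(t[~post], qs)).tolist()
    else:
        edges = list(bins)
    assignment = np.full(packed.n_obs, -1, np.intp)
    inner = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)
    assignment[~post] = inner[~post]
    assignment[post] = len(edges) - 1  # post-discontinuation bin
    return assignment, edges


def pcvpc(dataset: StudyDataset, spec: PopulationModel, n_sim: int = 1000,
          seed: int = 0, bins=None, percentiles=(2.5, 50.0, 97.5),
          lloq: float = LLOQ) -> VPCResult:
    """Prediction-corrected visual predictive check.

    Simulates ``n_sim`` replicates of the dataset on its own design (fresh
    etas and residuals), prediction-corrects observed and simulated values
    with the same population predictions, and returns, per time bin, the
    observed percentiles with 95% confidence bands of the simulated ones.
    Simulated values below the LLOQ are censored the same way observed BLQ
    values are (excluded).  Empty bins are dropped with a warning.
    """
    from .model import PopPKModel

    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    model = PopPKModel(dataset, spec)
    packed = model.packed
    typcl, v = subject_typicals(packed, spec)
    pred, _ = _predict(packed, typcl, v)
    assignment, edges = _assign_bins(packed, dataset, bins)
    pc_obs = prediction_correct(packed.y, pred, assignment)

    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, packed.n_obs))
    for i in range(n_sim):
        sims[i] = model.simulate_observations(rng, spec=spec)
    sims[sims < lloq] = np.nan
    pc_sims = np.empty_like(sims)
    for i in range(n_sim):
        pc_sims[i] = prediction_correct(sims[i], pred, assignment)

    rows = []
    for b in np.unique(assignment):
        mask = assignment == b
        obs_b = pc_obs[mask]
        obs_b = obs_b[np.isfinite(obs_b)]
        if obs_b.size == 0:
            warnings.warn(f"empty VPC bin {b}; dropped", RuntimeWarning)
            continue
        t_mid = float(np.median(packed.t[mask]))
        sim_b = pc_sims[:, mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sim_stats = np.nanpercentile(sim_b, percentiles, axis=1)  # (n_pct, n_sim)
        for pi, p in enumerate(percentiles):
            obs_stat = float(np.percentile(obs_b, p))
            band = sim_stats[pi][np.isfinite(sim_stats[pi])]
            lo, hi = (np.percentile(band, [2.5, 97.5]) if band.size
                      else (np.nan, np.nan))
            rows.append({"bin": int(b), "t_mid": t_mid, "stat": p,
                         "n_obs": int(obs_b.size), "observed": obs_stat,
                         "sim_lo": float(lo), "sim_hi": float(hi)})
    table = pd.DataFrame(rows)
    return VPCResult(table=table, bin_edges=edges, n_simulations=n_sim, seed=seed)
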