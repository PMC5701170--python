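"""Configuration files: model presets, tolerances, seeds, simulation grids.

A config file (YAML or JSON) may name a model preset or spell out parameter
values and covariate effects explicitly::

    model:
      preset: final_2017          # or tvcl/tvv/... plus effects
    fit:
      ftol: 1.0e-9
    seed: 1
    simulation:
      pump_speeds: [1700, 2000, 2300, 2600, 2900]
      rates: [0.84, 0.63, 0.42, 0.21, 0.105]
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .covariates import CovariateEffect
from .structural import PRESETS, PopulationModel

__all__ = ["load_config", "model_from_config", "model_to_config"]


def load_config(path) -> dict:
    """Load a YAML or JSON config file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def model_from_config(cfg: dict) -> PopulationModel:
    """Build a :class:`PopulationModel` from a config ``model`` section."""
    section = cfg.get("model", cfg)
    preset = section.get("preset")
    if preset is not None:
        try:
            model = PRESETS[preset]()
        except KeyError:
            raise KeyError(f"unknown model preset {preset!r}; "
                           f"available: {sorted(PRESETS)}") from None
        overrides = {k: v for k, v in section.items() if k != "preset"}
        return model.with_params(**overrides) if overrides else model
    effects = tuple(
        CovariateEffect(parameter=e["parameter"], covariate=e["covariate"],
                        form=e["form"], coef=float(e["coef"]),
                        center=e.get("center"),
                        categorical=bool(e.get("categorical", False)))
        for e in section.get("effects", []))
    return PopulationModel(
        tvcl=float(section["tvcl"]), tvv=float(section["tvv"]),
        omega2_cl=float(section.get("omega2_cl", 0.0)),
        sigma_prop=float(section.get("sigma_prop", 0.0)),
        sigma_add=float(section.get("sigma_add", 0.0)),
        effects=effects)


def model_to_config(model: PopulationModel) -> dict:
    """Serialise a model spec to a config-compatible dict."""
    return {
        "tvcl": model.tvcl, "tvv": model.tvv, "omega2_cl": model.omega2_cl,
        "sigma_prop": model.sigma_prop, "sigma_add": model.sigma_add,
        "effects": [
            {"parameter": e.parameter, "covariate": e.covariate, "form": e.form,
             "coef": e.coef, "center": e.center, "categorical": e.categorical}
            for e in model.effects],
    }
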