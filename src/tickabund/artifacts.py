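"""Posterior persistence: self-describing ``.npz`` archives.

A fitted :class:`~tickabund.inference.PosteriorResult` is stored as a numpy
archive holding the natural-scale draw arrays, the per-observation
log-likelihood matrix and the model specification (as JSON), so it round-trips
with numpy alone.  Loading requires the panel the model was fitted to, from
which the design matrices are rebuilt and verified against the archive.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .design import build_design
from .inference import ModelSpec, PosteriorResult
from .priors import PriorConfig

__all__ = ["save_posterior", "load_posterior"]

_FORMAT_VERSION = 1


def _spec_to_json(spec: ModelSpec) -> str:
    d = dataclasses.asdict(spec)
    if isinstance(spec.prior_set, PriorConfig):
        d["prior_set"] = {"__prior_config__":
                          {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                           for k, v in dataclasses.asdict(spec.prior_set).items()}}
    return json.dumps(d)


def _spec_from_json(text: str) -> ModelSpec:
    d = json.loads(text)
    ps = d.get("prior_set")
    if isinstance(ps, dict) and "__prior_config__" in ps:
        cfg = ps["__prior_config__"]
        cfg["sigma_scale"] = np.asarray(cfg["sigma_scale"], float)
        d["prior_set"] = PriorConfig(**cfg)
    return ModelSpec(**d)


def save_posterior(result: PosteriorResult, path) -> None:
    """Write a fitted posterior to ``path`` (numpy ``.npz`` archive)."""
    arrays = {f"derived_{k}": np.asarray(v)
              for k, v in result.derived.items()}
    conv = result.convergence
    np.savez_compressed(
        path,
        format_version=np.array(_FORMAT_VERSION),
        spec_json=np.array(_spec_to_json(result.spec)),
        param_names=np.array(result.param_names),
        hyper_map=result.hyper_map,
        x_map=result.x_map,
        loglik=result.loglik,
        ll_stage=result.ll_stage,
        ll_row=result.ll_row,
        loglik_plugin=result.loglik_plugin,
        convergence_params=np.array(list(conv.index)),
        convergence_rhat=conv["rhat"].to_numpy(),
        convergence_ess=conv["ess"].to_numpy(),
        converged=np.array(result.converged),
        optimizer_message=np.array(result.optimizer_message),
        weight_ess=np.array(result.weight_ess),
        **arrays,
    )


def load_posterior(path, panel: pd.DataFrame) -> PosteriorResult:
    """Rebuild a :class:`PosteriorResult` from an archive and its panel.

    ``panel`` must be the lag-attached panel the model was fitted to; the
    design is rebuilt from it and checked for shape consistency with the
    stored log-likelihood matrix.
    """
    with np.load(path, allow_pickle=False) as z:
        version = int(z["format_version"])
        if version != _FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported posterior format "
                             f"version {version}")
        spec = _spec_from_json(str(z["spec_json"]))
        derived = {k[len("derived_"):]: z[k]
                   for k in z.files if k.startswith("derived_")}
        design = build_design(panel)
        n_ll = int(sum(design.stage_mask(j).sum() for j in range(3)))
        if z["loglik"].shape[1] != n_ll:
            raise ValueError(
                f"{path}: panel has {n_ll} retained observation-stages but "
                f"the archive stores {z['loglik'].shape[1]}; this is not the "
                "panel the model was fitted to")
        convergence = pd.DataFrame({
            "parameter": z["convergence_params"],
            "rhat": z["convergence_rhat"],
            "ess": z["convergence_ess"],
        }).set_index("parameter")
        return PosteriorResult(
            spec=spec, design=design,
            param_names=[str(s) for s in z["param_names"]],
            hyper_map=z["hyper_map"], x_map=z["x_map"], derived=derived,
            loglik=z["loglik"], ll_stage=z["ll_stage"], ll_row=z["ll_row"],
            loglik_plugin=z["loglik_plugin"], convergence=convergence,
            converged=bool(z["converged"]),
            optimizer_message=str(z["optimizer_message"]),
            weight_ess=float(z["weight_ess"]))
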