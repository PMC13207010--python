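"""End-to-end pipeline: prepare -> (simulate) -> fit -> diagnose -> effects.

A YAML config names either a real visit-record CSV (``input``) or a
``simulate`` block, the families and prior set to fit, and which reports to
produce.  Every run writes an artifact directory containing the panel, the
posterior archives and summary tables, diagnostic CSVs with their figures,
and a JSON manifest recording the run id, config hash, seeds and package
version.  All figures are regenerable from the CSVs written next to them.
Reruns with the same config and seed reproduce the data-preparation outputs
exactly and the posterior summaries up to sampler determinism (the sampler
itself is seeded, so summaries are bit-reproducible on one platform).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .artifacts import save_posterior
from .descriptives import describe_counts
from .diagnostics import (compare_models, fit_criteria, pit_from_result,
                          posterior_predictive_monthly, zero_profile)
from .effects import (peak_ordering, seasonal_curves_from_result,
                      sensitivity_run, year_effect_series)
from .inference import ModelSpec, fit
from .panel import (DEFAULT_MIN_VISITS, aggregate_monthly, attach_lags,
                    filter_well_sampled, read_survey_csv, write_panel_csv)
from .synthetic import (GeneratorConfig, TrueParameters, default_truth,
                        simulate_panel)

__all__ = ["run_pipeline", "PipelineError", "generator_from_config"]

logger = logging.getLogger(__name__)

_FAMILIES = ("nb", "zinb")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@contextmanager
def _stage(name: str, timings: dict):
    logger.info("stage %s: start", name)
    t0 = time.perf_counter()
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        logger.exception("stage %s: failed", name)
        raise PipelineError(f"pipeline stage {name!r} failed: {exc}") from exc
    timings[name] = round(time.perf_counter() - t0, 3)
    logger.info("stage %s: done in %.1fs", name, timings[name])


def generator_from_config(block: dict, seed: int) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a ``simulate`` config block.

    Recognised keys: ``family, years, start_month, month_missing_prob,
    max_visits, habitats_per_location, seed`` and a ``truth`` sub-mapping of
    :class:`TrueParameters` field overrides.
    """
    block = dict(block or {})
    truth_over = block.pop("truth", {}) or {}
    base = dataclasses.asdict(default_truth())
    unknown = set(truth_over) - set(base)
    if unknown:
        raise ValueError(f"unknown truth fields in simulate config: "
                         f"{sorted(unknown)}")
    base.update(truth_over)
    truth = TrueParameters(**base)
    kwargs = {}
    for key in ("family", "years", "start_month", "month_missing_prob",
                "max_visits", "habitats_per_location"):
        if key in block:
            kwargs[key] = block.pop(key)
    if "years" in kwargs:
        kwargs["years"] = tuple(kwargs["years"])
    gen_seed = block.pop("seed", seed)
    if block:
        raise ValueError(f"unknown simulate config keys: {sorted(block)}")
    return GeneratorConfig(truth=truth, seed=gen_seed, **kwargs)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config_path, out_dir=None) -> Path:
    """Execute the full pipeline described by a YAML config file.

    Returns the artifact directory.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    config_path = Path(config_path)
    raw = config_path.read_bytes()
    config = yaml.safe_load(raw) or {}
    config_hash = hashlib.sha256(raw).hexdigest()[:12]
    seed = int(config.get("seed", 0))
    run_id = config.get("run_id") or f"run-{config_hash}-s{seed}"

    out = Path(out_dir or config.get("out_dir") or f"tickabund-{run_id}")
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s [" + run_id + "] %(message)s"))
    root = logging.getLogger("tickabund")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    timings: dict = {}
    artifacts: list = []

    def _write_csv(df: pd.DataFrame, name: str, **kwargs):
        path = out / name
        df.to_csv(path, **kwargs)
        artifacts.append(name)
        return path

    try:
        logger.info("run %s: config %s (sha256 %s), seed %d",
                    run_id, config_path, config_hash, seed)

        # ---- prepare / simulate ------------------------------------------
        if ("input" in config) == ("simulate" in config):
            raise PipelineError(
                "pipeline stage 'prepare' failed: config must name exactly "
                "one of 'input' (visit records CSV) or 'simulate'")
        latents = None
        with _stage("prepare", timings):
            if "input" in config:
                records = read_survey_csv(config["input"])
                panel = aggregate_monthly(records)
                min_visits = int(config.get("prepare", {})
                                 .get("min_visits", DEFAULT_MIN_VISITS))
                panel = filter_well_sampled(panel, min_visits=min_visits)
                if len(panel) == 0:
                    raise ValueError("no location passes the visit filter")
                panel = attach_lags(panel)
            else:
                gen = generator_from_config(config["simulate"], seed)
                panel, latents = simulate_panel(gen)
                with open(out / "latents.json", "w", encoding="utf-8") as fh:
                    json.dump(_jsonable(latents), fh, indent=1)
                artifacts.append("latents.json")
            write_panel_csv(panel, out / "panel.csv")
            artifacts.append("panel.csv")
            _write_csv(describe_counts(panel), "descriptives.csv")
            logger.info("panel: %d rows, %d locations", len(panel),
                        panel["location"].nunique())

        # ---- fit ----------------------------------------------------------
        fit_cfg = dict(config.get("fit", {}))
        families = fit_cfg.pop("families", ["nb"])
        bad = set(families) - set(_FAMILIES)
        if bad:
            raise PipelineError(f"pipeline stage 'fit' failed: unknown "
                                f"families {sorted(bad)}")
        results = {}
        with _stage("fit", timings):
            for family in families:
                spec = ModelSpec(family=family, seed=seed, **fit_cfg)
                res = fit(panel, spec)
                results[family] = res
                save_posterior(res, out / f"posterior_{family}.npz")
                artifacts.append(f"posterior_{family}.npz")
                _write_csv(res.summarize(), f"summary_{family}.csv")
                _write_csv(res.convergence, f"convergence_{family}.csv")
                logger.info("fit %s: converged=%s weight_ess=%.0f",
                            family, res.converged, res.weight_ess)

        # ---- diagnose -----------------------------------------------------
        if config.get("diagnose", True):
            from .plots import (plot_pit_hist, plot_ppc_monthly,
                                plot_zero_heatmaps)
            with _stage("diagnose", timings):
                criteria = {}
                for family, res in results.items():
                    crit = fit_criteria(res)
                    criteria[family] = crit
                    ppc = posterior_predictive_monthly(res, panel, seed=seed)
                    _write_csv(ppc, f"ppc_monthly_{family}.csv", index=False)
                    plot_ppc_monthly(ppc, out / f"ppc_monthly_{family}.png")
                    artifacts.append(f"ppc_monthly_{family}.png")
                    pit = pit_from_result(res, seed=seed + 1)
                    _write_csv(pd.DataFrame({"pit": pit.pit_values}),
                               f"pit_{family}.csv", index=False)
                    plot_pit_hist(pit, out / f"pit_{family}.png")
                    artifacts.append(f"pit_{family}.png")
                crit_df = pd.DataFrame(
                    {f: dataclasses.asdict(c) for f, c in criteria.items()})
                _write_csv(crit_df, "criteria.csv")
                prof = zero_profile(panel)
                _write_csv(prof.by_habitat, "zero_by_habitat.csv")
                _write_csv(prof.by_month, "zero_by_month.csv")
                plot_zero_heatmaps(prof, out / "zero_heatmaps.png")
                artifacts.append("zero_heatmaps.png")
                if set(families) >= {"nb", "zinb"}:
                    report = compare_models(criteria["nb"], criteria["zinb"])
                    _write_csv(report.to_frame(), "model_comparison.csv")
                    (out / "model_comparison_note.txt").write_text(
                        report.note + "\n", encoding="utf-8")
                    artifacts.append("model_comparison_note.txt")

        # ---- effects ------------------------------------------------------
        if config.get("effects", True):
            from .plots import plot_seasonal_curves, plot_year_effect
            with _stage("effects", timings):
                for family, res in results.items():
                    curves = seasonal_curves_from_result(res)
                    _write_csv(pd.concat([c.to_frame() for c in curves]),
                               f"seasonal_curves_{family}.csv", index=False)
                    plot_seasonal_curves(curves,
                                         out / f"seasonal_curves_{family}.png")
                    artifacts.append(f"seasonal_curves_{family}.png")
                    _write_csv(peak_ordering(curves).table,
                               f"peak_months_{family}.csv", index=False)
                    series = year_effect_series(res)
                    _write_csv(series, f"year_effect_{family}.csv",
                               index=False)
                    plot_year_effect(series, out / f"year_effect_{family}.png")
                    artifacts.append(f"year_effect_{family}.png")

        # ---- sensitivity --------------------------------------------------
        if config.get("sensitivity", False):
            with _stage("sensitivity", timings):
                family = families[0]
                spec = ModelSpec(family=family, seed=seed, **fit_cfg)
                table = sensitivity_run(panel, spec)
                _write_csv(table.table, f"sensitivity_{family}.csv")
                _write_csv(table.flags, f"sensitivity_flags_{family}.csv")
                for name, err in table.errors.items():
                    logger.warning("sensitivity: prior set %s failed: %s",
                                   name, err)

        manifest = {
            "run_id": run_id,
            "config_file": str(config_path),
            "config_sha256": config_hash,
            "seed": seed,
            "package_version": _pkg_version,
            "families": list(families),
            "n_panel_rows": int(len(panel)),
            "timings_s": timings,
            "artifacts": sorted(set(artifacts)),
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
        logger.info("run %s complete: %d artifacts", run_id,
                    len(manifest["artifacts"]))
        return out
    finally:
        root.removeHandler(handler)
        handler.close()
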