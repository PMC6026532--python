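"""End-to-end orchestration: data in, fitted suite + reports out.

A run proceeds: ingest (or simulate) the call and focal-day tables; compute
descriptive summaries; fit the acoustic model registry with full-vs-null
and per-predictor likelihood-ratio tests plus diagnostics; run the
within-individual permutation omnibus; fit the two exposure-offset rate
models; and emit CSV/JSON artifacts with a machine-readable manifest.  One
global seed fans out to fixed per-stage seeds, so any stage can be re-run
independently yet reproducibly, and a repeated run with the same
configuration writes byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import read_call_table, read_focal_table, summarize_observation
from .models import (
    dispersion_parameter,
    drop1_tests,
    fit_model,
    full_null_test,
    model_registry,
    model_table,
    sign_table,
    stability_check,
    vif_check,
)
from .omnibus import omnibus_test
from .rates import fit_rate_model, rate_drop1, rate_full_null_test, rate_registry
from .simulate import SimConfig, default_config, simulate_call_table, simulate_focal_days
from .study_tables import reconstructed_leafclip_log

logger = logging.getLogger("panthoot")

__all__ = ["RunConfig", "run_pipeline", "emit_report"]

#: A reduced registry for smoke runs: four Gaussian models, one per phase.
REDUCED_REGISTRY = (
    "total_duration_s",
    "intro_duration_s",
    "buildup_mid_call_f0_hz",
    "climax_duration_s",
)


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    calls_path: str | None = None
    focal_path: str | None = None
    calls_column_map: str | None = None
    focal_column_map: str | None = None
    simulate: bool = False
    sim_config: SimConfig | None = None
    registry: str | tuple = "full"  # "full", "reduced", or response names
    n_perm: int = 1000
    seed: int = 1
    run_omnibus: bool = True
    run_stability: bool = True
    outdir: str | None = None
    log_level: str = "INFO"

    def selected_specs(self) -> list:
        by_resp = {s.response: s for s in model_registry()}
        if self.registry == "full":
            return list(by_resp.values())
        names = REDUCED_REGISTRY if self.registry == "reduced" else self.registry
        return [by_resp[r] for r in names]

    def validate(self) -> None:
        if self.n_perm < 2:
            raise ValueError("n_perm must be >= 2")
        if not self.simulate and (self.calls_path is None or self.focal_path is None):
            raise ValueError("either set simulate=True or give both input paths")


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _config_hash(config: RunConfig) -> str:
    d = dataclasses.asdict(config)
    d.pop("outdir", None)  # where the report lands does not change results
    d.pop("log_level", None)
    if d.get("sim_config") is not None:
        d["sim_config"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in d["sim_config"].items()
        }
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report bundle as a dict.

    With ``config.outdir`` set the bundle is also written to disk via
    :func:`emit_report`.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    flags = []

    if config.simulate:
        sim = config.sim_config if config.sim_config is not None else default_config()
        calls = simulate_call_table(sim, seed=_stage_seed(config.seed, "calls"))
        days = simulate_focal_days(sim, seed=_stage_seed(config.seed, "days"))
        logger.info("simulated %d calls, %d focal days", len(calls), len(days))
    else:
        calls = read_call_table(config.calls_path, column_map=config.calls_column_map)
        days = read_focal_table(config.focal_path, column_map=config.focal_column_map)
        logger.info("read %d calls, %d focal days", len(calls), len(days))

    descriptives = summarize_observation(days, reconstructed_leafclip_log()).as_dict()

    specs = config.selected_specs()
    acoustic_rows, sign_rows, diagnostics = [], [], {"dispersion": {}, "vif": {}, "stability": {}}
    for spec in specs:
        full = fit_model(spec, calls, include_test_predictors=True)
        test = full_null_test(spec, calls)
        tests = drop1_tests(spec, calls, full=full)
        acoustic_rows.append((spec, full.n_obs, test))
        sign_rows.append((spec, full, tests))
        if not full.converged:
            flags.append(f"{spec.response}: full fit flagged ({full.fallback})")
        if spec.family != "gaussian":
            y = calls.loc[calls[spec.response].notna(), spec.response].to_numpy(float)
            diagnostics["dispersion"][spec.response] = dispersion_parameter(full, y)
        if config.run_stability:
            diagnostics["stability"][spec.response] = stability_check(
                spec, calls, full=full
            )
        logger.info(
            "%s: chisq=%.2f df=%d p=%.3g", spec.response, test.statistic, test.df, test.p_value
        )
    diagnostics["vif"] = vif_check(calls)

    omnibus = None
    if config.run_omnibus:
        result = omnibus_test(
            calls, specs, n_perm=config.n_perm, seed=_stage_seed(config.seed, "omnibus")
        )
        omnibus = result.summary()
        flags.extend(f"omnibus: {m}" for m in result.excluded_models)
        if result.n_fallback_p1:
            flags.append(
                f"omnibus: {result.n_fallback_p1} permutation fits failed; "
                "each contributed p=1"
            )
        logger.info("omnibus overall p = %.4g", result.overall_p)

    rate_results = {}
    for rspec in rate_registry():
        full = fit_rate_model(rspec, days)
        test = rate_full_null_test(rspec, days)
        tests = rate_drop1(rspec, days, full=full)
        if not full.converged:
            flags.append(f"rate {rspec.response}: fit flagged ({full.fallback})")
        rate_results[rspec.response] = {
            "n": full.n_obs,
            "coefficients": full.coefficients,
            "nb_theta": full.nb_theta,
            "full_null": dataclasses.asdict(test),
            "drop1": {p: dataclasses.asdict(t) for p, t in tests.items()},
        }

    bundle = {
        "descriptives": descriptives,
        "model_table": model_table(acoustic_rows),
        "sign_table": sign_table(sign_rows),
        "diagnostics": diagnostics,
        "omnibus": omnibus,
        "rates": rate_results,
        "manifest": {
            "package_version": __version__,
            "seed": config.seed,
            "n_perm": config.n_perm,
            "registry": list(s.response for s in specs),
            "config_hash": _config_hash(config),
            "soft_flags": flags,
        },
    }
    if config.outdir is not None:
        emit_report(bundle, config.outdir)
    return bundle


def emit_report(bundle: dict, outdir) -> list:
    """Write the report bundle (CSV for tables, JSON otherwise).

    Returns the list of written paths; column orders and number formats are
    stable so identical bundles produce identical files.
    """
    if not bundle:
        raise ValueError("empty report bundle")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def dump_json(name, obj):
        path = out / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")
        written.append(path)

    for name, key in (("model_table.csv", "model_table"), ("sign_table.csv", "sign_table")):
        df = bundle.get(key)
        if isinstance(df, pd.DataFrame):
            df.to_csv(out / name, index=False)
            written.append(out / name)
    for key in ("descriptives", "diagnostics", "omnibus", "rates", "manifest"):
        if bundle.get(key) is not None:
            dump_json(f"{key}.json", bundle[key])
    return written
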