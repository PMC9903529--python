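"""End-to-end pipeline: simulate/load -> exclusions -> descriptives ->
cross-lagged models -> mediation -> reallocation -> reports.

Every stage writes plain delimited text or JSON into the run directory,
and a manifest records the seed, configuration hash and package version
so any report is traceable to the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, coda
from .clpm import (
    ClpmConfig,
    build_model_frame,
    predict_reallocation,
    run_clpm,
    run_mediation,
)
from .cohort import apply_exclusions, validate_cohort
from .synthgen import GeneratorParams, generate_cohort, inject_missingness

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Exactly one input source: either ``cohort_path`` (delimited text) or
    simulation via ``n``/``seed``.
    """

    out_dir: str = "movecoda_run"
    cohort_path: str | None = None
    n: int = 231
    seed: int = 42
    min_valid_days: int = 1  # 3 reproduces the stricter sensitivity filter
    include_energy: bool = False
    mediation_pairs: tuple = (("ilr1", "fmi"), ("ilr1", "aerobic"))
    reallocation_max_delta: float = 30.0
    reallocation_step: float = 1.0
    exclusion_counts: tuple = (9, 12, 9)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def _descriptives(cohort: pd.DataFrame, out: Path) -> dict:
    summary = {}
    for wave in ("w1", "w2"):
        cols = [f"{p}_{wave}" for p in ("vpa", "mpa", "lpa", "sb", "sleep")]
        parts = coda.replace_zeros(cohort[cols].to_numpy(dtype=float))
        gm = coda.geometric_mean_composition(parts)
        vm = coda.variation_matrix(parts)
        tern = coda.ternary_coordinates(coda.amalgamate(parts))
        pd.DataFrame(vm, index=coda.PARTS, columns=coda.PARTS).to_csv(
            out / f"variation_matrix_{wave}.csv"
        )
        pd.DataFrame(tern, columns=["x", "y"]).to_csv(
            out / f"ternary_{wave}.csv", index=False
        )
        summary[wave] = {
            "geometric_mean_min_per_day": dict(zip(coda.PARTS, np.round(gm, 2)))
        }
    return summary


def _clpm_payload(result) -> dict:
    f = result.fitted
    payload = {
        "n": f.n,
        "chi2": f.chi2,
        "df": f.df,
        "p_value": f.p_value,
        "converged": f.converged,
        "estimates": f.estimates,
        "se": f.se,
        "standardized": f.standardized(),
        "p_values": f.p_values(),
    }
    if f.indices is not None:
        payload["fit_indices"] = {
            "cfi": f.indices.cfi,
            "rmsea": f.indices.rmsea,
            "rmsea_ci_90": list(f.indices.rmsea_ci),
            "srmr": f.indices.srmr,
            "scaled_chi2": f.indices.scaled_chi2,
            "scaling_factor": f.indices.scaling_factor,
        }
    return payload


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory.

    Stage failures raise with the failing stage named; outputs written
    before the failure are preserved for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if config.cohort_path is not None:
            cohort = pd.read_csv(config.cohort_path)
        else:
            cohort = generate_cohort(GeneratorParams(n=config.n, seed=config.seed))
            cohort = inject_missingness(
                cohort, counts=tuple(config.exclusion_counts), seed=config.seed
            )
            cohort.to_csv(out / "cohort.csv", index=False)
        validate_cohort(cohort)

        stage = "exclusions"
        analytical, report = apply_exclusions(cohort)
        if config.min_valid_days > 1:
            keep = (analytical["n_valid_days_w1"] >= config.min_valid_days) & (
                analytical["n_valid_days_w2"] >= config.min_valid_days
            )
            analytical = analytical.loc[keep]
        _write_json(
            out / "exclusion_report.json",
            {**report.to_dict(), "min_valid_days": config.min_valid_days,
             "analysed_n": len(analytical)},
        )

        stage = "descriptives"
        summary = _descriptives(analytical, out)
        _write_json(out / "descriptives.json", summary)

        stage = "cross-lagged models"
        frame = build_model_frame(analytical)
        clpm_results = {}
        for outcome_set in ("bodycomp", "fitness"):
            cfg = ClpmConfig(
                outcome_set=outcome_set, include_energy=config.include_energy
            )
            res = run_clpm(frame, cfg)
            clpm_results[outcome_set] = res
            _write_json(out / f"clpm_{outcome_set}.json", _clpm_payload(res))
            res.report.to_csv(out / f"clpm_{outcome_set}_paths.csv", index=False)

        stage = "mediation"
        mediations = {}
        for x, y in config.mediation_pairs:
            med = run_mediation(frame, x=x, y=y)
            mediations[(x, y)] = med
            _write_json(
                out / f"mediation_{x}_{y}.json",
                {
                    "x": med.x, "m": med.m, "y": med.y, "n": med.n,
                    "a": med.a, "b": med.b, "c_prime": med.c_prime,
                    "indirect": med.indirect, "total": med.total,
                    "se": med.se, "p": med.p, "standardized": med.standardized,
                },
            )

        stage = "reallocation"
        cols = [f"{p}_w1" for p in ("vpa", "mpa", "lpa", "sb", "sleep")]
        base = coda.geometric_mean_composition(
            coda.replace_zeros(analytical[cols].to_numpy(dtype=float))
        )
        deltas = np.arange(
            -config.reallocation_max_delta,
            config.reallocation_max_delta + config.reallocation_step / 2,
            config.reallocation_step,
        )
        deltas = deltas[deltas > -base[0] + 1e-9]  # keep VPA positive
        for (x, y), med in mediations.items():
            if x != "ilr1":
                continue
            for variant in ("total", "indirect"):
                curve = predict_reallocation(med, base, deltas, variant=variant)
                curve.to_frame().to_csv(
                    out / f"reallocation_{y}_{variant}.csv", index=False
                )

        stage = "manifest"
        _write_json(
            out / "manifest.json",
            {
                "package": "movecoda",
                "version": __version__,
                "seed": config.seed,
                "config": asdict(config),
                "config_hash": config.config_hash(),
            },
        )
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed during stage '{stage}': {exc}") from exc
    return out
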