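"""Configuration, orchestration and assembly of results tables.

A run configuration (YAML or dict) lists stages; each stage either loads
tabular inputs or generates them synthetically, runs the corresponding
analysis, and contributes rows to a single results table shaped like the
published kinetic/selectivity tables (variant, block, parameter, value,
uncertainty, display).  All randomness flows from explicit per-stage seeds
through one generator hierarchy; identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .errors import InvalidParameterError
from .indicator_assay import (
    AssayScenario,
    BufferSpec,
    IndicatorCalibration,
    quantify_timeseries,
    read_plate_csv,
    write_progress_csv,
)
from .halide_assay import halide_from_absorbance, read_standards_csv
from .kinetics import KineticDataset, fit_hill, fit_michaelis_menten
from .selectivity import e_from_c_eep, read_gc_csv
from .spm import build_spm_graph, dccm, mean_distance_matrix, read_ensemble_table, shortest_path_map, write_edge_csv
from .synthetic_data import (
    ResolutionTruth,
    TrueKinetics,
    simulate_rate_dataset,
    simulate_melt_curve,
    simulate_resolution_outcome,
)
from .thermal_shift import melting_temperature, read_melt_csv

__all__ = ["RunConfig", "ResultsTable", "run_pipeline", "load_config"]

RESULT_COLUMNS = ["variant", "block", "parameter", "value", "uncertainty", "display"]


@dataclass
class ResultsTable:
    """Long-format results keyed by (variant, block, parameter)."""

    rows: list[dict[str, Any]] = field(default_factory=list)

    def add(self, variant: str, block: str, parameter: str, value: float,
            uncertainty: float = float("nan"), display: str | None = None) -> None:
        key = (variant, block, parameter)
        if any((r["variant"], r["block"], r["parameter"]) == key for r in self.rows):
            raise InvalidParameterError(f"duplicate results key {key}")
        self.rows.append(
            {
                "variant": variant, "block": block, "parameter": parameter,
                "value": value, "uncertainty": uncertainty,
                "display": display if display is not None else f"{value:.3g}",
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=RESULT_COLUMNS)


@dataclass
class RunConfig:
    """Validated run configuration: a list of stage dicts plus bookkeeping."""

    stages: list[dict[str, Any]]
    output_dir: Path | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        if not isinstance(raw.get("stages", []), list):
            raise InvalidParameterError("config 'stages' must be a list")
        stages = raw.get("stages", [])
        for k, stage in enumerate(stages):
            if "kind" not in stage:
                raise InvalidParameterError(f"stage {k} missing 'kind'")
            for key in ("plate", "gc_table", "melt", "ensemble", "standards"):
                if key in stage and not Path(stage[key]).exists():
                    raise InvalidParameterError(
                        f"stage {k} ({stage['kind']}): input file {stage[key]!r} not found"
                    )
        out = raw.get("output_dir")
        return cls(
            stages=stages,
            output_dir=Path(out) if out else None,
            seed=int(raw.get("seed", 0)),
        )


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _scenario_from_block(block: dict[str, Any]) -> AssayScenario:
    buf = block.get("buffer", {})
    cal = block.get("calibration", {})
    return AssayScenario(
        buffer=BufferSpec(**buf) if buf else BufferSpec(total_conc=1.0),
        calibration=IndicatorCalibration(**cal) if cal else IndicatorCalibration(),
        substrate0=block.get("substrate0", 10.0),
        enzyme_loading=block.get("enzyme_loading", 0.05),
        dilution_factor=block.get("dilution_factor", 2.0),
    )


def _stage_seed(config: RunConfig, stage: dict[str, Any], index: int) -> int:
    return int(stage.get("seed", config.seed + index))


def _run_stage(stage: dict[str, Any], seed: int, table: ResultsTable,
               outdir: Path | None) -> None:
    kind = stage["kind"]
    variant = str(stage.get("variant", stage.get("label", "sample")))
    if kind == "resolution":
        if "gc_table" in stage:
            observations = read_gc_csv(stage["gc_table"])
        else:
            truth = ResolutionTruth(
                e_true=float(stage["e_true"]),
                target_conversion=float(stage["conversion"]),
                preferred_enantiomer=stage.get("preferred", "S"),
            )
            obs = simulate_resolution_outcome(truth)
            observations = [obs]
        for o in observations:
            res = e_from_c_eep(o.conversion, o.ee_p)
            label = o.label if o.label not in ("", "synthetic") else variant
            table.add(label, stage.get("block", "resolution"), "E", res.e_value,
                      display=f"{res.display} ({o.preferred_enantiomer})")
            table.add(label, stage.get("block", "resolution"), "conversion", o.conversion)
    elif kind == "kinetics":
        model = stage.get("model", "hill")
        if "dataset" in stage:
            ds_block = stage["dataset"]
            dataset = KineticDataset(s=ds_block["s"], rate=ds_block["rate"],
                                     sd=ds_block.get("sd"))
        else:
            truth = TrueKinetics(
                model="hill" if model == "hill" else "michaelis_menten",
                vmax_equivalent=float(stage["vmax"]),
                half_saturation=float(stage["half_saturation"]),
                hill_n=float(stage.get("hill_n", 1.0)),
            )
            dataset = simulate_rate_dataset(
                truth, stage["concentrations"],
                n_replicates=int(stage.get("replicates", 2)),
                cv=float(stage.get("cv", 0.02)), seed=seed,
            )
        block = stage.get("block", "kinetics")
        if model == "hill":
            fit = fit_hill(dataset)
            table.add(variant, block, "kobs_max", fit.kobs_max, fit.se_kobs_max)
            table.add(variant, block, "K50", fit.k50, fit.se_k50)
            table.add(variant, block, "n_H", fit.n_h, fit.se_n_h)
            table.add(variant, block, "efficiency", fit.efficiency, fit.se_efficiency)
        else:
            fit = fit_michaelis_menten(dataset)
            table.add(variant, block, "kcat", fit.kcat, fit.se_kcat)
            table.add(variant, block, "KM", fit.km, fit.se_km)
            table.add(variant, block, "efficiency", fit.efficiency, fit.se_efficiency)
    elif kind == "quantify":
        scenario = _scenario_from_block(stage)
        wells = read_plate_csv(stage["plate"])
        curves = [quantify_timeseries(w, scenario) for w in wells]
        if outdir is not None:
            write_progress_csv(outdir / f"{variant}_progress.csv", curves)
        for c in curves:
            table.add(f"{variant}:{c.label}", "assay", "final_product_mM",
                      float(c.product[-1]))
    elif kind == "halide":
        curve = read_standards_csv(stage["standards"])
        table.add(variant, "halide", "slope", curve.slope)
        table.add(variant, "halide", "intercept", curve.intercept)
        table.add(variant, "halide", "r_squared", curve.r_squared)
        reads = pd.read_csv(stage["plate"])
        for _, row in reads.iterrows():
            conc = halide_from_absorbance(float(row["A460"]), curve)
            table.add(f"{variant}:{row['sample']}:{row['time_s']}", "halide",
                      "halide_mM", conc)
    elif kind == "melt":
        if "melt" in stage:
            curves = read_melt_csv(stage["melt"])
        else:
            import numpy as np

            curves = [
                simulate_melt_curve(
                    tm=float(stage["tm"]), steepness=float(stage.get("steepness", 1.0)),
                    plateaus=tuple(stage.get("plateaus", (0.0, 1.0))),
                    t_grid=np.arange(*stage.get("t_range", (10.0, 90.0, 0.5))),
                    noise_sd=float(stage.get("noise_sd", 0.0)), seed=seed, label=variant,
                )
            ]
        for c in curves:
            res = melting_temperature(c)
            table.add(c.label or variant, "thermal", "Tm_C", res.tm)
    elif kind == "spm":
        ensemble = read_ensemble_table(stage["ensemble"])
        graph = build_spm_graph(
            mean_distance_matrix(ensemble), dccm(ensemble),
            residue_labels=ensemble.residue_labels,
            distance_cutoff=float(stage.get("distance_cutoff", 6.0)),
            min_abs_corr=float(stage.get("min_abs_corr", 0.01)),
        )
        mapped = shortest_path_map(graph, usage_quantile=float(stage.get("usage_quantile", 0.8)))
        if outdir is not None:
            write_edge_csv(outdir / f"{variant}_spm_edges.csv", mapped)
        table.add(variant, "spm", "n_edges", mapped.graph.number_of_edges())
        table.add(variant, "spm", "n_map_edges", len(mapped.map_edges))
    else:
        raise InvalidParameterError(f"unknown stage kind {kind!r}")


def run_pipeline(config: RunConfig) -> ResultsTable:
    """Execute the configured stage chain and assemble the results table.

    Writes per-stage CSV outputs plus a machine-readable run log (inputs,
    seeds, version) when an output directory is configured.  Partial outputs
    are removed if a stage fails.
    """
    table = ResultsTable()
    outdir = config.output_dir
    written: list[Path] = []
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    log: dict[str, Any] = {"version": __version__, "seed": config.seed, "stages": []}
    try:
        for k, stage in enumerate(config.stages):
            seed = _stage_seed(config, stage, k)
            before = set(outdir.iterdir()) if outdir is not None else set()
            try:
                _run_stage(stage, seed, table, outdir)
            except Exception as exc:
                raise type(exc)(f"stage {k} ({stage['kind']}): {exc}") from exc
            if outdir is not None:
                written.extend(set(outdir.iterdir()) - before)
            log["stages"].append({"index": k, "kind": stage["kind"], "seed": seed,
                                  "params": {x: str(v) for x, v in stage.items()}})
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    if outdir is not None:
        table.to_frame().to_csv(outdir / "results.csv", index=False)
        with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=2)
    return table
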