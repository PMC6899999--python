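"""End-to-end orchestration: simulate -> analyse -> summarise -> compare.

A :class:`PipelineConfig` names a panel of motor variants (defaulting to
the published rkin430/MCAK panel), imaging conditions and analysis/stats
options. :func:`run_pipeline` simulates a dataset per variant, measures
every kymograph, summarises end residence per variant, and compares each
variant against the reference by two-sample KS and fold change. The
result is a machine-readable JSON report (validated against the schema
shipped with the package) plus per-variant CSVs. A fixed master seed
reproduces the report bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import benchmark, residence_stats
from .io import write_events_csv
from .kymo_analysis import AnalysisConfig, analyse_kymograph
from .params import DEFAULT_PANEL, ImagingParams, MotorParams
from .simulate import generate_dataset

logger = logging.getLogger("kymodwell")


class SchemaError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


@dataclass
class StatsConfig:
    reference: str = "WT"
    bootstrap_resamples: int = 10_000
    bootstrap_seed: int = 12345


@dataclass
class PipelineConfig:
    panel: dict[str, MotorParams] = field(
        default_factory=lambda: dict(DEFAULT_PANEL)
    )
    imaging: ImagingParams = field(default_factory=ImagingParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    n_microtubules: int = 8
    mt_length_range: tuple[float, float] = (4.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.panel) == 0:
            raise ValueError("panel must contain at least one variant")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a pipeline config from a YAML file.

    Recognised blocks: ``panel`` (mapping of variant name to MotorParams
    fields; a variant given as ``null``/``default`` pulls the built-in
    panel entry), ``imaging``, ``analysis``, ``stats``, ``dataset``
    (n_microtubules, mt_length_range) and ``seed``. A ``motor`` block is
    accepted as a single-variant panel.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    panel_block = raw.get("panel")
    if panel_block is None and "motor" in raw:
        m = dict(raw["motor"])
        panel_block = {m.get("name", "motor"): m}
    if panel_block is not None:
        panel = {}
        for name, fields_ in panel_block.items():
            if fields_ in (None, "default"):
                panel[name] = DEFAULT_PANEL[name]
            else:
                fields_ = dict(fields_)
                fields_.setdefault("name", name)
                panel[name] = MotorParams(**fields_)
        kwargs["panel"] = panel
    if "imaging" in raw:
        kwargs["imaging"] = ImagingParams(**raw["imaging"])
    if "analysis" in raw:
        kwargs["analysis"] = AnalysisConfig(**raw["analysis"])
    if "stats" in raw:
        kwargs["stats"] = StatsConfig(**raw["stats"])
    ds = raw.get("dataset", {})
    if "n_microtubules" in ds:
        kwargs["n_microtubules"] = int(ds["n_microtubules"])
    if "mt_length_range" in ds:
        kwargs["mt_length_range"] = tuple(ds["mt_length_range"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return PipelineConfig(**kwargs)


def _finite_or_none(x: Optional[float]) -> Optional[float]:
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return None
    return float(x)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full panel pipeline and write report + CSVs to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    variant_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(config.panel, master.spawn(len(config.panel)))
    }

    datasets: dict[str, residence_stats.ResidenceDataset] = {}
    report_variants: dict[str, dict] = {}
    velocities_by_variant: dict[str, float] = {}

    for name, motor in config.panel.items():
        t0 = time.perf_counter()
        try:
            ds = generate_dataset(
                motor,
                config.imaging,
                config.n_microtubules,
                seed=variant_seeds[name],
                out_dir=out_dir / name,
                mt_length_range=config.mt_length_range,
            )
            results = [analyse_kymograph(k, config.analysis) for k in ds.kymographs]
        except Exception as exc:  # noqa: BLE001 - stage-named diagnostics
            raise PipelineError(f"stage simulate/analyse [{name}]: {exc}") from exc
        write_events_csv(out_dir / name / "events.csv", [r.traces for r in results])

        durations, counts = benchmark.collect_end_residences(results, ds.microtubules)
        velocities = benchmark.collect_velocities(results)
        runs = benchmark.collect_run_lengths(results)
        n_events = sum(len(r.traces) for r in results)
        entry: dict = {
            "n_microtubules": config.n_microtubules,
            "n_events": int(n_events),
            "n_end_events": int(durations.size),
            "end_residence_mean_s": None,
            "end_residence_sem_s": None,
            "end_residence_corrected_mean_s": None,
            "velocity_mean_nm_s": _finite_or_none(
                velocities.mean() if velocities.size else None
            ),
            "run_length_mean_um": _finite_or_none(
                runs.mean() if runs.size else None
            ),
        }
        if durations.size:
            summary = residence_stats.summarize(
                durations, name, config.imaging.frame_interval
            )
            datasets[name] = summary
            entry["end_residence_mean_s"] = summary.mean
            entry["end_residence_sem_s"] = summary.sem
            entry["end_residence_corrected_mean_s"] = (
                residence_stats.dwell_mean_from_frame_counts(
                    counts, config.imaging.frame_interval
                )
            )
            summary.histogram().to_csv(
                out_dir / name / "end_residence_hist.csv", index=False
            )
        if entry["velocity_mean_nm_s"] is not None:
            velocities_by_variant[name] = entry["velocity_mean_nm_s"]
        report_variants[name] = entry
        logger.info(
            "variant %s: %d events (%d at end) in %.2fs",
            name, n_events, durations.size, time.perf_counter() - t0,
        )

    reference = config.stats.reference if config.stats.reference in datasets else None
    comparisons = []
    if reference is not None:
        ref_ds = datasets[reference]
        for name, ds in datasets.items():
            if name == reference:
                continue
            ks = residence_stats.ks_two_sample(ds.durations, ref_ds.durations)
            fc = residence_stats.fold_change(
                ds, ref_ds,
                n_boot=config.stats.bootstrap_resamples,
                seed=config.stats.bootstrap_seed,
            )
            comparisons.append(
                {
                    "variant": name,
                    "reference": reference,
                    "ks_D": ks.D,
                    "ks_p_value": ks.p_value,
                    "fold_change": fc.ratio,
                    "fold_change_ci_low": fc.ci_low,
                    "fold_change_ci_high": fc.ci_high,
                }
            )

    correlation = None
    shared = [
        n for n in datasets
        if n in velocities_by_variant and report_variants[n]["end_residence_mean_s"]
    ]
    if len(shared) >= 3:
        rep = residence_stats.correlation_report(
            [velocities_by_variant[n] for n in shared],
            [report_variants[n]["end_residence_mean_s"] for n in shared],
            labels=shared,
        )
        correlation = {
            "r": _finite_or_none(rep.r),
            "p_value": _finite_or_none(rep.p_value),
            "n": rep.n,
        }

    report = {
        "seed": config.seed,
        "reference": config.stats.reference,
        "variants": report_variants,
        "comparisons": comparisons,
        "correlation_velocity_vs_end_residence": correlation,
    }
    validate_report(report)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    if comparisons:
        import pandas as pd

        pd.DataFrame(comparisons).to_csv(out_dir / "comparisons.csv", index=False)
    return report


# -- minimal JSON-schema validation (subset: type/required/properties/
#    additionalProperties/items/enum) for the shipped report schema -------

def load_report_schema() -> dict:
    text = (
        resources.files("kymodwell").joinpath("schema/report.schema.json").read_text()
    )
    return json.loads(text)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "null": type(None),
}


def _check_type(value, expected: str) -> bool:
    if expected == "number":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if expected == "integer":
        return isinstance(value, int) and not isinstance(value, bool)
    return isinstance(value, _TYPES[expected])


def _validate(value, schema: dict, path: str) -> None:
    types = schema.get("type")
    if types is not None:
        if isinstance(types, str):
            types = [types]
        if not any(_check_type(value, t) for t in types):
            raise SchemaError(f"{path}: expected type {types}, got {type(value).__name__}")
    if "enum" in schema and value not in schema["enum"]:
        raise SchemaError(f"{path}: {value!r} not in enum {schema['enum']}")
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                raise SchemaError(f"{path}: missing required key {key!r}")
        props = schema.get("properties", {})
        for key, sub in props.items():
            if key in value:
                _validate(value[key], sub, f"{path}.{key}")
        extra = schema.get("additionalProperties")
        if isinstance(extra, dict):
            for key, v in value.items():
                if key not in props:
                    _validate(v, extra, f"{path}.{key}")
    if isinstance(value, list) and "items" in schema:
        for i, v in enumerate(value):
            _validate(v, schema["items"], f"{path}[{i}]")


def validate_report(report: dict, schema: Optional[dict] = None) -> None:
    """Raise :class:`SchemaError` unless the report matches the schema."""
    if schema is None:
        schema = load_report_schema()
    # nullable top-level correlation: handled by its own type union
    _validate(report, schema, "$")
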