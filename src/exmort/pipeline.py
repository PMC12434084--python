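"""End-to-end three-phase pipeline.

Phase I fits and forecasts the per-cause seasonal model; phase II combines
observed and forecast panels into the binary exceedance matrix and
estimates the per-cause binomial parameters; phase III answers probability
queries (single, joint, sums of causes) and produces the validation report.

Every run writes its artifacts plus a manifest recording the configuration
hash, the seed and a digest of each output file, so a rerun with an
identical configuration is byte-identical and verifiably so.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import exceedance, forecasting, probability, simulate, sumdist, validation
from .errors import ConfigError, EventError, ExmortError, PipelineStageError
from .panel import read_panel, write_panel

log = logging.getLogger("exmort.pipeline")


@dataclass
class PipelineConfig:
    """Structured configuration of one pipeline run.

    Exactly one input source: ``input_csv`` (wide weekly-count CSV) or
    ``simulation`` (keyword arguments of :class:`simulate.SimulationConfig`).
    """

    output_dir: str = "exmort_out"
    input_csv: str | None = None
    simulation: dict | None = None
    column_mapping: dict | None = None
    forecast: dict = field(default_factory=dict)
    include_boundary: bool = False
    probability_queries: list = field(default_factory=list)
    probability_rounding: str = "none"
    sum_queries: list = field(default_factory=list)
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise ConfigError(
                "exactly one input source required: input_csv or simulation"
            )

    def canonical(self) -> str:
        """Deterministic JSON form used for the manifest hash."""
        d = {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}
        return json.dumps(d, sort_keys=True, default=str)


def parse_components(text: str) -> list[probability.BinomialSpec]:
    """Parse ``n1:p1,n2:p2,...`` with an optional repeat suffix ``xR``.

    ``"50:0.5x5"`` means five independent binomial(50, 0.5) components.
    """
    comps = []
    for part in text.split(","):
        part = part.strip()
        m = re.match(r"^(\d+):([0-9.eE+-]+)(?:x(\d+))?$", part)
        if not m:
            raise EventError(f"cannot parse component spec {part!r}")
        n, p, rep = int(m.group(1)), float(m.group(2)), int(m.group(3) or 1)
        comps.extend([probability.BinomialSpec(n, p)] * rep)
    if not comps:
        raise EventError("empty component list")
    return comps


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, code: str = "stage_failure"):
    """Decorator-free stage wrapper: re-raise package errors with stage info."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, ExmortError):
                raise PipelineStageError(name, code, str(exc)) from exc
            log.info("stage %s: done (%.3fs)", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return a structured summary.

    Artifacts written to ``output_dir``: combined_panel.csv,
    exceedance_matrix.csv, estimates.csv, independence.json,
    probabilities.csv, sums.csv, validation.json, validation_table.csv and
    manifest.json.
    """
    logging.basicConfig(level=getattr(logging, str(config.verbosity).upper(), 20))
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("load", "load_failure"):
        if config.simulation is not None:
            sim_kwargs = dict(config.simulation)
            sim_kwargs.setdefault("seed", config.seed)
            sim = simulate.SimulationConfig(**sim_kwargs)
            observed = simulate.generate_panel(sim)
        else:
            observed = read_panel(config.input_csv, column_mapping=config.column_mapping)

    with _stage("forecast", "forecast_failure"):
        fc_config = forecasting.ForecastConfig(**config.forecast)
        model = forecasting.fit_forecaster(observed, fc_config)
        forecast_panel = model.forecast()
        correlations = forecasting.fitted_correlations(observed, model)

    with _stage("exceedance", "exceedance_failure"):
        combined = exceedance.combine(observed, forecast_panel)
        write_panel(combined, outdir / "combined_panel.csv", include_segment=True)
        matrix = exceedance.build_matrix(combined)
        matrix.to_frame().to_csv(outdir / "exceedance_matrix.csv", index=False)
        estimates = exceedance.estimate_wcmi(matrix)
        exceedance.estimates_frame(estimates).to_csv(
            outdir / "estimates.csv", index=False
        )
        indep = exceedance.independence_test(matrix)
        with open(outdir / "independence.json", "w") as fh:
            json.dump(
                {
                    "chi2": indep.chi2,
                    "df": indep.df,
                    "p_value": indep.p_value,
                    "cramers_v": indep.cramers_v,
                },
                fh,
                indent=2,
            )
            fh.write("\n")

    with _stage("probability", "probability_failure"):
        specs = {
            e.cause: probability.BinomialSpec(e.n, e.p_hat) for e in estimates
        }
        results = probability.evaluate_queries(
            config.probability_queries, specs, rounding=config.probability_rounding
        )
        with open(outdir / "probabilities.csv", "w") as fh:
            fh.write("query,probability\n")
            for q, p in results:
                fh.write(f'"{q}",{p!r}\n')

    with _stage("sumdist", "sumdist_failure"):
        sum_rows = []
        for spec in config.sum_queries:
            comps = parse_components(spec["components"])
            label, event = probability.parse_event(spec["event"])
            p = sumdist.sum_event_probability(
                comps, event, method=spec.get("method", "auto")
            )
            sum_rows.append((spec["components"], event.describe(label), p))
        with open(outdir / "sums.csv", "w") as fh:
            fh.write("components,event,probability\n")
            for comps_text, ev_text, p in sum_rows:
                fh.write(f'"{comps_text}","{ev_text}",{p!r}\n')

    with _stage("validate", "validation_failure"):
        report = validation.validate_windows(
            matrix,
            include_boundary=config.include_boundary,
            correlations=correlations,
        )
        report.to_json(outdir / "validation.json")
        report.to_csv(outdir / "validation_table.csv")

    with _stage("manifest", "manifest_failure"):
        artifacts = sorted(
            p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
            "seed": config.seed,
            "artifacts": {name: _sha256(outdir / name) for name in artifacts},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return {
        "n_weeks_observed": observed.n_weeks,
        "n_weeks_forecast": forecast_panel.n_weeks,
        "n_pairs": matrix.n,
        "estimates": {e.cause: e.p_hat for e in estimates},
        "independence": {
            "chi2": indep.chi2,
            "df": indep.df,
            "p_value": indep.p_value,
            "cramers_v": indep.cramers_v,
        },
        "probabilities": dict(results),
        "sums": {f"{c} {e}": p for c, e, p in sum_rows},
        "validation": report.to_dict(),
        "manifest": manifest,
        "output_dir": str(outdir),
    }
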