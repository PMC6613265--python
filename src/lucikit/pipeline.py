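"""Reproducible multi-stage pipeline: generate -> fit-decay -> calibrate -> rhythm.

A :class:`RunConfig` (usually loaded from YAML) selects stages and
parameters; :func:`run_pipeline` executes them into an artifact directory
and writes a ``manifest.txt`` with the config echo, seed, package version
and a SHA-256 checksum per output file.  All randomness derives from the
single config seed, and floats are serialised at full precision, so the
same config always produces byte-identical outputs and checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .calibration import fit_calibration, linearity_report, matrix_inhibition
from .decay import fit_first_order_decay
from .io import read_traces, write_traces
from .noise import NoiseModel
from .reporter import ReporterParams
from .rhythm import DEFAULT_PERIOD_BOUNDS, estimate_rhythm
from .synth import WellDesign, generate_decay_series, generate_dilution_series, generate_plate_experiment

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

STAGES = ("generate", "fit-decay", "calibrate", "rhythm")

_DEFAULT_DESIGN = (
    {"reporter": "NL", "genotype": "BOA-NL", "replicate": 1},
    {"reporter": "NL", "genotype": "BOA-NL", "replicate": 2},
    {"reporter": "FLUC", "genotype": "BOA-FLUC", "replicate": 1},
    {"reporter": "FLUC", "genotype": "BOA-FLUC", "replicate": 2},
)


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Unknown keys anywhere in the config mapping are rejected, so a typo in
    a parameter name fails loudly instead of silently using a default.
    """

    seed: int
    stages: tuple[str, ...] = STAGES
    model: dict[str, float] = field(default_factory=dict)
    noise: dict[str, float] = field(default_factory=dict)
    design: tuple[dict[str, Any], ...] = _DEFAULT_DESIGN
    duration_h: float = 72.0
    sampling_interval_h: float = 0.5
    decay: dict[str, float] = field(default_factory=lambda: {"half_life_days": 37.2, "span_days": 28, "interval_days": 1})
    dilution: dict[str, float] = field(default_factory=lambda: {"top_concentration": 0.1, "fold": 10, "n_steps": 6, "inhibition": 0.9})
    period_bounds: tuple[float, float] = DEFAULT_PERIOD_BOUNDS

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}; valid stages: {', '.join(STAGES)}")

    def reporter_params(self) -> ReporterParams:
        return ReporterParams(**self.model)

    def noise_model(self) -> NoiseModel | None:
        return NoiseModel(**self.noise) if self.noise else None


_ALLOWED_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML pipeline config."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    if "design" in raw:
        raw["design"] = tuple(raw["design"])
    if "period_bounds" in raw:
        raw["period_bounds"] = tuple(raw["period_bounds"])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dump_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the configured stages into ``outdir``; returns the directory.

    Each stage logs its timing to the module logger.  On failure, files
    written by the failing run are removed so no partial artifact directory
    is left behind.  A stage that needs an input produced by an earlier,
    unselected stage raises an error naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            written.extend(_run_stage(stage, config, outdir))
            logger.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
        manifest = outdir / "manifest.txt"
        lines = [
            f"lucikit {__version__}",
            f"seed: {config.seed}",
            f"stages: {', '.join(config.stages)}",
            "config: " + json.dumps(dataclasses.asdict(config), sort_keys=True),
            "outputs:",
        ]
        for p in sorted(set(written)):
            lines.append(f"  {p.name}  sha256:{_sha256(p)}")
        manifest.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return outdir


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: missing input {path.name} (produced by stage {produced_by!r})"
        )
    return path


def _run_stage(stage: str, config: RunConfig, outdir: Path) -> list[Path]:
    if stage == "generate":
        return _stage_generate(config, outdir)
    if stage == "fit-decay":
        series_path = _require(outdir / "decay_series.csv", stage, "generate")
        df = _read_two_col(series_path)
        fit = fit_first_order_decay(df)
        out = outdir / "decay_fit.json"
        _dump_json(dataclasses.asdict(fit) | {"converged": True, "half_life_days": fit.half_life_h / 24.0}, out)
        return [out]
    if stage == "calibrate":
        rec: dict[str, Any] = {"converged": True}
        curves = {}
        series = {}
        for label in ("buffer", "extract"):
            p = _require(outdir / f"dilution_{label}.csv", stage, "generate")
            s = _read_dilution(p, label)
            series[label] = s
            curves[label] = dataclasses.asdict(fit_calibration(s))
        rec["curves"] = curves
        rec["matrix_inhibition"] = matrix_inhibition(series["extract"], series["buffer"])
        rep = linearity_report(series["buffer"])
        rec["max_linearity_deviation"] = float(np.nanmax(rep["deviation"].to_numpy()))
        out = outdir / "calibration.json"
        _dump_json(rec, out)
        return [out]
    if stage == "rhythm":
        traces_path = _require(outdir / "traces.csv", stage, "generate")
        exp = read_traces(traces_path)
        rows = []
        for w in exp.wells:
            fit = estimate_rhythm(w.times_h, w.signal_cps, config.period_bounds)
            rows.append(
                {
                    "well": w.well,
                    "reporter": w.reporter,
                    "genotype": w.genotype,
                    "replicate": w.replicate,
                    **dataclasses.asdict(fit),
                }
            )
        out = outdir / "rhythm_fits.json"
        _dump_json(rows, out)
        return [out]
    raise ValueError(f"unknown stage {stage!r}")


def _stage_generate(config: RunConfig, outdir: Path) -> list[Path]:
    params = config.reporter_params()
    noise = config.noise_model()
    # independent, seed-derived streams per generated artifact
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(config.seed).spawn(4)]

    design = [WellDesign(**d) for d in config.design]
    exp = generate_plate_experiment(
        params,
        design,
        duration_h=config.duration_h,
        sampling_interval_h=config.sampling_interval_h,
        noise=noise,
        seed=seeds[0],
    )
    p_traces = write_traces(exp, outdir / "traces.csv")

    d = config.decay
    rate = float(np.log(2) / (d["half_life_days"] * 24.0))
    times = np.arange(0, d["span_days"] + d.get("interval_days", 1) / 2, d.get("interval_days", 1)) * 24.0
    decay_series = generate_decay_series(rate, times, noise=noise, seed=seeds[1])
    p_decay = outdir / "decay_series.csv"
    _write_two_col(decay_series, p_decay)

    dil = dict(config.dilution)
    inhibition = float(dil.pop("inhibition", 1.0))
    common = {k: dil[k] for k in ("top_concentration", "fold", "n_steps")}
    common["n_steps"] = int(common["n_steps"])
    buf = generate_dilution_series(**common, noise=noise, seed=seeds[2], matrix_label="buffer")
    ext = generate_dilution_series(
        **common, noise=noise, seed=seeds[3], matrix_label="plant_extract", inhibition=inhibition
    )
    p_buf = _write_dilution(buf, outdir / "dilution_buffer.csv")
    p_ext = _write_dilution(ext, outdir / "dilution_extract.csv")
    return [p_traces, p_decay, p_buf, p_ext]


def _write_two_col(series, path: Path) -> Path:
    import pandas as pd

    pd.DataFrame({"time_h": series.times_h, "activity": series.activity}).to_csv(
        path, index=False, float_format=lambda x: repr(float(x))
    )
    return path


def _read_two_col(path: Path):
    import pandas as pd

    from .decay import DecaySeries

    df = pd.read_csv(path)
    for col in ("time_h", "activity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col}")
    return DecaySeries(times_h=df["time_h"].to_numpy(float), activity=df["activity"].to_numpy(float))


def _write_dilution(series, path: Path) -> Path:
    import pandas as pd

    pd.DataFrame(
        {
            "dilution_factor": series.dilution_factors,
            "signal_cps": series.signal,
            "matrix": series.matrix_label,
        }
    ).to_csv(path, index=False, float_format=lambda x: repr(float(x)))
    return path


def _read_dilution(path: Path, label: str):
    import pandas as pd

    from .calibration import DilutionSeries

    df = pd.read_csv(path)
    for col in ("dilution_factor", "signal_cps"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col}")
    matrix = str(df["matrix"].iloc[0]) if "matrix" in df.columns else label
    return DilutionSeries(
        dilution_factors=df["dilution_factor"].to_numpy(float),
        signal=df["signal_cps"].to_numpy(float),
        matrix_label=matrix,
    )
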