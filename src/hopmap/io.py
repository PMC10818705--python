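"""File formats, packaged fixtures, configuration, and the pipeline runner.

Delimited conventions: comma-separated, period decimal separator, SI
units encoded in the column names (``potential_v_nhe``, ``k_obs_s``,
``time_s``).  Kinetic-trace files are two columns (time_s,
delta_absorbance) preceded by ``# key: value`` comment headers, of which
``# wavelength_nm:`` is mandatory.  Every file the pipeline writes
carries a provenance header (tool version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError, TraceFormatError, UnitsError
from .et_core import (
    ETParameters,
    PotentialTable,
    RateTable,
    max_potential_spread,
    percent_rate_difference,
    round_to_nearest_ten_percent,
)
from .flashquench import KineticTrace, aggregate_fits, assign_phases, fit_biexp
from .hopping_map import HoppingSystem, generate_map, map_point_for_ph, single_step_rate

__all__ = [
    "RunConfig",
    "read_trace",
    "write_trace",
    "read_potential_table",
    "read_rate_table",
    "load_table2_potentials",
    "load_table3_rates",
    "write_map",
    "run_pipeline",
]

logger = logging.getLogger("hopmap")


# ---------------------------------------------------------------- traces

def read_trace(path) -> KineticTrace:
    """Read a two-column kinetic trace (time_s, delta_absorbance).

    Comment lines start with '#'; a '# wavelength_nm: <value>' header is
    required.  Non-monotone time axes and malformed rows are rejected
    with distinct errors.
    """
    path = Path(path)
    meta: dict = {}
    times: list[float] = []
    values: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        if line.lower().startswith("time_s"):
            continue  # optional column header
        parts = [p for p in line.replace(",", " ").split() if p]
        if len(parts) != 2:
            raise TraceFormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            times.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError as exc:
            raise TraceFormatError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if "wavelength_nm" not in meta:
        raise TraceFormatError(f"{path}: missing required '# wavelength_nm:' header")
    try:
        wavelength = float(meta.pop("wavelength_nm"))
    except ValueError as exc:
        raise TraceFormatError(f"{path}: non-numeric wavelength header") from exc
    t = np.asarray(times)
    if t.size and np.any(np.diff(t) <= 0):
        raise TraceFormatError(f"{path}: time axis is not strictly increasing")
    return KineticTrace(time=t, delta_a=np.asarray(values), wavelength=wavelength, meta=meta)


def write_trace(trace: KineticTrace, path) -> None:
    """Write a trace in the two-column format read_trace accepts."""
    path = Path(path)
    lines = [f"# wavelength_nm: {trace.wavelength:g}"]
    for key, val in sorted(trace.meta.items()):
        lines.append(f"# {key}: {val}")
    lines.append("time_s,delta_absorbance")
    for t, a in zip(trace.time, trace.delta_a):
        lines.append(f"{float(t)!r},{float(a)!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- tables

def _read_table_csv(path, required_columns) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    cols = set(df.columns)
    missing = set(required_columns) - cols
    if missing:
        mv_like = {c for c in cols if "mv" in c.lower()}
        if mv_like:
            raise UnitsError(
                f"{path}: columns {sorted(mv_like)} suggest mV units; potentials "
                f"must be supplied in V (column names {sorted(required_columns)})"
            )
        raise DataError(f"{path}: missing required columns {sorted(missing)}")
    return df


def read_potential_table(path) -> PotentialTable:
    """Read a pH/species/potential table; units must be V (column name checked)."""
    return PotentialTable(_read_table_csv(path, PotentialTable.COLUMNS))


def read_rate_table(path) -> RateTable:
    """Read a pH/variant/k_obs table in s^-1."""
    return RateTable(_read_table_csv(path, RateTable.COLUMNS))


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("hopmap").joinpath("data", name)))


def load_table2_potentials() -> PotentialTable:
    """Packaged DPV peak potentials (Cu and Tyr109 couples, pH 5-9)."""
    return read_potential_table(_fixture_path("table2_potentials.csv"))


def load_table3_rates() -> RateTable:
    """Packaged observed Cu(I)-oxidation rate constants (pH 6-9, 4 variants)."""
    return read_rate_table(_fixture_path("table3_rates.csv"))


# ---------------------------------------------------------------- config

@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    File paths default to the packaged measurement tables; trace_glob may
    point at a set of replicate trace files to fit and aggregate.
    """

    r_d_i: float = 16.5
    r_i_a: float = 18.3
    r_d_a: float = 34.8
    lambda_reorg: float = 0.8
    beta: float = 1.1
    temperature: float = 298.0
    k0: float = 1.0e13
    r0: float = 3.0
    ru_potential: float = 1.0
    tyr_species: str = "Tyr109Met122"
    potential_table: str | None = None  # None -> packaged fixture
    rate_table: str | None = None
    trace_glob: str | None = None
    map_n: int = 201
    dg1_range: tuple[float, float] = (-0.4, 0.4)
    dgtot_range: tuple[float, float] = (-1.0, -0.4)
    ph_points: tuple[float, ...] = (6.0, 9.0)
    out_dir: str = "hopmap_out"
    seed: int = 0
    verbose: bool = False

    def system(self) -> HoppingSystem:
        et = ETParameters(
            lambda_reorg=self.lambda_reorg,
            beta=self.beta,
            temperature=self.temperature,
            k0=self.k0,
            r0=self.r0,
        )
        return HoppingSystem(r_d_i=self.r_d_i, r_i_a=self.r_i_a, r_d_a=self.r_d_a, et=et)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("dg1_range", "dgtot_range", "ph_points"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _provenance(config: RunConfig) -> str:
    return (
        f"# hopmap version: {__version__}\n"
        f"# seed: {config.seed}\n"
        f"# config_sha: {config.config_hash()}\n"
    )


def write_map(grid, path, config: RunConfig | None = None) -> None:
    """Export a hopping map as a long-format CSV (dg1_ev, dgtot_ev, log10_k)."""
    path = Path(path)
    header = _provenance(config) if config is not None else ""
    with open(path, "w") as fh:
        fh.write(header)
        grid.to_long_frame().to_csv(fh, index=False, float_format="%.12g")


# --------------------------------------------------------------- pipeline

def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write a machine-readable summary.

    Stages: hopping-map generation, per-pH map points (calculated overall
    rates from the measured potentials), descriptive table comparisons,
    and — when trace files are supplied — biexponential fitting with
    replicate aggregation.  Any stage failure aborts with a diagnostic
    naming the stage.  Outputs are deterministic for a given config, so
    reruns are byte-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_sha": config.config_hash(),
    }

    def stage(name):
        logger.info("stage: %s", name)
        return name

    name = stage("load_tables")
    try:
        potentials = (
            read_potential_table(config.potential_table)
            if config.potential_table
            else load_table2_potentials()
        )
        rates = (
            read_rate_table(config.rate_table)
            if config.rate_table
            else load_table3_rates()
        )
    except Exception as exc:
        raise DataError(f"stage {name!r} failed: {exc}") from exc

    name = stage("hopping_map")
    try:
        sys = config.system()
        grid = generate_map(sys, config.dg1_range, config.dgtot_range, config.map_n)
        write_map(grid, out_dir / "hopping_map.csv", config)
        summary["map"] = {
            "n_dg1": len(grid.dg1_axis),
            "n_dgtot": len(grid.dgtot_axis),
            "file": "hopping_map.csv",
        }
    except Exception as exc:
        raise ConfigError(f"stage {name!r} failed: {exc}") from exc

    name = stage("map_points")
    try:
        points = {}
        for ph in config.ph_points:
            pt = map_point_for_ph(
                sys, potentials, ph, config.tyr_species, config.ru_potential
            )
            points[f"pH {ph:g}"] = {
                "dg1_ev": pt.dg1,
                "dgtot_ev": pt.dg_total,
                "k_hop_s": pt.k_hop,
                "log10_k": pt.log10_k,
                "single_step_rate_s": single_step_rate(sys, pt.dg_total),
            }
        summary["map_points"] = points
    except Exception as exc:
        raise DataError(f"stage {name!r} failed: {exc}") from exc

    name = stage("table_comparisons")
    try:
        tyr_group = [s for s in potentials.species() if s != "Cu"]
        pct = percent_rate_difference(rates, "Met122", "Lys122", 9.0)
        summary["comparisons"] = {
            "max_tyr_potential_spread_v": max_potential_spread(potentials, tyr_group),
            "met_vs_lys_ph9_percent": pct,
            "met_vs_lys_ph9_percent_nearest10": round_to_nearest_ten_percent(pct),
        }
    except Exception as exc:
        raise DataError(f"stage {name!r} failed: {exc}") from exc

    if config.trace_glob:
        name = stage("trace_fits")
        try:
            paths = sorted(Path().glob(config.trace_glob))
            if not paths:
                raise DataError(f"no trace files match {config.trace_glob!r}")
            assignments = []
            per_trace = {}
            for p in paths:
                trace = read_trace(p)
                fit = fit_biexp(trace)
                pa = assign_phases(fit, trace.wavelength)
                assignments.append(pa)
                per_trace[p.name] = {
                    "k_obs_s": pa.redox_rate,
                    "excited_state_rate_s": pa.excited_state_rate,
                    "rss": fit.rss,
                }
            summary["traces"] = per_trace
            if len(assignments) >= 2:
                mean, sd = aggregate_fits(assignments)
                summary["k_obs_aggregate"] = {"mean_s": mean, "sd_s": sd,
                                              "log10_mean": float(np.log10(mean))}
        except Exception as exc:
            raise DataError(f"stage {name!r} failed: {exc}") from exc

    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log_path = out_dir / "run_log.txt"
    log_path.write_text(
        _provenance(config)
        + "".join(f"# {k} = {v!r}\n" for k, v in sorted(config.__dict__.items()))
    )
    return summary
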