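"""Readers and writers for the package's text formats.

Tables are tab-separated with '#'-prefixed header lines carrying column names
(with units) and key=value metadata; genomic tracks are bedGraph (0-based,
half-open).  Rate configs accept explicit unit tags (``s-1`` canonical,
``min-1`` converted on read) because the literature quotes hydrolysis rates
per minute and closure rates per second.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from parbclamp.assays import PhosphateTimeCourse, SensorTrace, TitrationExperiment, FitResult
from parbclamp.kinetics import RateSet
from parbclamp.spreading import OccupancyProfile

PathLike = Union[str, Path]


def convert_rate(value: float, unit: str) -> float:
    """Convert a rate to canonical s^-1 from a tagged unit."""
    if unit in ("s-1", "1/s", "per_s"):
        return value
    if unit in ("min-1", "1/min", "per_min"):
        return value / 60.0
    raise ValueError(f"unknown rate unit {unit!r} (use 's-1' or 'min-1')")


def rates_from_config(section: dict) -> RateSet:
    """Build a RateSet from a config mapping with an optional units block.

    Example::

        rates: {k_oc: 0.01, k_co: 0.01, k_oc_dna: 1.0, k_co_dna: 0.0,
                k_h: 1.0, kd_open: 1.0}
        units: {k_h: min-1}
    """
    section = dict(section)
    units = section.pop("units", {})
    known = {"k_oc", "k_co", "k_oc_dna", "k_co_dna", "k_h", "kd_open", "k_on"}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown rate keys: {sorted(unknown)}")
    missing = {"k_oc", "k_co", "k_oc_dna", "k_co_dna", "k_h", "kd_open"} - set(section)
    if missing:
        raise ValueError(f"missing rate keys: {sorted(missing)}")
    vals = {}
    for key, value in section.items():
        if key in units and key != "kd_open":
            value = convert_rate(float(value), units[key])
        vals[key] = float(value)
    return RateSet(**vals)


def load_config(path: PathLike, allowed_sections: Optional[set] = None) -> dict:
    """Load a YAML run config, rejecting unknown top-level sections."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    if allowed_sections is not None:
        unknown = set(cfg) - allowed_sections
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return cfg


def dump_resolved_config(cfg: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _write_meta(fh, meta: dict) -> None:
    for k, v in meta.items():
        if isinstance(v, (int, float, str, bool)):
            fh.write(f"# {k}={v}\n")


def write_quantity_table(path: PathLike, rows: list) -> None:
    """Rows of (name, value, unit) as a headered TSV."""
    with open(path, "w") as fh:
        fh.write("# name\tvalue\tunit\n")
        for name, value, unit in rows:
            fh.write(f"{name}\t{value:.10g}\t{unit}\n")


def write_bedgraph(profile: OccupancyProfile, path: PathLike, chrom: str = "synthetic") -> None:
    """bedGraph track: chrom, 0-based half-open start/end, value."""
    ends = profile.ends
    with open(path, "w") as fh:
        _write_meta(fh, {k: v for k, v in profile.metadata.items() if k != "noise"})
        for s, e, v in zip(profile.starts, ends, profile.occupancy):
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path: PathLike) -> OccupancyProfile:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["chrom", "start", "end", "value"]
    )
    starts = df["start"].to_numpy(dtype=np.int64)
    ends = df["end"].to_numpy(dtype=np.int64)
    bin_size = int(ends[0] - starts[0])
    return OccupancyProfile(
        starts=starts,
        bin_size=bin_size,
        occupancy=df["value"].to_numpy(dtype=float),
        metadata={"length_bp": int(ends[-1]), "path": str(path)},
    )


def write_itc(exp: TitrationExperiment, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# vo_ul={exp.vo}\n")
        truth = exp.metadata.get("truth")
        if truth:
            for k, v in truth.items():
                fh.write(f"# truth_{k}={v}\n")
        if "seed" in exp.metadata:
            fh.write(f"# seed={exp.metadata['seed']}\n")
        fh.write("# injection\tdv_ul\tmt_um\txt_um\theat\n")
        heats = exp.heats if exp.heats is not None else np.full(exp.n_injections, np.nan)
        for i in range(exp.n_injections):
            fh.write(f"{i + 1}\t{exp.dv[i]:.10g}\t{exp.mt[i]:.10g}\t{exp.xt[i]:.10g}\t{heats[i]:.10g}\n")


def _read_meta(path: PathLike) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body and "\t" not in body:
                k, v = body.split("=", 1)
                try:
                    meta[k.strip()] = float(v)
                except ValueError:
                    meta[k.strip()] = v.strip()
    return meta


def _read_table(path: PathLike, columns: list) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] != len(columns):
        raise ValueError(
            f"{path}: expected columns {columns}, found {df.shape[1]} columns"
        )
    df.columns = columns
    return df


def read_itc(path: PathLike) -> TitrationExperiment:
    meta = _read_meta(path)
    if "vo_ul" not in meta:
        raise ValueError(f"{path}: missing '# vo_ul=' header")
    df = _read_table(path, ["injection", "dv_ul", "mt_um", "xt_um", "heat"])
    truth = {k[len("truth_"):]: v for k, v in meta.items() if k.startswith("truth_")}
    metadata = {"path": str(path)}
    if truth:
        metadata["truth"] = truth
    if "seed" in meta:
        metadata["seed"] = int(meta["seed"])
    return TitrationExperiment(
        vo=float(meta["vo_ul"]),
        dv=df["dv_ul"].to_numpy(),
        mt=df["mt_um"].to_numpy(),
        xt=df["xt_um"].to_numpy(),
        heats=df["heat"].to_numpy(),
        metadata=metadata,
    )


def write_trace(trace: SensorTrace, path: PathLike) -> None:
    with open(path, "w") as fh:
        truth = trace.metadata.get("truth")
        if truth:
            for k, v in truth.items():
                fh.write(f"# truth_{k}={v}\n")
        if "seed" in trace.metadata:
            fh.write(f"# seed={trace.metadata['seed']}\n")
        fh.write("# time_s\tsignal\tphase\n")
        for t, y, p in zip(trace.times, trace.signal, trace.phases):
            fh.write(f"{t:.10g}\t{y:.10g}\t{p}\n")


def read_trace(path: PathLike) -> SensorTrace:
    meta = _read_meta(path)
    df = _read_table(path, ["time_s", "signal", "phase"])
    truth = {k[len("truth_"):]: v for k, v in meta.items() if k.startswith("truth_")}
    metadata = {"path": str(path)}
    if truth:
        metadata["truth"] = truth
    return SensorTrace(
        times=df["time_s"].to_numpy(),
        signal=df["signal"].to_numpy(),
        phases=df["phase"].to_numpy(dtype=object),
        metadata=metadata,
    )


def write_ctpase(tc: PhosphateTimeCourse, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# protein_um={tc.protein_conc}\n")
        truth = tc.metadata.get("truth")
        if truth:
            for k, v in truth.items():
                fh.write(f"# truth_{k}={v}\n")
        if "seed" in tc.metadata:
            fh.write(f"# seed={tc.metadata['seed']}\n")
        fh.write("# time_min\tphosphate_um\n")
        for t, p in zip(tc.times, tc.phosphate_um()):
            fh.write(f"{t:.10g}\t{p:.10g}\n")


def read_ctpase(path: PathLike) -> PhosphateTimeCourse:
    meta = _read_meta(path)
    if "protein_um" not in meta:
        raise ValueError(f"{path}: missing '# protein_um=' header")
    df = _read_table(path, ["time_min", "phosphate_um"])
    truth = {k[len("truth_"):]: v for k, v in meta.items() if k.startswith("truth_")}
    metadata = {"path": str(path)}
    if truth:
        metadata["truth"] = truth
    return PhosphateTimeCourse(
        times=df["time_min"].to_numpy(),
        protein_conc=float(meta["protein_um"]),
        phosphate=df["phosphate_um"].to_numpy(),
        metadata=metadata,
    )


def write_trajectory(trajectory, path: PathLike) -> None:
    """Delimited event table: time, reaction id, reaction name, species counts."""
    net = trajectory.network
    counts = trajectory.species_counts()
    with open(path, "w") as fh:
        _write_meta(fh, trajectory.metadata)
        fh.write("# time_s\treaction_id\treaction\t" + "\t".join(net.species) + "\n")
        fh.write("0\t-\tinitial\t" + "\t".join(str(c) for c in counts[0]) + "\n")
        for t, j, row in zip(trajectory.times, trajectory.reaction_index, counts[1:]):
            name = net.reactions[j].name
            fh.write(f"{t:.10g}\t{j}\t{name}\t" + "\t".join(str(c) for c in row) + "\n")


def write_fit_report(result: FitResult, path: PathLike, units: Optional[dict] = None) -> None:
    """Plain-text fit report: parameter, estimate, SE, unit, convergence."""
    units = units or {}
    with open(path, "w") as fh:
        fh.write(f"# converged={result.converged}\n")
        if result.flags:
            fh.write(f"# flags={','.join(result.flags)}\n")
        if math.isfinite(result.residual_norm):
            fh.write(f"# residual_norm={result.residual_norm:.6g}\n")
        fh.write("# parameter\testimate\tse\tunit\n")
        for name, value in result.params.items():
            se = result.errors.get(name, float("nan"))
            fh.write(f"{name}\t{value:.10g}\t{se:.6g}\t{units.get(name, '-')}\n")
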