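"""Shared file I/O: CSV serialization, constants configs and run manifests.

CSV dialect: comma-separated, header row, '.' decimal, UTF-8, floats at
9 significant digits.  Every CLI run writes a JSON manifest (config
snapshot, seeds, package version, timestamp, output paths) sufficient to
re-run it bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lrbc_core import LrbcConstants, LrbcSeries
from .mc_transport import RadialReflectanceProfile
from .occlusion_synthesis import DemodulatedSeries

FLOAT_FMT = "%.9g"


def _pkg_version() -> str:
    try:
        return version("lrbcsim")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def write_profile_csv(profile: RadialReflectanceProfile, path) -> None:
    stderr = (profile.bin_stderr if profile.bin_stderr is not None
              else np.zeros_like(profile.bin_values))
    df = pd.DataFrame({"bin_center_mm": profile.bin_centers,
                       "value": profile.bin_values, "stderr": stderr})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_profile_csv(path, n_packets: int = 0) -> RadialReflectanceProfile:
    df = pd.read_csv(path)
    return RadialReflectanceProfile(
        bin_centers=df["bin_center_mm"].to_numpy(),
        bin_values=df["value"].to_numpy(), n_packets=n_packets,
        bin_stderr=df["stderr"].to_numpy())


def write_series_csv(series: LrbcSeries, path) -> None:
    phase = (series.annotations if series.annotations is not None
             else np.full(series.time.shape, "", dtype=object))
    df = pd.DataFrame({"t_s": series.time, "lrbc_um": series.lrbc, "phase": phase})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_demod_csv(demod: DemodulatedSeries, path) -> None:
    pd.DataFrame({"t_s": demod.time, "ve_590": demod.ve_590,
                  "ve_780": demod.ve_780}).to_csv(path, index=False,
                                                  float_format=FLOAT_FMT)


def read_demod_csv(path) -> DemodulatedSeries:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    return DemodulatedSeries(time=t, ve_590=df["ve_590"].to_numpy(),
                             ve_780=df["ve_780"].to_numpy(), rate=rate)


def save_constants(constants: LrbcConstants, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(constants), fh, sort_keys=False)


def load_constants(path) -> LrbcConstants:
    with open(path, "r", encoding="utf-8") as fh:
        return LrbcConstants(**yaml.safe_load(fh))


@dataclasses.dataclass
class RunManifest:
    """Record of one CLI run, sufficient to reproduce it bit-identically."""

    subcommand: str
    parameters: dict
    seeds: list[int]
    outputs: list[str]
    package_version: str = dataclasses.field(default_factory=_pkg_version)
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat())

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(**data)


def manifest_path(output: str | Path) -> Path:
    out = Path(output)
    return out.with_suffix(out.suffix + ".manifest.json")
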