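"""File formats: plate-reader traces, time courses, models and scenarios.

Concentration columns in CSV output carry an explicit ``_M`` suffix (molar);
metric outputs use minutes and nM for parity with how thrombin-generation
results are usually plotted.  Time courses round-trip through CSV at 12
significant digits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .library import Scenario
from .network import ModelSpec
from .simulate import TimeCourse

logger = logging.getLogger("coagkin")

__all__ = [
    "PlateTrace",
    "PlateFormatError",
    "read_plate_csv",
    "synth_trace",
    "write_timecourse_csv",
    "read_timecourse_csv",
    "load_scenario",
    "save_scenario",
    "load_model",
    "save_model",
]


class PlateFormatError(ValueError):
    """Unparseable or non-uniform plate-reader table."""


@dataclass
class PlateTrace:
    """One well's fluorescence trace.

    ``f_min``/``f_max`` are the per-well calibration values (baseline and
    complete-conversion fluorescence); conversion is
    (F - f_min) / (f_max - f_min).
    """

    well: str
    times: np.ndarray  # s, uniform cadence
    fluorescence: np.ndarray  # arbitrary units
    f_min: Optional[float] = None
    f_max: Optional[float] = None
    interpolated: int = 0  # number of reads filled by interpolation

    def conversion(self) -> np.ndarray:
        if self.f_min is not None:
            lo = self.f_min
        else:
            # uncalibrated well: estimate the baseline from the early reads
            # (robust to read noise, unlike the observed minimum)
            head = self.fluorescence[: min(5, len(self.fluorescence))]
            lo = float(np.median(head))
        hi = self.f_max if self.f_max is not None else float(np.max(self.fluorescence))
        if hi <= lo:
            raise PlateFormatError(f"well {self.well}: f_max must exceed f_min")
        return (self.fluorescence - lo) / (hi - lo)


def _check_cadence(times: np.ndarray, well: str) -> None:
    dt = np.diff(times)
    if len(dt) == 0:
        raise PlateFormatError(f"well {well}: fewer than 2 reads")
    med = np.median(dt)
    if med <= 0 or np.any(np.abs(dt - med) > 0.1 * med):
        raise PlateFormatError(f"well {well}: non-uniform read cadence (>10% jitter)")


def _fill_gaps(values: np.ndarray, well: str) -> tuple[np.ndarray, int]:
    bad = ~np.isfinite(values)
    if bad.all():
        raise PlateFormatError(f"well {well}: no finite reads")
    n = int(bad.sum())
    if n:
        idx = np.arange(len(values))
        values = values.copy()
        values[bad] = np.interp(idx[bad], idx[~bad], values[~bad])
        logger.info("well %s: interpolated %d missing read(s)", well, n)
    return values, n


def read_plate_csv(path, dialect: str = "wide") -> list[PlateTrace]:
    """Read plate-reader fluorescence traces from CSV.

    wide -- one ``time_s`` column plus one column per well.
    long -- columns ``well``, ``time_s``, ``fluorescence``.

    Missing reads (empty cells) are linearly interpolated and counted in
    ``interpolated``; a non-uniform cadence beyond 10% jitter is an error.
    """
    df = pd.read_csv(path)
    traces: list[PlateTrace] = []
    if dialect == "wide":
        if "time_s" not in df.columns:
            raise PlateFormatError("wide dialect needs a 'time_s' column")
        times = df["time_s"].to_numpy(float)
        for col in df.columns:
            if col == "time_s":
                continue
            _check_cadence(times, col)
            vals, n = _fill_gaps(df[col].to_numpy(float), col)
            traces.append(PlateTrace(well=str(col), times=times, fluorescence=vals, interpolated=n))
    elif dialect == "long":
        need = {"well", "time_s", "fluorescence"}
        if not need.issubset(df.columns):
            raise PlateFormatError(f"long dialect needs columns {sorted(need)}")
        for well, grp in df.groupby("well", sort=False):
            grp = grp.sort_values("time_s")
            times = grp["time_s"].to_numpy(float)
            _check_cadence(times, str(well))
            vals, n = _fill_gaps(grp["fluorescence"].to_numpy(float), str(well))
            traces.append(PlateTrace(well=str(well), times=times, fluorescence=vals, interpolated=n))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return traces


def synth_trace(
    t_i: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    horizon_min: float = 240.0,
    interval_s: float = 60.0,
    steepness: float = 0.2,
    f_min: float = 100.0,
    f_max: float = 10100.0,
    well: str = "synthetic",
) -> PlateTrace:
    """Synthetic plate trace: logistic conversion crossing 5% at ``t_i`` (min).

    ``steepness`` is the logistic rate in 1/min; ``noise_sd`` is Gaussian
    noise expressed as a fraction of the calibration span.  Seeded and
    reproducible.
    """
    if not 0.0 < t_i < horizon_min:
        raise ValueError("t_i must lie inside the horizon")
    times = np.arange(0.0, horizon_min * 60.0 + 1, interval_s)
    t_min = times / 60.0
    t0 = t_i + np.log(1.0 / 0.05 - 1.0) / steepness  # C(t_i) = 0.05
    conv = 1.0 / (1.0 + np.exp(-steepness * (t_min - t0)))
    rng = np.random.default_rng(seed)
    f = f_min + (f_max - f_min) * conv
    if noise_sd:
        f = f + noise_sd * (f_max - f_min) * rng.standard_normal(len(f))
    return PlateTrace(
        well=well, times=times, fluorescence=f, f_min=f_min, f_max=f_max
    )


# ---------------------------------------------------------------------------
# time courses
# ---------------------------------------------------------------------------

def write_timecourse_csv(tc: TimeCourse, path, tidy: bool = False) -> None:
    df = tc.to_tidy_frame() if tidy else tc.to_wide_frame()
    df.to_csv(path, index=False, float_format="%.12e")


def read_timecourse_csv(path) -> TimeCourse:
    """Read back a wide-format time-course CSV written by this package."""
    df = pd.read_csv(path)
    species = [c[:-2] for c in df.columns if c.endswith("_M") and c != "iia_max_M"]
    conc = np.vstack([df[f"{n}_M"].to_numpy(float) for n in species])
    return TimeCourse(
        times=df["time_s"].to_numpy(float),
        conc=conc,
        eps=df["eps"].to_numpy(float) if "eps" in df else np.ones(len(df)),
        iia_max=df["iia_max_M"].to_numpy(float) if "iia_max_M" in df else np.zeros(len(df)),
        species_names=species,
    )


# ---------------------------------------------------------------------------
# configuration documents
# ---------------------------------------------------------------------------

def _load_doc(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _dump_doc(obj: dict, path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(obj, sort_keys=False))
    else:
        path.write_text(json.dumps(obj, indent=2))


def load_scenario(path) -> Scenario:
    return Scenario.from_dict(_load_doc(path))


def save_scenario(s: Scenario, path) -> None:
    _dump_doc(s.to_dict(), path)


def load_model(path) -> ModelSpec:
    return ModelSpec.from_dict(_load_doc(path))


def save_model(m: ModelSpec, path) -> None:
    _dump_doc(m.to_dict(), path)
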