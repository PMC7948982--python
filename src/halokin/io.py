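"""Config and CSV input/output.

Configs are flat YAML key-value documents with per-halide sub-blocks; CSV
dialects are UTF-8, comma-delimited, '.' decimal, with a header row:

* trace: ``time_s,value,channel`` (long format written; a wide
  single-channel ``time_s,value`` file is also read);
* species time course: ``time_s`` then one column per species name;
* saturation dataset: ``conc_mM,kobs_s-1[,se]``;
* inactivation series: ``age_s,amplitude``;
* sidecar ground-truth files: YAML, written next to the data file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ValidationError
from .fitting import InactivationSeries, SaturationDataset
from .optics import OpticalModel, Trace
from .scheme import (
    SPECIES,
    Halide,
    InitialConditions,
    RateParameters,
    SpeciesTimeCourse,
    TimeGrid,
)

__all__ = [
    "params_to_dict",
    "params_from_dict",
    "init_to_dict",
    "init_from_dict",
    "optics_to_dict",
    "optics_from_dict",
    "load_config",
    "save_config",
    "write_trace_csv",
    "read_trace_csv",
    "write_timecourse_csv",
    "write_saturation_csv",
    "read_saturation_csv",
    "write_inactivation_csv",
    "read_inactivation_csv",
    "write_sidecar",
    "read_sidecar",
]


# --- dataclass <-> plain dict ------------------------------------------------

def params_to_dict(params: RateParameters) -> dict:
    out = {
        "k_bind_flavin": params.k_bind_flavin,
        "k_inact": params.k_inact,
        "k_ox": params.k_ox,
        "k_unc": params.k_unc,
        "k_dehyd": params.k_dehyd,
        "k_capture": params.k_capture,
        "k_leak": params.k_leak,
        "f_unc_pop": params.f_unc_pop,
        "halide_on_rate": params.halide_on_rate,
        "halides": {
            h.value: {
                "kd_mM": params.kd_mM.get(h),
                "k_hox": params.k_hox.get(h, 0.0),
            }
            for h in Halide
            if h in params.kd_mM or h in params.k_hox
        },
    }
    return out


def params_from_dict(raw: Mapping) -> RateParameters:
    raw = dict(raw)
    halides = raw.pop("halides", {})
    kd, khox = {}, {}
    for name, block in halides.items():
        h = Halide.coerce(name)
        if block.get("kd_mM") is not None:
            kd[h] = float(block["kd_mM"])
        if block.get("k_hox") is not None:
            khox[h] = float(block["k_hox"])
    kwargs = {k: v for k, v in raw.items() if v is not None or k in ("f_unc_pop", "halide_on_rate")}
    unknown = set(kwargs) - {
        "k_bind_flavin", "k_inact", "k_ox", "k_unc", "k_dehyd",
        "k_capture", "k_leak", "f_unc_pop", "halide_on_rate",
    }
    if unknown:
        raise ConfigError(f"unknown rate-parameter keys: {sorted(unknown)}")
    if kd:
        kwargs["kd_mM"] = kd
    if khox:
        kwargs["k_hox"] = khox
    return RateParameters(**kwargs)


def init_to_dict(init: InitialConditions) -> dict:
    return {name: getattr(init, name) for name in SPECIES + ("o2_uM", "x_conc_mM")}


def init_from_dict(raw: Mapping) -> InitialConditions:
    allowed = set(SPECIES) | {"o2_uM", "x_conc_mM"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown initial-condition keys: {sorted(unknown)}")
    return InitialConditions(**{k: float(v) for k, v in raw.items()})


def optics_to_dict(optics: OpticalModel) -> dict:
    return {
        "path_length_cm": optics.path_length_cm,
        "eps": {ch: dict(tbl) for ch, tbl in optics.eps.items()},
        "phi": {ch: dict(tbl) for ch, tbl in optics.phi.items()},
    }


def optics_from_dict(raw: Mapping) -> OpticalModel:
    kwargs = {}
    if "path_length_cm" in raw:
        kwargs["path_length_cm"] = float(raw["path_length_cm"])
    for key in ("eps", "phi"):
        if key in raw:
            kwargs[key] = {ch: dict(tbl) for ch, tbl in raw[key].items()}
    return OpticalModel(**kwargs)


# --- config files ------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML run config; returns the raw mapping.

    Recognized top-level blocks: ``rates``, ``initial``, ``optics``,
    ``energetics`` (per-halide ``e_ts``/``e_product``), plus free-form keys
    the CLI interprets (seed, halide, channel, ...).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping: {path}")
    return raw


def save_config(raw: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(raw), fh, sort_keys=False)


# --- CSV ---------------------------------------------------------------------

def write_trace_csv(trace: Trace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_trace_csv(path: str | Path, channel: str | None = None) -> Trace:
    """Read a trace CSV (long format, or wide ``time_s,value``).

    For a long-format file containing several channels, ``channel`` selects
    which one to return.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns or "value" not in df.columns:
        raise ValidationError(f"trace CSV must have columns time_s,value[,channel]: {path}")
    if "channel" in df.columns:
        channels = df["channel"].unique()
        if channel is None:
            if len(channels) > 1:
                raise ValidationError(
                    f"trace CSV holds channels {sorted(channels)}; pass channel= to choose one"
                )
            channel = channels[0]
        df = df[df["channel"] == channel]
        if df.empty:
            raise ValidationError(f"channel {channel!r} not present in {path}")
    else:
        channel = channel or "A380"
    df = df.sort_values("time_s")
    return Trace(str(channel), TimeGrid(df["time_s"].to_numpy()), df["value"].to_numpy())


def write_timecourse_csv(tc: SpeciesTimeCourse, path: str | Path) -> None:
    tc.to_frame().to_csv(path, index=False)


def write_saturation_csv(ds: SaturationDataset, path: str | Path) -> None:
    data = {"conc_mM": ds.conc_mM, "kobs_s-1": ds.kobs}
    if ds.se is not None:
        data["se"] = ds.se
    pd.DataFrame(data).to_csv(path, index=False)


def read_saturation_csv(path: str | Path, halide: Halide | str | None = None) -> SaturationDataset:
    df = pd.read_csv(path)
    if "conc_mM" not in df.columns or "kobs_s-1" not in df.columns:
        raise ValidationError(f"saturation CSV must have columns conc_mM,kobs_s-1[,se]: {path}")
    se = df["se"].to_numpy() if "se" in df.columns else None
    return SaturationDataset(
        Halide.coerce(halide), df["conc_mM"].to_numpy(), df["kobs_s-1"].to_numpy(), se
    )


def write_inactivation_csv(series: InactivationSeries, path: str | Path) -> None:
    pd.DataFrame({"age_s": series.age_s, "amplitude": series.amplitude}).to_csv(path, index=False)


def read_inactivation_csv(path: str | Path) -> InactivationSeries:
    df = pd.read_csv(path)
    if "age_s" not in df.columns or "amplitude" not in df.columns:
        raise ValidationError(f"inactivation CSV must have columns age_s,amplitude: {path}")
    return InactivationSeries(df["age_s"].to_numpy(), df["amplitude"].to_numpy())


def _pythonize(obj):
    if isinstance(obj, dict):
        return {k: _pythonize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pythonize(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_sidecar(sidecar: Mapping, path: str | Path) -> None:
    """Write a ground-truth sidecar (YAML) next to its data file."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_pythonize(dict(sidecar)), fh, sort_keys=False)


def read_sidecar(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
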