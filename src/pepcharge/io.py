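"""Delimited-text readers/writers for every input dialect, plus configuration.

All files are comma-delimited with ``# key = value`` metadata lines before
the header.  Dialects:

* QCM-D traces: columns ``time_s, harmonic, df_Hz, dD_e-6``; metadata
  ``f1_Hz``, ``dialect`` (``raw`` frequency shifts or harmonic-``normalized``).
* LSPR traces: columns ``time_s, dlambda_nm``.
* SHG isotherms: columns ``conc_M, E_norm, sigma_E, extrapolated``;
  metadata ``signal`` (``efield`` or ``intensity`` — intensities are
  converted as E = sqrt(I) on read).
* Charge-density profiles: columns ``z_A, rho_<component>...``; metadata
  ``units`` (``C_m3`` or ``e_A3``) and optional ``area_A2``.
* Binding coordinates: columns ``role, peptide_id, x_A, y_A, z_A`` with
  role ``P`` for phosphorus or a residue type (``ARG``/``LYS``); metadata
  ``box_A = lx ly lz``.

The structured configuration (:class:`AnalysisConfig`) is YAML with
recursive unknown-key rejection; :func:`config_hash` hashes the canonical
JSON form, so the hash changes iff a semantic field changes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acoustic import HarmonicTrace
from .constants import E_PER_A3_TO_C_PER_M3
from .electrostatics import BindingGeometry, ChargeDensityProfile, DEFAULT_CUTOFFS
from .isotherm import IsothermData
from .optical import LSPRTrace

__all__ = [
    "read_qcmd", "write_qcmd",
    "read_lspr", "write_lspr",
    "read_isotherm", "write_isotherm",
    "read_profile", "write_profile",
    "read_coordinates", "write_coordinates",
    "AnalysisConfig", "config_hash",
]


def _read_meta(path) -> tuple[dict, int]:
    meta, skip = {}, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta, skip


def _write_table(path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, index=False)


def read_qcmd(path) -> tuple[dict[int, HarmonicTrace], dict]:
    """Read a QCM-D trace file -> ({harmonic: HarmonicTrace}, metadata)."""
    meta, skip = _read_meta(path)
    df = pd.read_csv(path, skiprows=skip)
    dialect = meta.get("dialect", "raw")
    traces = {}
    for nu, grp in df.groupby("harmonic"):
        nu = int(nu)
        f_shift = grp["df_Hz"].to_numpy(float)
        if dialect == "normalized":
            f_shift = f_shift * nu
        traces[nu] = HarmonicTrace(
            grp["time_s"].to_numpy(float), nu, f_shift, grp["dD_e-6"].to_numpy(float) * 1e-6
        )
    return traces, meta


def write_qcmd(path, traces: dict[int, HarmonicTrace], f1: float = 4.95e6, dialect: str = "raw") -> None:
    rows = []
    for nu in sorted(traces):
        t = traces[nu]
        f_shift = t.frequency_shift / nu if dialect == "normalized" else t.frequency_shift
        rows.append(pd.DataFrame({
            "time_s": t.time, "harmonic": nu, "df_Hz": f_shift, "dD_e-6": t.dissipation * 1e6,
        }))
    _write_table(path, pd.concat(rows, ignore_index=True), {"f1_Hz": f1, "dialect": dialect})


def read_lspr(path) -> tuple[LSPRTrace, dict]:
    meta, skip = _read_meta(path)
    df = pd.read_csv(path, skiprows=skip)
    return LSPRTrace(df["time_s"].to_numpy(float), df["dlambda_nm"].to_numpy(float)), meta


def write_lspr(path, trace: LSPRTrace) -> None:
    _write_table(path, pd.DataFrame({"time_s": trace.time, "dlambda_nm": trace.dlambda}), {})


def read_isotherm(path) -> tuple[IsothermData, dict]:
    """Read an isotherm file; intensity-dialect signals become E = sqrt(I)."""
    meta, skip = _read_meta(path)
    df = pd.read_csv(path, skiprows=skip)
    e = df["E_norm"].to_numpy(float)
    sig = df["sigma_E"].to_numpy(float) if "sigma_E" in df else None
    if meta.get("signal", "efield") == "intensity":
        e = np.sqrt(e)
        if sig is not None:
            # first-order propagation through E = sqrt(I): dE = dI/(2 sqrt(I))
            sig = sig / (2.0 * np.maximum(e, 1e-12))
    extra = df["extrapolated"].to_numpy(bool) if "extrapolated" in df else None
    return IsothermData(df["conc_M"].to_numpy(float), e, sig, extra), meta


def write_isotherm(path, iso: IsothermData, signal: str = "efield") -> None:
    if signal != "efield":
        raise ValueError("writer emits the efield dialect only")
    _write_table(path, pd.DataFrame({
        "conc_M": iso.concentration, "E_norm": iso.e_norm,
        "sigma_E": iso.sigma_e, "extrapolated": iso.extrapolated.astype(int),
    }), {"signal": "efield"})


def read_profile(path) -> tuple[ChargeDensityProfile, dict]:
    """Read a charge-density profile; densities converted to C m^-3."""
    meta, skip = _read_meta(path)
    df = pd.read_csv(path, skiprows=skip)
    factor = E_PER_A3_TO_C_PER_M3 if meta.get("units", "C_m3") == "e_A3" else 1.0
    dens = {
        col[4:]: df[col].to_numpy(float) * factor
        for col in df.columns if col.startswith("rho_")
    }
    area = float(meta["area_A2"]) if "area_A2" in meta else None
    return ChargeDensityProfile(df["z_A"].to_numpy(float), dens, area), meta


def write_profile(path, profile: ChargeDensityProfile) -> None:
    data = {"z_A": profile.z}
    for k, v in profile.densities.items():
        data[f"rho_{k}"] = v
    meta = {"units": "C_m3"}
    if profile.area is not None:
        meta["area_A2"] = profile.area
    _write_table(path, pd.DataFrame(data), meta)


def read_coordinates(path, cutoffs: dict | None = None) -> tuple[BindingGeometry, dict]:
    meta, skip = _read_meta(path)
    df = pd.read_csv(path, skiprows=skip)
    box = np.array([float(v) for v in meta["box_A"].split()])
    is_p = df["role"] == "P"
    sc = df[~is_p]
    return BindingGeometry(
        sidechain_xyz=sc[["x_A", "y_A", "z_A"]].to_numpy(float),
        sidechain_type=sc["role"].to_numpy(str),
        peptide_id=sc["peptide_id"].to_numpy(int),
        phosphorus_xyz=df[is_p][["x_A", "y_A", "z_A"]].to_numpy(float),
        box=box,
        cutoffs=dict(cutoffs or DEFAULT_CUTOFFS),
    ), meta


def write_coordinates(path, geom: BindingGeometry) -> None:
    sc = pd.DataFrame({
        "role": geom.sidechain_type, "peptide_id": geom.peptide_id,
        "x_A": geom.sidechain_xyz[:, 0], "y_A": geom.sidechain_xyz[:, 1],
        "z_A": geom.sidechain_xyz[:, 2],
    })
    pp = pd.DataFrame({
        "role": "P", "peptide_id": -1,
        "x_A": geom.phosphorus_xyz[:, 0], "y_A": geom.phosphorus_xyz[:, 1],
        "z_A": geom.phosphorus_xyz[:, 2],
    })
    _write_table(
        path, pd.concat([pp, sc], ignore_index=True),
        {"box_A": " ".join(f"{v:g}" for v in geom.box)},
    )


# ---------------------------------------------------------------------------
# configuration


def _from_dict(cls, data: dict):
    """Instantiate a dataclass from a dict, rejecting unknown keys recursively."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = _CONFIG_SECTIONS.get(name)
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _from_dict(sub, value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


@dataclass(frozen=True)
class SensorConfig:
    f1_Hz: float = 4.95e6
    mass_sensitivity_ng_cm2_Hz: float = 18.0


@dataclass(frozen=True)
class FluidConfig:
    density_kg_m3: float = 1000.0
    viscosity_kg_m_s: float = 0.001


@dataclass(frozen=True)
class FilmConfig:
    density_kg_m3: float = 1050.0
    noise_df_Hz: float = 0.5
    noise_dd: float = 0.05e-6
    steady_window_s: tuple = (3000.0, 3600.0)
    rate_window_s: tuple = (600.0, 900.0)


@dataclass(frozen=True)
class OpticsConfig:
    sensitivity_nm_RIU: float = 110.0
    decay_length_nm: float = 20.0
    dn_dc_cm3_g: float = 0.182
    thickness_nm: float | None = None


@dataclass(frozen=True)
class GCConfig:
    temperature_K: float = 298.15
    electrolyte_M: float = 0.1
    epsilon_r: float = 78.2
    sigma0_C_m2: float = -0.1


@dataclass(frozen=True)
class MDConfig:
    electrolyte_M: float = 0.15
    temperature_K: float = 303.15
    grahame_window_A: tuple = (18.0, 24.0)
    cutoff_arg_A: float = 5.5
    cutoff_lys_A: float = 4.5


@dataclass(frozen=True)
class FitConfig:
    seed: int = 0
    n_starts: int = 5
    c_extrap_M: float = 0.1
    k_last_points: int = 3
    sensitivity_perturbation: float = 0.10
    # chi(3) response B from an independent optical-voltmeter calibration;
    # None leaves B free (B and delta-sigma are then nearly degenerate)
    calibrated_b_per_V: float | None = None


@dataclass(frozen=True)
class PeptideConfig:
    name: str = "ARG8"
    footprint_nm2: float = 4.7  # back-computed occupancy footprints: 4.0 Lys8 / 4.7 Arg8
    molar_mass_g_mol: float | None = None
    z_max: int | None = None


@dataclass(frozen=True)
class AnalysisConfig:
    """Structured analysis configuration; unknown keys are rejected."""

    sensor: SensorConfig = field(default_factory=SensorConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    film: FilmConfig = field(default_factory=FilmConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    gc: GCConfig = field(default_factory=GCConfig)
    md: MDConfig = field(default_factory=MDConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    peptide: PeptideConfig = field(default_factory=PeptideConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        return _from_dict(cls, data or {})

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_CONFIG_SECTIONS = {
    "sensor": SensorConfig, "fluid": FluidConfig, "film": FilmConfig,
    "optics": OpticsConfig, "gc": GCConfig, "md": MDConfig,
    "fit": FitConfig, "peptide": PeptideConfig,
}


def config_hash(config: AnalysisConfig) -> str:
    """sha256 over the canonical JSON form of the configuration."""
    canon = json.dumps(config.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(canon.encode()).hexdigest()
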