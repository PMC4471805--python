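"""Delimited-text readers/writers and configuration handling.

All on-disk formats are plain delimited text (comma or tab, auto-detected)
with explicit header names, plus YAML for scheme definitions, instrument
sidecars and fit reports:

* binding data: ``conc_uM, mw_kDa[, mw_sigma_kDa]``
* chromatograms: ``volume_ml, ls, dri[, uv]`` with a YAML sidecar carrying
  ``dn_dc`` and ``ls_calib``
* melting curves: ``temp_C, theta222``
* CD spectra: ``wavelength_nm, signal[, ht_volts]``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cdtherm import CDSpectrum, MeltingCurve
from .equilibrium import PRESETS, AssemblyScheme, BindingCurve, ValidationError, build_scheme
from .secmals import DEFAULT_DN_DC, Chromatogram

__all__ = [
    "read_table",
    "read_binding_curve",
    "write_binding_curve",
    "read_chromatogram",
    "write_chromatogram",
    "read_melting_curve",
    "write_melting_curve",
    "read_cd_spectrum",
    "scheme_from_config",
    "scheme_to_config",
    "write_report",
]


def read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    """Read a comma- or tab-delimited table, validating required headers.

    Errors name the offending file and, for parse failures, the line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ValidationError(f"{path}: cannot parse delimited text ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    return df


def read_binding_curve(path: str | Path) -> BindingCurve:
    df = read_table(path, ["conc_uM", "mw_kDa"])
    sigma = df["mw_sigma_kDa"].to_numpy() if "mw_sigma_kDa" in df.columns else None
    return BindingCurve(df["conc_uM"].to_numpy(), df["mw_kDa"].to_numpy(), mw_sigma=sigma)


def write_binding_curve(curve: BindingCurve, path: str | Path) -> None:
    data = {"conc_uM": curve.c_total, "mw_kDa": curve.mw}
    if curve.mw_sigma is not None:
        data["mw_sigma_kDa"] = curve.mw_sigma
    if curve.overloaded is not None:
        data["overloaded"] = curve.overloaded.astype(int)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def read_chromatogram(path: str | Path, sidecar: str | Path | None = None) -> Chromatogram:
    """Read detector traces; instrument constants come from a YAML sidecar.

    The sidecar defaults to ``<stem>.yaml`` next to the trace file and may
    set ``dn_dc`` and ``ls_calib``; absent values fall back to defaults.
    """
    path = Path(path)
    df = read_table(path, ["volume_ml", "ls", "dri"])
    constants = {"dn_dc": DEFAULT_DN_DC, "ls_calib": 0.01}
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".yaml")
    if sidecar.exists():
        loaded = yaml.safe_load(sidecar.read_text()) or {}
        constants.update({k: float(v) for k, v in loaded.items() if k in constants})
    uv = df["uv"].to_numpy() if "uv" in df.columns else None
    return Chromatogram(df["volume_ml"].to_numpy(), df["ls"].to_numpy(), df["dri"].to_numpy(), uv=uv, **constants)


def write_chromatogram(chrom: Chromatogram, path: str | Path, sidecar: str | Path | None = None) -> None:
    path = Path(path)
    data = {"volume_ml": chrom.volume, "ls": chrom.ls, "dri": chrom.dri}
    if chrom.uv is not None:
        data["uv"] = chrom.uv
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".yaml")
    sidecar.write_text(yaml.safe_dump({"dn_dc": chrom.dn_dc, "ls_calib": chrom.ls_calib}, sort_keys=True))


def read_melting_curve(path: str | Path) -> MeltingCurve:
    df = read_table(path, ["temp_C", "theta222"])
    return MeltingCurve(df["temp_C"].to_numpy(), df["theta222"].to_numpy())


def write_melting_curve(curve: MeltingCurve, path: str | Path) -> None:
    pd.DataFrame({"temp_C": curve.temperature, "theta222": curve.theta222}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_cd_spectrum(path: str | Path) -> CDSpectrum:
    df = read_table(path, ["wavelength_nm", "signal"])
    ht = df["ht_volts"].to_numpy() if "ht_volts" in df.columns else None
    return CDSpectrum(df["wavelength_nm"].to_numpy(), df["signal"].to_numpy(), ht_voltage=ht)


def scheme_from_config(source: str | Path | dict) -> AssemblyScheme:
    """Build a scheme from a YAML file or mapping.

    Either ``preset: <name>`` (with optional keyword overrides for the preset
    factory) or the explicit fields ``name, protomer_mass_kDa, tag_mass_kDa,
    base_unit, steps: [{order, kd_uM}, ...]``.
    """
    cfg = source if isinstance(source, dict) else yaml.safe_load(Path(source).read_text())
    if not isinstance(cfg, dict):
        raise ValidationError(f"scheme config must be a mapping, got {type(cfg).__name__}")
    cfg = dict(cfg)
    preset = cfg.pop("preset", None)
    if preset is not None:
        if preset not in PRESETS:
            raise ValidationError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
        return PRESETS[preset](**cfg)
    try:
        steps = [(int(s["order"]), float(s["kd_uM"])) for s in cfg.get("steps", [])]
        return build_scheme(
            str(cfg["name"]),
            float(cfg["protomer_mass_kDa"]),
            float(cfg.get("tag_mass_kDa", 0.0)),
            cfg.get("base_unit", "monomer"),
            steps,
        )
    except KeyError as exc:
        raise ValidationError(f"scheme config missing field {exc}") from exc


def scheme_to_config(scheme: AssemblyScheme) -> dict:
    return {
        "name": scheme.name,
        "protomer_mass_kDa": scheme.protomer_mass,
        "tag_mass_kDa": scheme.tag_mass,
        "base_unit": scheme.base_unit,
        "steps": [{"order": o, "kd_uM": k} for o, k in scheme.steps],
    }


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a fit report deterministically (sorted keys, plain YAML)."""
    Path(path).write_text(yaml.safe_dump(_plain(report), sort_keys=True))


def _plain(obj):
    """Recursively convert numpy scalars/arrays for clean YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj
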