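"""Readers and writers for the pipeline's tabular interfaces.

VOI statistics CSV (UTF-8, header required), one row per organ per scan:

    patient_id, organ, t_min, volume_ml, conc_Bq_per_ml, decay_corrected

Study configuration is YAML or JSON with at least
``administered_activity_MBq`` (scalar or per-patient mapping) and
``radionuclide``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .biokinetics import GA68, LU177, RadionuclideSpec, VoiSample

__all__ = [
    "read_voi_csv",
    "write_voi_csv",
    "voi_samples_by_patient",
    "read_study_config",
    "resolve_radionuclide",
]

VOI_COLUMNS = [
    "patient_id",
    "organ",
    "t_min",
    "volume_ml",
    "conc_Bq_per_ml",
    "decay_corrected",
]

_KNOWN_NUCLIDES = {"ga-68": GA68, "ga68": GA68, "lu-177": LU177, "lu177": LU177}


def read_voi_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in VOI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing VOI columns {missing}")
    if (df["volume_ml"] <= 0).any() or (df["conc_Bq_per_ml"] < 0).any():
        raise ValueError(f"{path}: non-physical volume or concentration")
    return df


def write_voi_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.8e", encoding="utf-8")


def voi_samples_by_patient(df: pd.DataFrame) -> dict[str, dict[str, list[VoiSample]]]:
    """Nest the VOI table as patient -> organ -> time-ordered samples."""
    out: dict[str, dict[str, list[VoiSample]]] = {}
    for row in df.itertuples(index=False):
        sample = VoiSample(
            organ=str(row.organ),
            t_h=float(row.t_min) / 60.0,
            volume_ml=float(row.volume_ml),
            conc_bq_per_ml=float(row.conc_Bq_per_ml),
            decay_corrected=bool(int(row.decay_corrected)),
        )
        out.setdefault(str(row.patient_id), {}).setdefault(sample.organ, []).append(sample)
    for organs in out.values():
        for samples in organs.values():
            samples.sort(key=lambda s: s.t_h)
    return out


def resolve_radionuclide(spec) -> RadionuclideSpec:
    """Accept a RadionuclideSpec, a known name, or {name, half_life_h}."""
    if isinstance(spec, RadionuclideSpec):
        return spec
    if isinstance(spec, str):
        key = spec.strip().lower()
        if key in _KNOWN_NUCLIDES:
            return _KNOWN_NUCLIDES[key]
        raise KeyError(f"unknown radionuclide {spec!r}; give name and half-life")
    return RadionuclideSpec(
        name=spec["name"], physical_half_life_h=float(spec["half_life_h"])
    )


def read_study_config(path) -> dict:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        if path.suffix in (".yaml", ".yml"):
            cfg = yaml.safe_load(fh)
        else:
            cfg = json.load(fh)
    if "administered_activity_MBq" not in cfg:
        raise ValueError(f"{path}: missing administered_activity_MBq")
    return cfg
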