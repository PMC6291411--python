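"""Access to the reference data shipped with the package.

Shipped as editable CSV/JSON rather than hard-coded constants:

* ``phantom_masses.csv`` — nominal reference-person organ masses (grams) for
  the NURBS-style adult male/female phantoms (``male_2.0``/``female_2.0``)
  and the older stylised adult male (``male_1.1``, whose pancreas is 94.3 g
  against 140 g in the newer phantom).
* ``icrp103.json`` / ``icrp60.json`` — tissue-weighting schemes: named w_T
  values plus a pooled-remainder rule.
* ``organ_aliases.json`` — organ-label alias table used for case- and
  vocabulary-insensitive matching between TIAC tables and S-value matrices.
* ``ga68_grpr_reference_doses.csv`` — published organ-absorbed doses
  (mGy/MBq) and effective doses (mSv/MBq) for a Ga-68-labelled GRPR
  antagonist in men, at 0.5-h and 1-h urinary voiding cycles, with
  extrapolations to the female phantom and the reference person; used as the
  worked-example input for delta reports and ED-share arithmetic.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = [
    "load_aliases",
    "load_phantom_masses",
    "load_weighting_scheme",
    "load_reference_doses",
    "normalize_organ",
]


def _data_path(name: str):
    return resources.files("mirdose.data").joinpath(name)


@lru_cache(maxsize=None)
def load_aliases() -> dict[str, str]:
    """Organ alias table mapping normalized variant labels to canonical ones."""
    with _data_path("organ_aliases.json").open("r", encoding="utf-8") as fh:
        return json.load(fh)


def normalize_organ(label: str) -> str:
    """Canonical organ key: lowercase, underscores, aliases applied."""
    key = label.strip().lower().replace("-", "_").replace(" ", "_")
    while "__" in key:
        key = key.replace("__", "_")
    return load_aliases().get(key, key)


def load_phantom_masses(phantom_id: str) -> dict[str, float]:
    """Organ masses (g) of one phantom, keyed by canonical organ label."""
    df = pd.read_csv(_data_path("phantom_masses.csv"))
    sub = df[df["phantom_id"] == phantom_id]
    if sub.empty:
        known = sorted(df["phantom_id"].unique())
        raise KeyError(f"unknown phantom {phantom_id!r}; known: {known}")
    return {normalize_organ(o): float(m) for o, m in zip(sub["organ"], sub["mass_g"])}


def load_weighting_scheme(scheme: str) -> dict:
    """Raw JSON dict of a shipped weighting scheme (``ICRP103``/``ICRP60``)."""
    name = scheme.lower() + ".json"
    try:
        with _data_path(name).open("r", encoding="utf-8") as fh:
            return json.load(fh)
    except FileNotFoundError:
        raise KeyError(f"no shipped weighting scheme {scheme!r}") from None


def load_reference_doses() -> pd.DataFrame:
    """Published Ga-68 GRPR-antagonist dose table, indexed by canonical organ."""
    df = pd.read_csv(_data_path("ga68_grpr_reference_doses.csv"))
    df["organ"] = df["organ"].map(normalize_organ)
    return df.set_index("organ")
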