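"""MIRD-schema absorbed doses and ICRP effective dose.

The MIRD schema computes the mean absorbed dose to a target region T as

    D_T = sum_s  tau_s * S(T <- s),

where ``tau_s`` is the time-integrated activity coefficient of source region
s (hours per unit administered activity) and ``S(T <- s)`` the radionuclide-
and phantom-specific dose-per-cumulated-activity kernel, here an explicit
CSV input in mGy/(MBq h).  Doses are therefore linear in every TIAC.

Effective dose is the tissue-weighted sum ED = sum_T w_T H_T with the
radiation weighting w_R = 1 for the photon/electron/positron emitters
shipped here, so H_T = D_T numerically (mSv/MBq vs mGy/MBq).  Two weighting
schemes ship as JSON: the current one (pancreas sits in a 14-tissue pooled
remainder, effective w_T about 0.0092) and the older one (10-tissue
remainder; with the historical most-exposed-tissue split the pancreas can
carry up to 0.025).  The reference-person ED averages the male and female
equivalent organ doses tissue by tissue before weighting.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .biokinetics import RadionuclideSpec, TiacTable
from .resources import normalize_organ

__all__ = [
    "SValueMatrix",
    "PhantomSpec",
    "TissueWeightingScheme",
    "DoseReport",
    "EffectiveDoseResult",
    "compute_organ_doses",
    "rescale_self_dose_for_mass",
    "compute_effective_dose",
    "female_extrapolation",
    "tissue_ed_share",
]

logger = logging.getLogger(__name__)

#: Tissues that exist in one sex only; they are dropped (not imputed) from
#: the other sex's remainder average.
SEX_SPECIFIC = {
    "testes": "male",
    "prostate": "male",
    "ovaries": "female",
    "uterus": "female",
}

#: Fallback neighbours for the ``nearest_organ`` missing-tissue policy.
_NEAREST = {
    "muscle": "total_body",
    "skin": "total_body",
    "lymphatic_nodes": "total_body",
    "oral_mucosa": "salivary_glands",
    "extrathoracic_region": "thyroid",
    "eyes": "brain",
    "breast": "lungs",
    "esophagus": "thymus",
    "bone_surfaces": "red_marrow",
    "uterus": "urinary_bladder_wall",
    "prostate": "urinary_bladder_wall",
}


@dataclass
class PhantomSpec:
    """An anthropomorphic phantom: id, sex and organ-mass table (grams)."""

    phantom_id: str
    masses_g: dict[str, float]
    sex: str

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        self.masses_g = {normalize_organ(k): float(v) for k, v in self.masses_g.items()}
        if any(m <= 0 for m in self.masses_g.values()):
            raise ValueError("organ masses must be positive")

    def mass(self, organ: str) -> float:
        return self.masses_g[normalize_organ(organ)]


class SValueMatrix:
    """Target x source S-value kernel, in mGy per (MBq h) in the source.

    Stored as a pandas DataFrame with canonical (alias-resolved, lowercase)
    organ labels on both axes.  The CSV dialect puts target organs in the
    first column and sources across the header, with ``#``-prefixed metadata
    lines carrying ``phantom_id`` and ``units``.
    """

    UNITS = "mGy/(MBq.h)"

    def __init__(self, table: pd.DataFrame, phantom_id: str):
        table = table.copy()
        table.index = [normalize_organ(str(t)) for t in table.index]
        table.columns = [normalize_organ(str(s)) for s in table.columns]
        if (table.values < 0).any():
            raise ValueError("S-values must be >= 0")
        self.table = table.astype(float)
        self.phantom_id = phantom_id

    @property
    def targets(self) -> list[str]:
        return list(self.table.index)

    @property
    def sources(self) -> list[str]:
        return list(self.table.columns)

    def s(self, target: str, source: str) -> float:
        return float(self.table.loc[normalize_organ(target), normalize_organ(source)])

    @classmethod
    def from_csv(cls, path) -> "SValueMatrix":
        meta: dict[str, str] = {}
        body: list[str] = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#"):
                    if "=" in line:
                        k, v = line[1:].split("=", 1)
                        meta[k.strip()] = v.strip()
                else:
                    body.append(line)
        if "phantom_id" not in meta:
            raise ValueError(f"{path}: missing '# phantom_id = ...' metadata line")
        units = meta.get("units")
        if units is None:
            raise ValueError(f"{path}: missing '# units = ...' metadata line")
        if units.replace(" ", "") != cls.UNITS:
            raise ValueError(f"{path}: S-value units {units!r}, expected {cls.UNITS}")
        df = pd.read_csv(io.StringIO("".join(body)), index_col=0)
        return cls(df, phantom_id=meta["phantom_id"])

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# phantom_id = {self.phantom_id}\n")
            fh.write(f"# units = {self.UNITS}\n")
            self.table.to_csv(fh)


@dataclass
class TissueWeightingScheme:
    """Named tissue weights plus a pooled remainder.

    ``remainder_rule`` is ``mean`` (arithmetic mean of remainder-tissue
    doses) or ``mass_weighted`` (requires a phantom).  ``composites`` maps a
    scheme tissue to report organs averaged to form it (e.g. colon from its
    segments).  Weights including the remainder must sum to 1.
    """

    scheme_id: str
    weights: dict[str, float]
    remainder_tissues: tuple[str, ...]
    remainder_weight: float
    remainder_rule: str = "mean"
    composites: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = {normalize_organ(k): float(v) for k, v in self.weights.items()}
        self.remainder_tissues = tuple(normalize_organ(t) for t in self.remainder_tissues)
        self.composites = {
            normalize_organ(k): tuple(normalize_organ(m) for m in v)
            for k, v in self.composites.items()
        }
        if self.remainder_rule not in ("mean", "mass_weighted", "most_exposed_split"):
            raise ValueError(f"unknown remainder rule {self.remainder_rule!r}")
        total = sum(self.weights.values()) + self.remainder_weight
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.scheme_id}: tissue weights sum to {total!r}, expected 1"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "TissueWeightingScheme":
        rem = d.get("remainder", {})
        return cls(
            scheme_id=d["scheme_id"],
            weights=dict(d["weights"]),
            remainder_tissues=tuple(rem.get("tissues", ())),
            remainder_weight=float(rem.get("weight", 0.0)),
            remainder_rule=rem.get("rule", "mean"),
            composites={k: tuple(v) for k, v in d.get("composites", {}).items()},
        )

    @classmethod
    def shipped(cls, scheme_id: str) -> "TissueWeightingScheme":
        from .resources import load_weighting_scheme

        return cls.from_dict(load_weighting_scheme(scheme_id))


@dataclass
class DoseReport:
    """Organ absorbed doses (mGy/MBq) with per-scheme EDs and metadata."""

    organ_doses: dict[str, float]
    sex: str
    radionuclide: RadionuclideSpec | None = None
    effective_doses: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.organ_doses = {
            normalize_organ(k): float(v) for k, v in self.organ_doses.items()
        }
        if any(d < 0 for d in self.organ_doses.values()):
            raise ValueError("absorbed doses must be >= 0")
        if any(e < 0 for e in self.effective_doses.values()):
            raise ValueError("effective doses must be >= 0")

    def dose(self, organ: str) -> float:
        return self.organ_doses[normalize_organ(organ)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_mGy_per_MBq": pd.Series(self.organ_doses).sort_index()}
        )


@dataclass
class EffectiveDoseResult:
    """Per-sex and reference-person effective doses in mSv/MBq."""

    scheme_id: str
    per_sex: dict[str, float]
    reference: float
    imputations: list[str] = field(default_factory=list)


def compute_organ_doses(tiacs: TiacTable, svalues: SValueMatrix) -> DoseReport:
    """MIRD dose sum D_T = sum_s tau_s S(T<-s) for every target in the kernel.

    Organ labels are matched case-insensitively through the alias table; a
    TIAC source missing from the kernel is an error, never silently dropped.
    """
    tau = {normalize_organ(k): v for k, v in tiacs.tiacs_h.items()}
    missing = [s for s in tau if s not in svalues.table.columns]
    if missing:
        raise KeyError(
            f"source organ(s) {missing} absent from S-value matrix "
            f"(phantom {svalues.phantom_id}; sources: {svalues.sources})"
        )
    tau_vec = pd.Series(0.0, index=svalues.table.columns)
    for s, v in tau.items():
        tau_vec[s] = v
    doses = svalues.table.values @ tau_vec.values
    sex = "female" if "female" in svalues.phantom_id else "male"
    return DoseReport(
        organ_doses=dict(zip(svalues.targets, doses)),
        sex=sex,
        radionuclide=tiacs.radionuclide,
        metadata={"phantom_id": svalues.phantom_id},
    )


def rescale_self_dose_for_mass(dose: float, m_from_g: float, m_to_g: float) -> float:
    """Inverse-mass rescaling of a self-dose-dominated organ dose.

    The self-absorbed dose of a (mostly non-penetrating) emitter scales as
    1/mass, so D' = D * m_from / m_to.  The caller is responsible for
    applying this only to organs whose dose is dominated by self-irradiation.
    """
    if not (m_from_g > 0 and m_to_g > 0):
        raise ValueError("masses must be positive")
    if m_from_g != m_to_g:
        logger.info(
            "rescaling self dose %.4g by mass ratio %.4g/%.4g", dose, m_from_g, m_to_g
        )
    return dose * m_from_g / m_to_g


def _tissue_dose(
    report: DoseReport,
    tissue: str,
    scheme: TissueWeightingScheme,
    policy: str,
    imputations: list[str],
) -> float | None:
    """Equivalent dose of one scheme tissue from a per-sex report.

    Returns None only for sex-specific tissues absent from this sex.
    Composites (e.g. colon) are the arithmetic mean of their member organs.
    """
    doses = report.organ_doses
    if tissue == "gonads":
        gonad = "testes" if report.sex == "male" else "ovaries"
        if gonad in doses:
            return doses[gonad]
        tissue = gonad  # fall through to imputation with an explicit name
    if tissue in SEX_SPECIFIC and SEX_SPECIFIC[tissue] != report.sex:
        return None
    if tissue in doses:
        return doses[tissue]
    if tissue in scheme.composites:
        members = [doses[m] for m in scheme.composites[tissue] if m in doses]
        if members:
            return float(np.mean(members))
    # imputation
    if policy == "zero":
        value = 0.0
    elif policy == "nearest_organ":
        neighbour = _NEAREST.get(tissue, "total_body")
        value = doses.get(neighbour, doses.get("total_body"))
        if value is None:
            raise KeyError(
                f"cannot impute {tissue}: neither {neighbour} nor total_body in report"
            )
    elif policy == "total_body":
        if "total_body" not in doses:
            raise KeyError(f"cannot impute {tissue}: no total_body dose in report")
        value = doses["total_body"]
    else:
        raise ValueError(f"unknown missing-tissue policy {policy!r}")
    msg = f"{report.sex}: tissue {tissue!r} imputed ({policy}) -> {value:.4g}"
    imputations.append(msg)
    logger.warning(msg)
    return value


def _scheme_tissue_doses(
    report: DoseReport,
    scheme: TissueWeightingScheme,
    policy: str,
    imputations: list[str],
) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for tissue in list(scheme.weights) + list(scheme.remainder_tissues):
        out[tissue] = _tissue_dose(report, tissue, scheme, policy, imputations)
    return out


def _ed_from_tissue_doses(
    tissue_doses: Mapping[str, float | None],
    scheme: TissueWeightingScheme,
    phantom: PhantomSpec | None,
) -> float:
    ed = 0.0
    for tissue, w in scheme.weights.items():
        h = tissue_doses[tissue]
        if h is None:
            raise ValueError(f"no dose available for weighted tissue {tissue!r}")
        ed += w * h
    rem = [(t, tissue_doses[t]) for t in scheme.remainder_tissues]
    rem = [(t, h) for t, h in rem if h is not None]
    if rem:
        if scheme.remainder_rule == "mass_weighted":
            if phantom is None:
                raise ValueError("mass_weighted remainder rule needs a phantom")
            ws = np.array([phantom.mass(t) for t, _ in rem])
            hs = np.array([h for _, h in rem])
            ed += scheme.remainder_weight * float(np.average(hs, weights=ws))
        elif scheme.remainder_rule == "most_exposed_split":
            # historical rule: when a remainder tissue is the most exposed
            # tissue of all, half the remainder weight goes to it and half
            # to the mean of the other remainder tissues
            named_max = max(
                (tissue_doses[t] for t in scheme.weights if tissue_doses[t] is not None),
                default=0.0,
            )
            top_tissue, top = max(rem, key=lambda th: th[1])
            rest = [h for t, h in rem if t != top_tissue]
            if top > named_max and rest:
                ed += scheme.remainder_weight * 0.5 * top
                ed += scheme.remainder_weight * 0.5 * float(np.mean(rest))
            else:
                ed += scheme.remainder_weight * float(np.mean([h for _, h in rem]))
        else:
            ed += scheme.remainder_weight * float(np.mean([h for _, h in rem]))
    return ed


def compute_effective_dose(
    male: DoseReport | None,
    female: DoseReport | None,
    scheme: TissueWeightingScheme,
    missing_tissue_policy: str = "total_body",
    phantom: PhantomSpec | None = None,
) -> EffectiveDoseResult:
    """Per-sex and reference-person effective dose under one scheme.

    Per-sex ED weights that sex's own tissue doses; the reference-person ED
    first averages the male and female equivalent doses tissue by tissue
    (using the available sex where a tissue exists in one sex only — gonads
    combine testes and ovaries) and then applies the weights.  Tissues
    absent from a report are imputed per ``missing_tissue_policy``
    (``total_body`` default, ``zero`` or ``nearest_organ``); every
    imputation is recorded in the result and logged at WARNING.
    """
    if male is None and female is None:
        raise ValueError("at least one per-sex dose report is required")
    imputations: list[str] = []
    per_sex: dict[str, float] = {}
    per_sex_tissues: dict[str, dict[str, float | None]] = {}
    for report in (male, female):
        if report is None:
            continue
        td = _scheme_tissue_doses(report, scheme, missing_tissue_policy, imputations)
        per_sex_tissues[report.sex] = td
        per_sex[report.sex] = _ed_from_tissue_doses(td, scheme, phantom)

    if len(per_sex_tissues) == 2:
        averaged: dict[str, float | None] = {}
        for tissue in list(scheme.weights) + list(scheme.remainder_tissues):
            vals = [
                td[tissue]
                for td in per_sex_tissues.values()
                if td[tissue] is not None
            ]
            averaged[tissue] = float(np.mean(vals)) if vals else None
        reference = _ed_from_tissue_doses(averaged, scheme, phantom)
    else:
        reference = next(iter(per_sex.values()))
    return EffectiveDoseResult(
        scheme_id=scheme.scheme_id,
        per_sex=per_sex,
        reference=reference,
        imputations=imputations,
    )


def female_extrapolation(
    tiacs_male: TiacTable, svalues_female: SValueMatrix
) -> DoseReport:
    """Apply male-derived TIACs to the female phantom kernel.

    Male-only source organs (prostate, testes) are dropped with a log entry;
    female-only targets (ovaries, uterus, breast) appear as targets through
    the female kernel.
    """
    kept: dict[str, float] = {}
    for organ, tau in tiacs_male.tiacs_h.items():
        canon = normalize_organ(organ)
        if SEX_SPECIFIC.get(canon) == "male":
            logger.info("female extrapolation: dropping male-only source %s", canon)
            continue
        kept[canon] = tau
    tiacs = TiacTable(
        tiacs_h=kept,
        radionuclide=tiacs_male.radionuclide,
        provenance=dict(tiacs_male.provenance),
    )
    report = compute_organ_doses(tiacs, svalues_female)
    report.sex = "female"
    return report


def tissue_ed_share(w_t: float, organ_dose: float, effective_dose: float) -> float:
    """Fraction of the ED contributed by one tissue: w_T * H_T / ED."""
    if effective_dose <= 0:
        raise ValueError("effective dose must be positive")
    return w_t * organ_dose / effective_dose
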