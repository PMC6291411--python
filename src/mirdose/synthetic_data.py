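"""Study-shaped synthetic inputs: organ kinetics, VOI tables, toy S-kernels.

The generator emulates a first-in-human PET dosimetry protocol: four
whole-body scans at 15, 45, 70 and 100 min after injection of about 113 MBq
of a Ga-68-labelled tracer, patients voiding on a 30-min cycle.  Ground
truth is mono-exponential washout for most organs (normalized activity
``a0 * exp(-lambda_bio t)`` before physical decay), a gallbladder still in
its biologic uptake phase at the last scan, marrow sampled at three skeletal
sites, and urine accumulating in the bladder between voids.  Emitted
concentrations are decay-corrected to injection time (as PET reconstructions
are) and carry multiplicative lognormal noise whose coefficient of variation
defaults to 5%, the order of the quantitative accuracy of a well-calibrated
Ga-68 PET system.

Default per-organ amplitudes are tuned so the noiseless TIACs land near the
residence times reported for a Ga-68 GRPR antagonist (pancreas 8.13e-2 h,
kidneys 2.14e-2 h, ...); they are fixture inputs that make the synthetic
cohort look like the study, not measured claims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biokinetics import GA68, RadionuclideSpec
from .dose_engine import PhantomSpec, SValueMatrix
from .resources import load_phantom_masses, normalize_organ

__all__ = [
    "OrganKinetics",
    "KineticScenario",
    "default_scenario",
    "generate_voi_table",
    "administered_activities",
    "generate_toy_svalue_matrix",
    "default_phantom",
]

#: study scan schedule, hours post injection (15/45/70/100 min)
SCAN_TIMES_H = (0.25, 0.75, 70.0 / 60.0, 100.0 / 60.0)

MARROW_SITE_ORGANS = {
    "red_marrow_humeral_head": 30.0,
    "red_marrow_femoral_heads": 60.0,
    "red_marrow_lumbar_L3_L4": 90.0,
}


@dataclass(frozen=True)
class OrganKinetics:
    """Ground-truth kinetics of one organ.

    ``washout`` organs follow a0*exp(-lambda_bio*t) (decay-corrected scale);
    ``uptake`` organs follow a0*(1 - exp(-uptake_rate*t)), monotonically
    increasing over the scan window.
    """

    a0: float
    rate_per_h: float
    mode: str = "washout"
    volume_ml: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("washout", "uptake"):
            raise ValueError(f"unknown kinetic mode {self.mode!r}")
        if self.a0 < 0 or self.volume_ml <= 0:
            raise ValueError("a0 must be >= 0 and volume positive")

    def a_bio(self, t: np.ndarray) -> np.ndarray:
        """Decay-corrected normalized activity at times t (hours)."""
        t = np.asarray(t, dtype=float)
        if self.mode == "washout":
            return self.a0 * np.exp(-self.rate_per_h * t)
        return self.a0 * (1.0 - np.exp(-self.rate_per_h * t))


@dataclass(frozen=True)
class KineticScenario:
    """Complete description of one synthetic dosimetry study."""

    organs: dict[str, OrganKinetics]
    urinary_components: tuple[tuple[float, float], ...]
    administered_activity_mbq: float = 113.0
    administered_activity_sd_mbq: float = 21.0
    scan_times_h: tuple[float, ...] = SCAN_TIMES_H
    noise_cv: float = 0.05
    seed: int = 0
    n_patients: int = 5
    radionuclide: RadionuclideSpec = GA68
    acquisition_voiding_interval_h: float = 0.5
    bladder_volume_ml: float = 150.0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if sum(f for f, _ in self.urinary_components) > 1 + 1e-9:
            raise ValueError("urinary excreted fractions sum to more than 1")
        total_a0 = sum(
            k.a0 for name, k in self.organs.items()
            if normalize_organ(name) != "total_body"
        )
        if total_a0 > 1 + 1e-9:
            raise ValueError(f"organ a0 fractions sum to {total_a0:.3f} > 1")


def default_scenario(seed: int = 0, noise_cv: float = 0.05, n_patients: int = 5) -> KineticScenario:
    """The study-like default: abdominal-dominant washout, uptake gallbladder.

    Amplitudes chosen so a0/lambda_eff matches the reference residence
    times; biologic rates are plausible tracer clearances (0.02-0.2 /h).
    """
    lp = GA68.lambda_phys

    def washout(tau_h: float, lambda_bio: float, volume_ml: float) -> OrganKinetics:
        return OrganKinetics(
            a0=tau_h * (lambda_bio + lp),
            rate_per_h=lambda_bio,
            mode="washout",
            volume_ml=volume_ml,
        )

    organs = {
        "pancreas": washout(8.13e-2, 0.05, 140.0),
        "kidneys": washout(2.14e-2, 0.10, 310.0),
        "liver": washout(3.79e-2, 0.05, 1800.0),
        "spleen": washout(3.16e-3, 0.10, 150.0),
        "lungs": washout(2.88e-2, 0.20, 1200.0),
        "heart_wall": washout(2.16e-2, 0.15, 330.0),
        "brain": washout(1.53e-3, 0.05, 1450.0),
        "thyroid": washout(3.20e-4, 0.10, 20.0),
        "adrenals": washout(2.48e-4, 0.10, 14.0),
        "stomach_wall": washout(4.79e-3, 0.10, 150.0),
        "small_intestine": washout(4.01e-2, 0.02, 650.0),
        "colon": washout(2.695e-2, 0.02, 370.0),
        "gallbladder_contents": OrganKinetics(
            a0=3.5e-3, rate_per_h=1.2, mode="uptake", volume_ml=30.0
        ),
        "total_body": washout(1.43, 0.05, 73000.0),
    }
    # marrow sites share the study's per-gram kinetics: total marrow TIAC
    # 7.1e-3 h over 1170 g of red marrow
    tau_per_g = 7.1e-3 / 1170.0
    for site, vol in MARROW_SITE_ORGANS.items():
        organs[site] = washout(tau_per_g, 0.05, vol)
    return KineticScenario(
        organs=organs,
        urinary_components=((0.7, 0.6),),
        seed=seed,
        noise_cv=noise_cv,
        n_patients=n_patients,
    )


def administered_activities(scenario: KineticScenario) -> dict[str, float]:
    """Per-patient administered activities (MBq), deterministic in the seed."""
    rng = np.random.default_rng(scenario.seed)
    acts = rng.normal(
        scenario.administered_activity_mbq,
        scenario.administered_activity_sd_mbq,
        size=scenario.n_patients,
    )
    acts = np.clip(acts, 10.0, None)
    return {f"P{i + 1:02d}": float(a) for i, a in enumerate(acts)}


def _bladder_bio_content(scenario: KineticScenario, t: float) -> float:
    """Decay-corrected bladder content fraction at scan time t.

    Within the voiding cycle containing t (voids every T_v), the
    decay-corrected content is sum_i f_i (exp(-l_i t_k) - exp(-l_i t)) with
    t_k the last void before t.
    """
    tv = scenario.acquisition_voiding_interval_h
    t_k = math.floor(t / tv) * tv
    return sum(
        f * (math.exp(-li * t_k) - math.exp(-li * t))
        for f, li in scenario.urinary_components
    )


def generate_voi_table(scenario: KineticScenario) -> pd.DataFrame:
    """Emit the VOI-statistics table of a synthetic patient cohort.

    One row per patient, organ and scan time with columns ``patient_id,
    organ, t_min, volume_ml, conc_Bq_per_ml, decay_corrected``.
    Concentrations are decay-corrected to injection (flag 1), so organ
    quantification with the decay-undo flag recovers the physical curve
    a0*exp(-lambda_eff t) up to the multiplicative noise.  Identical seeds
    give byte-identical tables.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    activities = administered_activities(scenario)
    sigma = math.sqrt(math.log(1.0 + scenario.noise_cv**2))
    rows = []
    for pid, a_mbq in activities.items():
        for organ, kin in scenario.organs.items():
            per_gram = organ in MARROW_SITE_ORGANS
            for t in scenario.scan_times_h:
                a_bio = float(kin.a_bio(np.array([t]))[0])
                # marrow-site kinetics are per gram of tissue; at unit
                # density that is directly a per-mL concentration
                conc = a_bio * a_mbq * 1e6 / (1.0 if per_gram else kin.volume_ml)
                if sigma > 0:
                    conc *= math.exp(rng.normal(0.0, sigma) - 0.5 * sigma**2)
                rows.append((pid, organ, t * 60.0, kin.volume_ml, conc, 1))
        if scenario.urinary_components:
            for t in scenario.scan_times_h:
                a_bio = _bladder_bio_content(scenario, t)
                conc = a_bio * a_mbq * 1e6 / scenario.bladder_volume_ml
                if sigma > 0:
                    conc *= math.exp(rng.normal(0.0, sigma) - 0.5 * sigma**2)
                rows.append(
                    (pid, "urinary_bladder_contents", t * 60.0,
                     scenario.bladder_volume_ml, conc, 1)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "organ", "t_min", "volume_ml",
            "conc_Bq_per_ml", "decay_corrected",
        ],
    )


def default_phantom(phantom_id: str = "male_2.0") -> PhantomSpec:
    """PhantomSpec loaded from the shipped reference mass table."""
    sex = "female" if phantom_id.startswith("female") else "male"
    return PhantomSpec(
        phantom_id=phantom_id, masses_g=load_phantom_masses(phantom_id), sex=sex
    )


#: content sources irradiate their wall with this fraction of the wall's
#: inverse-mass self term
_CONTENT_TO_WALL = {
    "urinary_bladder_contents": "urinary_bladder_wall",
    "gallbladder_contents": "gallbladder_wall",
}

#: hollow organs whose residence time includes the luminal content; the wall
#: sees that content on top of the plain inverse-mass self term
_HOLLOW_SELF_BOOST = {
    "small_intestine": 1.45,
    "right_colon": 1.4,
    "left_colon": 1.4,
    "rectum": 1.4,
    "stomach_wall": 1.25,
}


def generate_toy_svalue_matrix(
    phantom: PhantomSpec,
    seed: int = 0,
    self_dose_g: float = 450.0,
    cross_scale: float = 0.02,
) -> SValueMatrix:
    """A physically plausible toy S-kernel for the phantom's organ set.

    Self-dose follows the inverse-mass law S(T<-T) = self_dose_g / m_T;
    cross-doses are c*exp(-d(T,s)) with a deterministic random symmetric
    organ-distance table (d uniform on [0, 3]); content sources deposit a
    fixed fraction of the wall's self term into their wall.  All entries are
    positive and reproducible for a fixed seed.  The default self-dose
    constant is sized so a Ga-68-like emitter gives tens to hundreds of
    uGy/MBq for abdominal organs.
    """
    organs = [o for o in sorted(phantom.masses_g) if o != "total_body"]
    missing = [o for o in organs if phantom.masses_g[o] <= 0]
    if missing:
        raise ValueError(f"non-positive masses for {missing}")
    rng = np.random.default_rng(seed)
    n = len(organs)
    d = rng.uniform(0.0, 3.0, size=(n, n))
    d = (d + d.T) / 2.0

    s = cross_scale * np.exp(-d)
    for i, organ in enumerate(organs):
        s[i, i] = (
            self_dose_g / phantom.masses_g[organ]
            * _HOLLOW_SELF_BOOST.get(organ, 1.0)
        )
    table = pd.DataFrame(s, index=organs, columns=organs)

    # content sources: wall gets a near-surface fraction of its self term,
    # other organs see content like they would see the wall
    for content, wall in _CONTENT_TO_WALL.items():
        if wall in table.index:
            col = table[wall] * 0.5
            col.loc[wall] = 0.09 * self_dose_g / phantom.masses_g[wall]
            table[content] = col

    # total-body target: uniform dilution over the whole-body mass
    tb_mass = phantom.masses_g.get("total_body", float(sum(phantom.masses_g.values())))
    table.loc["total_body"] = self_dose_g / tb_mass
    return SValueMatrix(table, phantom_id=phantom.phantom_id)
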