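"""Special source-organ constructions: red marrow, colon, urinary bladder.

Red marrow activity cannot be measured as one VOI; instead small marrow
samples are drawn at three skeletal sites (humeral head, femoral heads,
lumbar vertebrae L3-L4), each yielding a normalized activity concentration
per gram of marrow.  Site TIACs-per-gram are averaged and scaled by the
reference phantom's total red marrow mass.

The colon is measured as a single region and its TIAC partitioned to right
colon, left colon and rectum proportionally to reference segment masses.

The urinary bladder content follows a dynamic voiding model: urine flows in
from body compartments clearing with biologic rate constants, the content
decays physically, and the bladder is emptied every ``T_v`` hours.  The
bladder-content TIAC grows with the voiding interval and is bounded above by
the no-voiding integral.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .biokinetics import (
    DegenerateCurveError,
    OrganCurve,
    RadionuclideSpec,
    tiac_auto,
)

__all__ = [
    "MarrowVoiSet",
    "BladderModelParams",
    "red_marrow_tiac",
    "partition_colon",
    "bladder_content_tiac",
    "rescaled_bladder_tiac",
]

logger = logging.getLogger(__name__)

MARROW_SITES = ("humeral_head", "femoral_heads", "lumbar_L3_L4")


@dataclass
class MarrowVoiSet:
    """Marrow-site concentration curves plus the reference red marrow mass.

    ``site_curves`` maps site name to an ordered sequence of
    ``(t_hours, normalized activity per gram)`` pairs.  Three sites are
    expected; fewer are accepted with a warning.
    """

    site_curves: dict[str, tuple[tuple[float, float], ...]]
    red_marrow_mass_g: float

    def __post_init__(self) -> None:
        if not self.red_marrow_mass_g > 0:
            raise ValueError("red marrow mass must be positive")
        if not self.site_curves:
            raise ValueError("no marrow site curves given")
        if len(self.site_curves) < 3:
            logger.warning(
                "marrow VOI set has %d site(s), 3 expected (%s)",
                len(self.site_curves),
                ", ".join(MARROW_SITES),
            )


def red_marrow_tiac(
    voi_set: MarrowVoiSet, radionuclide: RadionuclideSpec
) -> float:
    """Red marrow TIAC: mean site TIAC-per-gram times reference marrow mass.

    Each site curve is fitted and integrated exactly like an organ curve
    (mono-exponential with trapezoid fallback); the per-gram TIACs are
    averaged across sites and multiplied by the phantom red marrow mass.
    """
    per_gram = []
    for site, pts in voi_set.site_curves.items():
        curve = OrganCurve(
            organ=f"red_marrow:{site}", points=tuple(pts), administered_activity_mbq=1.0
        )
        try:
            tau_g, _, _ = tiac_auto(curve, radionuclide)
        except DegenerateCurveError:
            logger.warning("marrow site %s unusable, skipped", site)
            continue
        per_gram.append(tau_g)
    if not per_gram:
        raise DegenerateCurveError("no usable marrow site curves")
    return float(np.mean(per_gram)) * voi_set.red_marrow_mass_g


def partition_colon(
    total_colon_tiac_h: float, segment_masses_g: dict[str, float]
) -> dict[str, float]:
    """Split a whole-colon TIAC across segments proportionally to mass.

    The partition conserves the total exactly: tau_seg = tau * m_seg / sum(m).
    """
    if total_colon_tiac_h < 0:
        raise ValueError("total colon TIAC must be >= 0")
    if any(m <= 0 for m in segment_masses_g.values()):
        raise ValueError("segment masses must be positive")
    total_mass = sum(segment_masses_g.values())
    if total_mass <= 0:
        raise ValueError("total colon mass is zero")
    return {
        seg: total_colon_tiac_h * m / total_mass
        for seg, m in segment_masses_g.items()
    }


@dataclass
class BladderModelParams:
    """Parameters of the dynamic urinary-bladder voiding model.

    ``components`` lists (fraction of administered activity excreted in
    urine, biologic rate constant 1/h) pairs describing flow from the body
    into the bladder; the bladder is voided every ``voiding_interval_h``
    hours. ``initial_content_fraction`` is the bladder content at t=0
    (normally 0: nothing has been excreted at injection).
    """

    voiding_interval_h: float
    components: tuple[tuple[float, float], ...]
    radionuclide: RadionuclideSpec
    initial_content_fraction: float = 0.0
    step_h: float = 0.002

    def __post_init__(self) -> None:
        if not self.voiding_interval_h > 0:
            raise ValueError("voiding interval must be positive")
        if not self.components:
            raise ValueError("at least one excretion component required")
        if any(lam <= 0 for _, lam in self.components):
            raise ValueError("biologic rate constants must be positive")
        if any(f < 0 for f, _ in self.components):
            raise ValueError("excreted fractions must be >= 0")
        if sum(f for f, _ in self.components) > 1 + 1e-9:
            raise ValueError("excreted fractions sum to more than 1")
        if not self.step_h > 0:
            raise ValueError("integration step must be positive")


def _bladder_content_on_grid(
    params: BladderModelParams, t_start: float, b_start: float, tt: np.ndarray
) -> np.ndarray:
    """Exact bladder content on a time grid within one voiding cycle.

    With content ``b_start`` at ``t_start`` and inflow rate
    sum_i f_i lambda_i exp(-(lambda_i + lambda_phys) t) (per unit
    administered activity), the content at t >= t_start is

        B(t) = b_start e^{-lp (t-t_start)}
             + sum_i f_i (e^{-li t_start} - e^{-li t}) e^{-lp t},

    i.e. everything excreted since the last void, physically decayed.
    """
    lp = params.radionuclide.lambda_phys
    b = b_start * np.exp(-lp * (tt - t_start))
    for f, li in params.components:
        b = b + f * (math.exp(-li * t_start) - np.exp(-li * tt)) * np.exp(-lp * tt)
    return b


def bladder_content_tiac(params: BladderModelParams) -> float:
    """TIAC of the bladder content under periodic voiding, in hours.

    Content is evaluated in closed form on a fixed grid within each voiding
    cycle, integrated by the trapezoid rule, and reset to zero at every void.
    Cycles are accumulated until the remaining urine inflow is negligible.
    The result converges as ``step_h`` shrinks and is bounded above by the
    no-voiding integral sum_i f_i lambda_i / ((lambda_i+lambda_phys) lambda_phys).
    """
    tv = params.voiding_interval_h
    lp = params.radionuclide.lambda_phys
    n_sub = max(2, int(math.ceil(tv / params.step_h)) + 1)

    total = 0.0
    b_start = params.initial_content_fraction
    t_start = 0.0
    min_rate = min(li for _, li in params.components)
    # inflow decays at least as fast as exp(-(min_rate+lp) t): cap the horizon
    horizon = 40.0 / (min_rate + lp)
    while t_start < horizon:
        tt = np.linspace(t_start, t_start + tv, n_sub)
        b = _bladder_content_on_grid(params, t_start, b_start, tt)
        total += float(np.trapezoid(b, tt))
        b_start = 0.0  # void
        t_start += tv
    return total


def rescaled_bladder_tiac(
    measured_tiac_h: float,
    acquisition_interval_h: float,
    params: BladderModelParams,
    requested_interval_h: float,
) -> float:
    """Extrapolate a measured bladder TIAC to another voiding interval.

    The dynamic model fixes the *shape* of the voiding-interval dependence;
    the measured TIAC anchors its scale.  At the acquisition's own interval
    the measurement is returned unchanged.
    """
    if measured_tiac_h < 0:
        raise ValueError("measured TIAC must be >= 0")
    if requested_interval_h == acquisition_interval_h:
        return measured_tiac_h
    from dataclasses import replace

    ref = bladder_content_tiac(replace(params, voiding_interval_h=acquisition_interval_h))
    new = bladder_content_tiac(replace(params, voiding_interval_h=requested_interval_h))
    if ref <= 0:
        raise ValueError("model TIAC at acquisition interval is zero; cannot rescale")
    return measured_tiac_h * new / ref
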