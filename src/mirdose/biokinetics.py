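"""Organ biokinetics: time-activity curves, mono-exponential fits, TIACs.

The raw material of image-based internal dosimetry is the fraction of the
administered activity found in each source organ at each scan time,

    a(t) = C(t) * V / A_inj,

with ``C`` the mean activity concentration in the organ VOI (Bq/mL), ``V``
the VOI volume (mL) and ``A_inj`` the administered activity (Bq).  For
organs in washout the curve is summarised by a mono-exponential
``a0 * exp(-lambda_eff * t)`` fitted by nonlinear least squares on the
untransformed activities, and the time-integrated activity coefficient
(TIAC, also called residence time) follows in closed form as
``tau = a0 / lambda_eff`` hours.  Organs still in their uptake phase at the
last scan (the gallbladder in a 2-h protocol) get a conservative
trapezoid-plus-physical-decay-tail integration instead.

All times are hours internally; readers convert from minutes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RadionuclideSpec",
    "GA68",
    "LU177",
    "VoiSample",
    "OrganCurve",
    "KineticFit",
    "TiacTable",
    "DegenerateCurveError",
    "DivergentIntegralError",
    "quantify_organ_activity",
    "fit_monoexponential",
    "tiac_from_fit",
    "tiac_trapezoid_tail",
    "tiac_auto",
    "substitute_radionuclide",
]

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


class DegenerateCurveError(ValueError):
    """Raised when a time-activity curve cannot support a kinetic fit."""


class DivergentIntegralError(ValueError):
    """Raised when the 0..infinity integral of a fit diverges (lambda_eff <= 0)."""


@dataclass(frozen=True)
class RadionuclideSpec:
    """A radionuclide identified by name and physical half-life in hours."""

    name: str
    physical_half_life_h: float

    def __post_init__(self) -> None:
        if not self.physical_half_life_h > 0:
            raise ValueError(
                f"physical half-life must be positive, got {self.physical_half_life_h}"
            )

    @property
    def lambda_phys(self) -> float:
        """Physical decay constant ln(2)/T_half in 1/h."""
        return LN2 / self.physical_half_life_h


#: Ga-68, positron emitter used for receptor PET (T_half 67.71 min).
GA68 = RadionuclideSpec("Ga-68", 67.71 / 60.0)
#: Lu-177, beta-emitting therapeutic partner (T_half 6.647 d).
LU177 = RadionuclideSpec("Lu-177", 6.647 * 24.0)


@dataclass(frozen=True)
class VoiSample:
    """One VOI measurement: organ, time post injection, volume, concentration.

    ``decay_corrected`` states whether the concentration was decay-corrected
    to injection time by the scanner software; the flag is explicit and never
    guessed.
    """

    organ: str
    t_h: float
    volume_ml: float
    conc_bq_per_ml: float
    decay_corrected: bool = False

    def __post_init__(self) -> None:
        if self.t_h < 0:
            raise ValueError(f"time post injection must be >= 0, got {self.t_h}")
        if not self.volume_ml > 0:
            raise ValueError(f"VOI volume must be positive, got {self.volume_ml}")
        if self.conc_bq_per_ml < 0:
            raise ValueError(f"concentration must be >= 0, got {self.conc_bq_per_ml}")


@dataclass(frozen=True)
class OrganCurve:
    """Normalized organ time-activity curve a(t) = A_organ(t) / A_administered.

    ``points`` is an ordered tuple of ``(t_hours, fraction)`` pairs with
    strictly increasing times.  Whole-body curves should satisfy a(t) <= 1 up
    to measurement noise (a 10% headroom is tolerated).
    """

    organ: str
    points: tuple[tuple[float, float], ...]
    administered_activity_mbq: float

    def __post_init__(self) -> None:
        times = [t for t, _ in self.points]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"{self.organ}: times must be strictly increasing")
        if any(a < 0 for _, a in self.points):
            raise ValueError(f"{self.organ}: normalized activities must be >= 0")
        if self.organ.lower().replace(" ", "_") in ("whole_body", "total_body"):
            if any(a > 1.1 for _, a in self.points):
                raise ValueError(
                    f"{self.organ}: whole-body fraction exceeds 1.1 "
                    "(more activity than administered)"
                )

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points], dtype=float)

    @property
    def activities(self) -> np.ndarray:
        return np.array([a for _, a in self.points], dtype=float)


@dataclass(frozen=True)
class KineticFit:
    """Mono-exponential fit a0*exp(-lambda_eff*t) of one organ curve.

    ``lambda_bio = lambda_eff - lambda_phys`` is the clearance attributable
    to physiology alone; it is negative for organs with net biologic uptake.
    ``mode`` records whether the TIAC should come from the closed-form
    integral (``monoexp``) or the conservative trapezoid-with-tail rule
    (``trapezoid_tail``).
    """

    organ: str
    a0: float
    lambda_eff: float
    r_squared: float
    radionuclide: RadionuclideSpec
    mode: str = "monoexp"

    def __post_init__(self) -> None:
        if self.a0 < 0:
            raise ValueError(f"{self.organ}: a0 must be >= 0, got {self.a0}")
        if self.r_squared > 1 + 1e-12:
            raise ValueError(f"{self.organ}: r_squared cannot exceed 1")
        if self.mode not in ("monoexp", "trapezoid_tail"):
            raise ValueError(f"unknown fit mode {self.mode!r}")

    @property
    def lambda_bio(self) -> float:
        """Biologic decay constant (1/h); exactly lambda_eff - lambda_phys."""
        return self.lambda_eff - self.radionuclide.lambda_phys


@dataclass
class TiacTable:
    """Per-source-organ time-integrated activity coefficients, in hours.

    ``provenance`` records how each value was obtained (monoexp fit,
    trapezoid, marrow model, bladder model, ...).
    """

    tiacs_h: dict[str, float]
    radionuclide: RadionuclideSpec
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for organ, tau in self.tiacs_h.items():
            if tau < 0:
                raise ValueError(f"{organ}: TIAC must be >= 0, got {tau}")

    def check_physical_bound(self) -> None:
        """Assert the sum over disjoint sources respects 1/lambda_phys.

        An activity fraction bounded by 1 cannot accumulate more than
        1/lambda_phys decays-per-administered-decay (1.628 h for Ga-68).
        """
        bound = 1.0 / self.radionuclide.lambda_phys
        total = sum(self.tiacs_h.values())
        if total > bound * (1 + 1e-9):
            raise ValueError(
                f"sum of TIACs {total:.4g} h exceeds physical bound {bound:.4g} h"
            )


def quantify_organ_activity(
    samples: Sequence[VoiSample],
    administered_activity_mbq: float,
    radionuclide: RadionuclideSpec,
    undo_decay_correction: bool = False,
) -> OrganCurve:
    """Convert VOI samples of one organ into a normalized time-activity curve.

    a(t_i) = conc_i * volume_i / (A_inj * 1e6).  When the input was
    decay-corrected to injection time and ``undo_decay_correction`` is set,
    each point is multiplied by exp(-lambda_phys * t_i) so the curve reflects
    the physical activity actually present in the organ.
    """
    if not administered_activity_mbq > 0:
        raise ValueError(
            f"administered activity must be positive, got {administered_activity_mbq}"
        )
    if not samples:
        raise ValueError("no VOI samples given")
    organs = {s.organ for s in samples}
    if len(organs) != 1:
        raise ValueError(f"samples mix organs: {sorted(organs)}")
    times = [s.t_h for s in samples]
    if len(set(times)) != len(times):
        raise ValueError(f"{samples[0].organ}: duplicate timepoints")

    lam = radionuclide.lambda_phys
    pts = []
    for s in sorted(samples, key=lambda s: s.t_h):
        a = s.conc_bq_per_ml * s.volume_ml / (administered_activity_mbq * 1e6)
        if s.decay_corrected and undo_decay_correction:
            a *= math.exp(-lam * s.t_h)
        pts.append((s.t_h, a))
    return OrganCurve(
        organ=samples[0].organ,
        points=tuple(pts),
        administered_activity_mbq=administered_activity_mbq,
    )


def _r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - np.mean(obs)) ** 2))
    if ss_tot == 0.0:
        # constant data: perfect fit iff residuals vanish
        return 1.0 if ss_res == 0.0 else -math.inf
    return 1.0 - ss_res / ss_tot


def fit_monoexponential(
    curve: OrganCurve,
    radionuclide: RadionuclideSpec,
    weighting: str = "relative",
) -> KineticFit:
    """Least-squares mono-exponential fit on untransformed activities.

    ``weighting="relative"`` (default) assumes measurement errors
    proportional to the signal — the error structure of quantitative PET
    concentrations — by weighting each residual with 1/a(t_i);
    ``weighting="equal"`` is plain unweighted least squares.  R^2 is always
    computed unweighted on the activity scale.  Raises
    :class:`DegenerateCurveError` for all-zero curves or fewer than two
    positive points.
    """
    if weighting not in ("relative", "equal"):
        raise ValueError(f"unknown weighting {weighting!r}")
    t = curve.times
    a = curve.activities
    pos = a > 0
    if int(pos.sum()) < 2:
        raise DegenerateCurveError(
            f"{curve.organ}: need >= 2 positive activities to fit, "
            f"got {int(pos.sum())}"
        )

    # log-linear start values from the positive points
    slope, intercept = np.polyfit(t[pos], np.log(a[pos]), 1)
    p0 = (float(np.exp(intercept)), float(-slope))

    def model(tt: np.ndarray, a0: float, lam: float) -> np.ndarray:
        return a0 * np.exp(-lam * tt)

    sigma = None
    if weighting == "relative":
        sigma = np.where(pos, a, a[pos].min())  # floor keeps zeros finite

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(model, t, a, p0=p0, sigma=sigma, maxfev=20000)
    a0, lam = float(popt[0]), float(popt[1])
    if a0 < 0:  # sign-degenerate optimum; clamp to the boundary
        a0 = 0.0
    r2 = _r_squared(a, model(t, a0, lam))
    return KineticFit(
        organ=curve.organ,
        a0=a0,
        lambda_eff=lam,
        r_squared=r2,
        radionuclide=radionuclide,
    )


def tiac_from_fit(fit: KineticFit) -> float:
    """Closed-form TIAC of a mono-exponential fit: tau = a0 / lambda_eff (h)."""
    if fit.mode != "monoexp":
        raise ValueError(f"{fit.organ}: closed-form TIAC needs a monoexp fit")
    if not fit.lambda_eff > 0:
        raise DivergentIntegralError(
            f"{fit.organ}: lambda_eff = {fit.lambda_eff:.4g} /h <= 0, the "
            "integral to infinity diverges; use the trapezoid-tail rule"
        )
    return fit.a0 / fit.lambda_eff


def tiac_trapezoid_tail(
    curve: OrganCurve, radionuclide: RadionuclideSpec
) -> float:
    """Trapezoidal TIAC over the scan window plus a physical-decay tail.

    The first segment assumes a(0) = 0 (no activity in any organ at
    injection); beyond the last measurement the activity is integrated
    analytically assuming physical decay only, tau_tail = a_last/lambda_phys.
    This is deliberately conservative for uptake-phase organs: no biologic
    clearance of the organ content is modelled.
    """
    t = curve.times
    a = curve.activities
    if t.size == 0:
        raise DegenerateCurveError(f"{curve.organ}: empty curve")
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        a = np.concatenate([[0.0], a])
    body = float(np.trapezoid(a, t))
    tail = float(a[-1]) / radionuclide.lambda_phys
    return body + tail


def tiac_auto(
    curve: OrganCurve, radionuclide: RadionuclideSpec
) -> tuple[float, KineticFit | None, str]:
    """Fit-then-integrate with automatic fallback to the trapezoid rule.

    Returns ``(tau, fit_or_None, provenance)``.  Curves whose fitted
    lambda_eff <= 0 (net uptake over the scan window) fall back to
    :func:`tiac_trapezoid_tail` with a logged warning, mirroring how an
    uptake-phase gallbladder is handled in a 2-h protocol.
    """
    try:
        fit = fit_monoexponential(curve, radionuclide)
    except DegenerateCurveError:
        if np.all(curve.activities == 0):
            return 0.0, None, "all-zero curve"
        logger.warning("%s: degenerate curve, using trapezoid+tail", curve.organ)
        return tiac_trapezoid_tail(curve, radionuclide), None, "trapezoid_tail (degenerate)"
    if fit.lambda_eff > 0:
        return tiac_from_fit(fit), fit, "monoexp fit"
    logger.warning(
        "%s: fitted lambda_eff = %.4g /h <= 0 (uptake phase), "
        "falling back to trapezoid+physical-decay tail (largely conservative)",
        curve.organ,
        fit.lambda_eff,
    )
    fit = replace(fit, mode="trapezoid_tail")
    return (
        tiac_trapezoid_tail(curve, radionuclide),
        fit,
        "trapezoid_tail (uptake phase, largely conservative)",
    )


def substitute_radionuclide(
    fit: KineticFit, old: RadionuclideSpec, new: RadionuclideSpec
) -> KineticFit:
    """Re-express a fit under another radionuclide, keeping biology fixed.

    The biologic clearance lambda_bio is a property of the tracer molecule
    and is carried over unchanged; the new effective constant is
    lambda_bio + lambda_phys(new).  Used to extrapolate diagnostic Ga-68
    kinetics to a theoretical Lu-177-labelled compound.
    """
    if fit.radionuclide != old:
        raise ValueError(
            f"fit was derived under {fit.radionuclide.name}, not {old.name}"
        )
    new_lambda_eff = fit.lambda_bio + new.lambda_phys
    if not new_lambda_eff > 0 and fit.mode == "monoexp":
        raise DivergentIntegralError(
            f"{fit.organ}: substituting {new.name} gives lambda_eff = "
            f"{new_lambda_eff:.4g} /h <= 0 (net biologic uptake); the "
            "infinite integral diverges"
        )
    return replace(fit, lambda_eff=new_lambda_eff, radionuclide=new)
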