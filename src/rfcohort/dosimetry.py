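"""Closed-form far-field dosimetry for caged-rodent RF exposure.

The exposure source is a single antenna radiating a 2.4 GHz 5G NR downlink
signal at an animal cage placed on the boresight axis.  In the far field
(beyond roughly one free-space wavelength for a combined electric/magnetic
dipole) the incident power density follows the inverse-square law

    S(r) = P_A * g / (4 * pi * r**2)          [W/m^2]

where ``P_A`` is the power delivered to the antenna input in watts and
``g = 10**(G_dB/10)`` the linearised antenna gain.  Whole-body averaged SAR
for an unrestrained cohort is estimated from the empirical scaling

    SAR_wb = (k / f_GHz) * <S> * <L> / <m>    [W/kg]

with ``<S>`` the incident power density averaged over the cage-occupiable
interval along the beam axis, ``<L>`` the cohort-mean animal length in
metres, ``<m>`` the cohort-mean body mass in kilograms, and ``k`` a
dimensionless coefficient (default ``5.954e-2``, see
:class:`DosimetryConstants`).  Reflections and multiple scattering inside
the room are deliberately ignored; the model is a free-space estimate.

Compliance is assessed against the ICNIRP whole-body limits
(0.08 W/kg SAR; 10 W/m^2 reference power density).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

__all__ = [
    "AntennaSpec",
    "ExposureScenario",
    "DosimetryConstants",
    "SarSummary",
    "ComplianceLimits",
    "ComplianceReport",
    "FarFieldWarning",
    "db_to_linear",
    "incident_power_density",
    "far_field_distance",
    "averaged_incident_power_density",
    "whole_body_sar",
    "sar_range",
    "icnirp_check",
]

_FOUR_PI = 4.0 * math.pi


class FarFieldWarning(UserWarning):
    """The cage near edge sits inside the nominal far-field distance.

    The inverse-square model is only asymptotically valid there; the
    warning is advisory because the reference setup operates at almost
    exactly one wavelength from the antenna.
    """


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be finite and > 0, got {value!r}")


def _check_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class AntennaSpec:
    """Radiating source: input power [W], gain [dB], carrier frequency [GHz]."""

    power_input_w: float
    gain_db: float
    frequency_ghz: float

    def __post_init__(self) -> None:
        _check_positive(power_input_w=self.power_input_w,
                        frequency_ghz=self.frequency_ghz)
        _check_finite(gain_db=self.gain_db)


@dataclass(frozen=True)
class ExposureScenario:
    """Geometry of one cage placement plus the exposed cohort's physique.

    ``r_near_m`` is the antenna-to-cage-near-edge distance; the animals can
    occupy ``[r_near_m, r_near_m + cage_extent_m]`` along the beam axis.
    ``mean_mass_kg`` / ``mean_length_m`` are cohort averages entering the
    SAR scaling.
    """

    r_near_m: float
    cage_extent_m: float
    mean_mass_kg: float
    mean_length_m: float
    name: str = ""

    def __post_init__(self) -> None:
        _check_positive(r_near_m=self.r_near_m,
                        mean_mass_kg=self.mean_mass_kg,
                        mean_length_m=self.mean_length_m)
        if not math.isfinite(self.cage_extent_m) or self.cage_extent_m < 0:
            raise ValueError(
                f"cage_extent_m must be finite and >= 0, got {self.cage_extent_m!r}")

    @property
    def r_far_m(self) -> float:
        return self.r_near_m + self.cage_extent_m


@dataclass(frozen=True)
class DosimetryConstants:
    """Physical constants of the SAR model.

    ``sar_coefficient`` is the dimensionless coefficient of the whole-body
    SAR scaling divided by the carrier frequency in GHz.  The default
    5.954e-2 reproduces the reference setup's reported averages
    (0.0076 and 0.0059 W/kg) from its printed power densities and cohort
    masses/lengths; it is overridable for other phantoms.
    """

    sar_coefficient: float = 5.954e-2
    speed_of_light: float = 2.998e8  # m/s

    def __post_init__(self) -> None:
        _check_positive(sar_coefficient=self.sar_coefficient,
                        speed_of_light=self.speed_of_light)


@dataclass(frozen=True)
class ComplianceLimits:
    """ICNIRP whole-body reference limits."""

    sar_whole_body_wkg: float = 0.08
    power_density_wm2: float = 10.0

    def __post_init__(self) -> None:
        _check_positive(sar_whole_body_wkg=self.sar_whole_body_wkg,
                        power_density_wm2=self.power_density_wm2)


@dataclass(frozen=True)
class SarSummary:
    """Min/avg/max incident power density and whole-body SAR for one scenario."""

    s_min_wm2: float
    s_avg_wm2: float
    s_max_wm2: float
    sar_min_wkg: float
    sar_avg_wkg: float
    sar_max_wkg: float
    far_field_ok: bool = True

    def __post_init__(self) -> None:
        vals = (self.s_min_wm2, self.s_avg_wm2, self.s_max_wm2,
                self.sar_min_wkg, self.sar_avg_wkg, self.sar_max_wkg)
        if any(v < 0 for v in vals):
            raise ValueError("power densities and SAR values must be >= 0")
        tol = 1e-12
        if not (self.s_min_wm2 <= self.s_avg_wm2 * (1 + tol) + tol
                and self.s_avg_wm2 <= self.s_max_wm2 * (1 + tol) + tol):
            raise ValueError("require s_min <= s_avg <= s_max")
        if not (self.sar_min_wkg <= self.sar_avg_wkg * (1 + tol) + tol
                and self.sar_avg_wkg <= self.sar_max_wkg * (1 + tol) + tol):
            raise ValueError("require sar_min <= sar_avg <= sar_max")


@dataclass(frozen=True)
class ComplianceReport:
    """Verdict against :class:`ComplianceLimits` with margin ratios.

    ``sar_margin`` is limit / sar_avg (cage-averaged, the quantity the
    limit is written for); ``density_margin`` is the reference level over
    the *worst-case* density ``s_max`` at the cage near edge.  Boundary
    equality counts as compliant.
    """

    compliant: bool
    sar_compliant: bool
    density_compliant: bool
    sar_margin: float
    density_margin: float


def db_to_linear(gain_db: float) -> float:
    """Convert a decibel gain to a linear power ratio, 10**(dB/10)."""
    if not math.isfinite(gain_db):
        raise ValueError(f"gain_db must be finite, got {gain_db!r}")
    return 10.0 ** (gain_db / 10.0)


def incident_power_density(antenna: AntennaSpec, r_m: float) -> float:
    """Far-field incident power density S(r) = P_A*g/(4*pi*r^2) in W/m^2."""
    if not math.isfinite(r_m) or r_m <= 0:
        raise ValueError(f"distance r_m must be finite and > 0, got {r_m!r}")
    g = db_to_linear(antenna.gain_db)
    return antenna.power_input_w * g / (_FOUR_PI * r_m * r_m)


def far_field_distance(antenna: AntennaSpec,
                       constants: DosimetryConstants = DosimetryConstants()) -> float:
    """Nominal far-field onset: one free-space wavelength c/f, in metres.

    For a combined electric/magnetic dipole with a common phase centre the
    radiated field is ~1/r beyond about one wavelength (~12 cm at 2.4 GHz).
    """
    return constants.speed_of_light / (antenna.frequency_ghz * 1e9)


def averaged_incident_power_density(antenna: AntennaSpec,
                                    r0_m: float, r1_m: float) -> float:
    """Line average of S(r) over [r0, r1] along the beam axis, W/m^2.

    The inverse-square profile integrates in closed form:

        (1/(r1-r0)) * int_{r0}^{r1} P_A*g/(4*pi*r^2) dr
            = P_A*g/(4*pi) * 1/(r0*r1)

    The degenerate interval r0 == r1 returns the pointwise density.
    """
    if not (math.isfinite(r0_m) and math.isfinite(r1_m)):
        raise ValueError("interval endpoints must be finite")
    if r0_m <= 0:
        raise ValueError(f"r0_m must be > 0, got {r0_m!r}")
    if r1_m < r0_m:
        raise ValueError(f"require r0_m <= r1_m, got [{r0_m!r}, {r1_m!r}]")
    g = db_to_linear(antenna.gain_db)
    return antenna.power_input_w * g / (_FOUR_PI * r0_m * r1_m)


def whole_body_sar(frequency_ghz: float, s_inc_wm2: float,
                   mean_length_m: float, mean_mass_kg: float,
                   constants: DosimetryConstants = DosimetryConstants()) -> float:
    """Whole-body averaged SAR, (k/f_GHz) * S * L / m, in W/kg.

    Linear in the incident power density and animal length, inversely
    proportional to body mass and carrier frequency.  ``s_inc_wm2 == 0``
    is allowed and returns 0.
    """
    _check_positive(frequency_ghz=frequency_ghz,
                    mean_length_m=mean_length_m, mean_mass_kg=mean_mass_kg)
    if not math.isfinite(s_inc_wm2) or s_inc_wm2 < 0:
        raise ValueError(f"s_inc_wm2 must be finite and >= 0, got {s_inc_wm2!r}")
    return (constants.sar_coefficient / frequency_ghz
            * s_inc_wm2 * mean_length_m / mean_mass_kg)


def sar_range(antenna: AntennaSpec, scenario: ExposureScenario,
              constants: DosimetryConstants = DosimetryConstants()) -> SarSummary:
    """Min/avg/max density and SAR over the cage-occupiable interval.

    The maximum density sits at the cage near edge, the minimum at the far
    edge, and the average is the line average of the inverse-square
    profile.  SAR values are the same three densities pushed through the
    (linear) whole-body SAR scaling, so ``sar_x/s_x`` is one constant.

    Emits :class:`FarFieldWarning` when the near edge is inside one
    wavelength of the antenna (the model is then an extrapolation).
    """
    r0, r1 = scenario.r_near_m, scenario.r_far_m
    s_max = incident_power_density(antenna, r0)
    s_min = incident_power_density(antenna, r1)
    s_avg = averaged_incident_power_density(antenna, r0, r1)

    far_field_ok = r0 >= far_field_distance(antenna, constants)
    if not far_field_ok:
        warnings.warn(
            f"cage near edge at {r0:.3f} m is inside the nominal far-field "
            f"distance {far_field_distance(antenna, constants):.3f} m; "
            "inverse-square densities are extrapolated",
            FarFieldWarning, stacklevel=2)

    def sar(s: float) -> float:
        return whole_body_sar(antenna.frequency_ghz, s,
                              scenario.mean_length_m, scenario.mean_mass_kg,
                              constants)

    return SarSummary(
        s_min_wm2=s_min, s_avg_wm2=s_avg, s_max_wm2=s_max,
        sar_min_wkg=sar(s_min), sar_avg_wkg=sar(s_avg), sar_max_wkg=sar(s_max),
        far_field_ok=far_field_ok,
    )


def icnirp_check(summary: SarSummary,
                 limits: ComplianceLimits = ComplianceLimits()) -> ComplianceReport:
    """Compliance verdict of one exposure summary against ICNIRP limits.

    Compliant iff the cage-averaged SAR is at or below the whole-body limit
    AND the cage-averaged density is at or below the reference level.  The
    reported density margin is quoted against the worst-case (near-edge)
    density, the conservative figure of merit.
    """
    sar_ok = summary.sar_avg_wkg <= limits.sar_whole_body_wkg
    dens_ok = summary.s_avg_wm2 <= limits.power_density_wm2
    sar_margin = (math.inf if summary.sar_avg_wkg == 0
                  else limits.sar_whole_body_wkg / summary.sar_avg_wkg)
    density_margin = (math.inf if summary.s_max_wm2 == 0
                      else limits.power_density_wm2 / summary.s_max_wm2)
    return ComplianceReport(
        compliant=sar_ok and dens_ok,
        sar_compliant=sar_ok,
        density_compliant=dens_ok,
        sar_margin=sar_margin,
        density_margin=density_margin,
    )


def summary_as_dict(summary: SarSummary, report: ComplianceReport) -> dict:
    """Flatten a summary + compliance report for JSON serialisation."""
    out = {k: getattr(summary, k) for k in (
        "s_min_wm2", "s_avg_wm2", "s_max_wm2",
        "sar_min_wkg", "sar_avg_wkg", "sar_max_wkg", "far_field_ok")}
    out.update({k: getattr(report, k) for k in (
        "compliant", "sar_compliant", "density_compliant",
        "sar_margin", "density_margin")})
    return out
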