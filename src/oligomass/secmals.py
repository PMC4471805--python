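"""SEC-MALS chromatogram processing: detector traces → binding points.

A size-exclusion column with in-line multi-angle light-scattering (LS) and
differential refractive-index (dRI) detectors yields, per elution slice, two
signals from which concentration and molecular weight follow:

* mass concentration from the refractive index, ``c = Δn / (dn/dc)`` with the
  standard protein refractive-index increment dn/dc = 0.1850 ml/g;
* molecular weight from the idealized single-constant Rayleigh relation,
  ``MW = LS / (k · c)`` with a lumped instrument calibration constant ``k``
  (the constructs analysed here are far below the angular-dependence size
  limit, so the full multi-angle Zimm formalism adds nothing).

Each injection of a dilution series is reduced to one binding point: the
protomer-equivalent concentration at the peak apex, and the
concentration-weighted mean MW across the half-height window around the apex.
Strongly asymmetric peaks (column overloading) are flagged and excluded from
association fits by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .equilibrium import BindingCurve, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "EmptyProfileError",
    "Chromatogram",
    "SlicedProfile",
    "InjectionPoint",
    "DEFAULT_DN_DC",
    "concentration_from_ri",
    "molar_from_mass",
    "mw_from_light_scattering",
    "process_chromatogram",
    "extract_injection_point",
    "assemble_binding_curve",
]

#: protein refractive-index increment, ml/g
DEFAULT_DN_DC = 0.1850

#: fraction of slices at each trace end used for the baseline median
BASELINE_FRACTION = 0.05

#: slices below this fraction of the apex mass concentration are masked
SIGNAL_THRESHOLD = 0.05

#: leading/trailing half-width ratio beyond which a peak is flagged as overloaded
OVERLOAD_ASYMMETRY = 3.0


class EmptyProfileError(ValueError):
    """No valid (above-threshold) region in a sliced profile."""


@dataclass
class Chromatogram:
    """Elution-volume-indexed detector traces plus instrument constants.

    ``ls_calib`` is the lumped calibration constant k such that
    ``MW(kDa) = ls / (k × c_mass)`` with ``c_mass`` in mg/ml.
    """

    volume: np.ndarray  # ml, strictly increasing
    ls: np.ndarray  # light-scattering signal, instrument units
    dri: np.ndarray  # differential refractive index, dimensionless Δn
    uv: np.ndarray | None = None
    dn_dc: float = DEFAULT_DN_DC  # ml/g
    ls_calib: float = 0.01

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.ls = np.asarray(self.ls, dtype=float)
        self.dri = np.asarray(self.dri, dtype=float)
        if self.uv is not None:
            self.uv = np.asarray(self.uv, dtype=float)
            if self.uv.shape != self.volume.shape:
                raise ValidationError("uv trace length must match volume grid")
        if not (self.volume.shape == self.ls.shape == self.dri.shape):
            raise ValidationError("volume, ls and dri must have equal length")
        if self.volume.size < 2 or np.any(np.diff(self.volume) <= 0):
            raise ValidationError("volume grid must be strictly increasing")
        if not self.dn_dc > 0:
            raise ValidationError(f"dn_dc must be > 0, got {self.dn_dc}")
        if not self.ls_calib > 0:
            raise ValidationError(f"ls_calib must be > 0, got {self.ls_calib}")


@dataclass
class SlicedProfile:
    """Per-slice concentration and MW, with a validity mask."""

    volume: np.ndarray  # ml
    c_mass: np.ndarray  # mg/ml
    c_molar: np.ndarray  # μM protomer-equivalent
    mw: np.ndarray  # kDa; NaN on masked slices
    valid_mask: np.ndarray


@dataclass
class InjectionPoint:
    """One binding point reduced from a single injection's peak."""

    c_peak: float  # μM protomer-equivalent at the apex
    mw_mean: float  # kDa, concentration-weighted over the half-height window
    overload_flag: bool = False


def _baseline(signal: np.ndarray) -> float:
    """Median of the outer slices of a trace — robust, parameter-free baseline."""
    n = max(1, int(round(BASELINE_FRACTION * signal.size)))
    return float(np.median(np.concatenate([signal[:n], signal[-n:]])))


def concentration_from_ri(chrom: Chromatogram) -> np.ndarray:
    """Per-slice mass concentration (mg/ml) from the dRI trace.

    The outer-slice median baseline is subtracted first; then
    ``c = Δn / (dn/dc)`` converted from g/ml to mg/ml.
    """
    dn = chrom.dri - _baseline(chrom.dri)
    c_mass = 1000.0 * dn / chrom.dn_dc
    if np.allclose(c_mass, 0.0, atol=1e-12):
        logger.warning("dRI trace is flat: no valid concentration slices")
    return c_mass


def molar_from_mass(c_mass, protomer_plus_tag_mass: float):
    """Convert mg/ml to μM protomer equivalents: μM = 1000 × (mg/ml) / kDa."""
    if not protomer_plus_tag_mass > 0:
        raise ValidationError(f"protomer_plus_tag_mass must be > 0, got {protomer_plus_tag_mass}")
    return 1000.0 * np.asarray(c_mass, dtype=float) / protomer_plus_tag_mass


def mw_from_light_scattering(
    chrom: Chromatogram, c_mass: np.ndarray, threshold: float = SIGNAL_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice MW (kDa) from the LS trace: ``mw = ls / (ls_calib × c_mass)``.

    The LS baseline is subtracted first.  Slices whose concentration is below
    ``threshold`` × apex are masked (MW = NaN), not raised: MW is a ratio of
    two small noisy numbers there.  Returns ``(mw, valid_mask)``.
    """
    ls = chrom.ls - _baseline(chrom.ls)
    apex = np.nanmax(c_mass)
    valid = c_mass > threshold * apex if apex > 0 else np.zeros_like(c_mass, dtype=bool)
    mw = np.full_like(c_mass, np.nan)
    np.divide(ls, chrom.ls_calib * c_mass, out=mw, where=valid)
    return mw, valid


def process_chromatogram(
    chrom: Chromatogram, protomer_plus_tag_mass: float, threshold: float = SIGNAL_THRESHOLD
) -> SlicedProfile:
    """Full slice-level reduction: dRI → c_mass → c_molar, LS → MW."""
    c_mass = concentration_from_ri(chrom)
    mw, valid = mw_from_light_scattering(chrom, c_mass, threshold)
    c_molar = molar_from_mass(np.clip(c_mass, 0.0, None), protomer_plus_tag_mass)
    return SlicedProfile(chrom.volume, c_mass, c_molar, mw, valid)


def _half_height_window(c: np.ndarray, valid: np.ndarray, apex: int) -> tuple[int, int]:
    """Contiguous slice range around the apex with c >= apex/2 (inclusive ends)."""
    half = c[apex] / 2.0
    left = apex
    while left > 0 and valid[left - 1] and c[left - 1] >= half:
        left -= 1
    right = apex
    while right < c.size - 1 and valid[right + 1] and c[right + 1] >= half:
        right += 1
    return left, right


def extract_injection_point(
    profile: SlicedProfile, asymmetry_limit: float = OVERLOAD_ASYMMETRY
) -> InjectionPoint:
    """Reduce one injection's profile to a single (concentration, MW) point.

    The on-column concentration is the apex-slice value (matching how a
    single concentration is tabulated per injection); MW is the
    concentration-weighted mean over the half-height window.  A peak whose
    leading/trailing half-widths differ by more than ``asymmetry_limit`` is
    flagged as overloaded.
    """
    if not np.any(profile.valid_mask):
        raise EmptyProfileError("no slices above the signal threshold")
    c = np.where(profile.valid_mask, profile.c_molar, -np.inf)
    apex = int(np.argmax(c))
    left, right = _half_height_window(profile.c_molar, profile.valid_mask, apex)

    sl = slice(left, right + 1)
    w = profile.c_molar[sl]
    mw = profile.mw[sl]
    ok = np.isfinite(mw)
    mw_mean = float(np.sum(w[ok] * mw[ok]) / np.sum(w[ok]))

    lead = profile.volume[apex] - profile.volume[left]
    trail = profile.volume[right] - profile.volume[apex]
    overload = False
    if lead > 0 and trail > 0:
        ratio = max(lead, trail) / min(lead, trail)
        overload = bool(ratio > asymmetry_limit)
    return InjectionPoint(float(profile.c_molar[apex]), mw_mean, overload)


def assemble_binding_curve(points: list[InjectionPoint]) -> BindingCurve:
    """Collect injection points into a concentration-sorted binding curve.

    Overloaded points are retained but flagged; association fits skip them by
    default.  A curve whose points are all overloaded is still emitted, with a
    warning — downstream fitting will refuse it for lack of usable points.
    """
    if not points:
        raise ValidationError("no injection points")
    pts = sorted(points, key=lambda p: p.c_peak)
    flags = np.array([p.overload_flag for p in pts])
    if flags.all():
        logger.warning("every injection point is flagged as overloaded")
    return BindingCurve(
        np.array([p.c_peak for p in pts]),
        np.array([p.mw_mean for p in pts]),
        provenance="measured",
        overloaded=flags,
    )
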