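"""Circular-dichroism spectra and thermal-unfolding analysis.

Spectra
-------
Far-UV CD spectra are smoothed with a Savitzky–Golay filter, truncated where
the detector high-tension voltage exceeds 800 V, converted to mean-residue
molar ellipticity (MRE), and decomposed into α-helix / β-strand / random-coil
contributions by nonnegative least squares against a three-component basis.
The shipped basis consists of synthetic idealized component spectra (sums of
Gaussian bands at the canonical extrema); the decomposition is therefore
semi-quantitative, as secondary-structure estimates from far-UV CD generally
are.

Melting
-------
Thermal unfolding followed at 222 nm is modelled as one or two independent
two-state (van't Hoff) transitions between linear folded and unfolded
baselines:

    θ(T) = (1 − F(T))·B_f(T) + F(T)·B_u(T),     F(T) = Σ_j w_j f_j(T)
    f_j(T) = K_j / (1 + K_j),   K_j = exp[ −(ΔH_j/R)(1/T − 1/Tm_j) ]   (T in K)

where ``w_j ≥ 0, Σ w_j = 1`` partition the folded→unfolded signal change
between transitions and ΔH_j is the van't Hoff enthalpy controlling transition
sharpness (ΔCp = 0).  Apparent Tm values are reported from the fitted
transition midpoints; a derivative-maximum estimator is provided as an
alternative.  A transition whose amplitude falls below three times the
residual noise is flagged as non-cooperative.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.signal import savgol_filter
from scipy.stats import f as f_dist

from .equilibrium import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CDSpectrum",
    "SecondaryStructureFractions",
    "MeltingCurve",
    "Transition",
    "MeltingFit",
    "GAS_CONSTANT_KJ",
    "HT_VOLTAGE_LIMIT",
    "smooth_signal",
    "mean_residue_ellipticity",
    "truncate_high_tension",
    "synthetic_basis",
    "deconvolute_secondary_structure",
    "melting_model",
    "fit_melting",
    "tm_from_derivative",
    "delta_tm",
]

#: gas constant, kJ mol⁻¹ K⁻¹
GAS_CONSTANT_KJ = 8.31446261815324e-3

#: detector high-tension voltage above which CD data are unreliable
HT_VOLTAGE_LIMIT = 800.0

_KELVIN = 273.15


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


@dataclass
class CDSpectrum:
    """A far-UV CD spectrum on a strictly monotone wavelength grid.

    ``mre`` is mean-residue molar ellipticity in deg·cm²·dmol⁻¹; ``meta`` may
    carry sample concentration (μM), path length (cm) and residue count.
    """

    wavelength: np.ndarray  # nm
    mre: np.ndarray
    meta: dict = field(default_factory=dict)
    ht_voltage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.mre = np.asarray(self.mre, dtype=float)
        if self.wavelength.shape != self.mre.shape:
            raise ValidationError("wavelength and mre must have equal length")
        d = np.diff(self.wavelength)
        if self.wavelength.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("wavelength grid must be strictly monotone")
        if self.ht_voltage is not None:
            self.ht_voltage = np.asarray(self.ht_voltage, dtype=float)
            if self.ht_voltage.shape != self.wavelength.shape:
                raise ValidationError("ht_voltage length must match wavelength grid")


@dataclass
class SecondaryStructureFractions:
    """Helix/strand/coil fractions, renormalized to sum to one after fitting."""

    helix: float
    strand: float
    coil: float
    residual: float | None = None  # rms misfit of the deconvolution, MRE units

    def as_array(self) -> np.ndarray:
        return np.array([self.helix, self.strand, self.coil])

    def __post_init__(self) -> None:
        for name in ("helix", "strand", "coil"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} fraction must lie in [0, 1], got {v}")


def smooth_signal(values, window: int, order: int) -> np.ndarray:
    """Savitzky–Golay smoothing (length-preserving; edges handled by
    polynomial fits on truncated windows).

    ``window`` must be odd and larger than ``order`` but smaller than the
    series length.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValidationError(f"window must be odd, got {window}")
    if window <= order:
        raise ValidationError(f"window ({window}) must exceed polynomial order ({order})")
    if window >= values.size:
        raise ValidationError(f"window ({window}) must be smaller than the series length ({values.size})")
    return savgol_filter(values, window, order, mode="interp")


def mean_residue_ellipticity(raw_mdeg, conc_um: float, path_cm: float, n_residues: int):
    """Convert raw ellipticity (mdeg) to mean-residue molar ellipticity.

    MRE = θ_mdeg / (10 × C_M × l × N_res) with C_M the molar concentration.
    """
    if not conc_um > 0:
        raise ValidationError(f"concentration must be > 0, got {conc_um}")
    if not path_cm > 0:
        raise ValidationError(f"path length must be > 0, got {path_cm}")
    if not n_residues > 0:
        raise ValidationError(f"residue count must be > 0, got {n_residues}")
    return np.asarray(raw_mdeg, dtype=float) / (10.0 * conc_um * 1e-6 * path_cm * n_residues)


def truncate_high_tension(spectrum: CDSpectrum, limit: float = HT_VOLTAGE_LIMIT) -> CDSpectrum:
    """Drop wavelengths where the detector high-tension voltage exceeds ``limit``.

    Applied before smoothing; a spectrum without a voltage trace is returned
    unchanged.
    """
    if spectrum.ht_voltage is None:
        return spectrum
    keep = spectrum.ht_voltage <= limit
    return CDSpectrum(
        spectrum.wavelength[keep], spectrum.mre[keep], dict(spectrum.meta), spectrum.ht_voltage[keep]
    )


def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def synthetic_basis(wavelengths) -> np.ndarray:
    """Synthetic idealized helix/strand/coil component spectra, shape (3, n).

    Gaussian-band caricatures of the canonical far-UV shapes (MRE units):
    α-helix with minima at 208/222 nm and a strong positive band near 192 nm;
    β-strand with a single minimum near 217 nm and a maximum near 196 nm;
    random coil with a deep minimum near 198 nm.  Adequate for recovering
    mixing fractions of spectra generated from the same components and for
    semi-quantitative decomposition of measured spectra.
    """
    w = np.asarray(wavelengths, dtype=float)
    helix = -33000 * _gauss(w, 222, 9) - 31000 * _gauss(w, 208, 8) + 68000 * _gauss(w, 192, 7)
    strand = -23000 * _gauss(w, 217, 10) + 35000 * _gauss(w, 196, 7)
    coil = -42000 * _gauss(w, 198, 8) + 3000 * _gauss(w, 222, 14)
    return np.vstack([helix, strand, coil])


def deconvolute_secondary_structure(
    spectrum: CDSpectrum, basis: np.ndarray | None = None
) -> SecondaryStructureFractions:
    """Nonnegative least-squares decomposition of a spectrum into basis fractions.

    ``basis`` must be a (3, n) array on the spectrum's own wavelength grid
    (default: :func:`synthetic_basis` evaluated there).  Coefficients are
    renormalized to fractions summing to one; the rms residual of the
    unnormalized fit is reported.
    """
    if basis is None:
        basis = synthetic_basis(spectrum.wavelength)
    basis = np.asarray(basis, dtype=float)
    if basis.ndim != 2 or basis.shape[0] != 3 or basis.shape[1] != spectrum.wavelength.size:
        raise ValidationError(
            f"basis must have shape (3, {spectrum.wavelength.size}) on the spectrum's wavelength grid"
        )
    coef, rnorm = nnls(basis.T, spectrum.mre)
    total = coef.sum()
    if total <= 0:
        raise ValidationError("deconvolution degenerate: all basis coefficients are zero")
    frac = coef / total
    return SecondaryStructureFractions(
        float(frac[0]), float(frac[1]), float(frac[2]), residual=float(rnorm / np.sqrt(spectrum.mre.size))
    )


# ---------------------------------------------------------------------------
# thermal unfolding
# ---------------------------------------------------------------------------


@dataclass
class MeltingCurve:
    """θ222 against temperature (°C), strictly increasing grid."""

    temperature: np.ndarray  # °C
    theta222: np.ndarray
    ramp_rate: float = 1.0  # °C/min, metadata

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.theta222 = np.asarray(self.theta222, dtype=float)
        if self.temperature.shape != self.theta222.shape:
            raise ValidationError("temperature and theta222 must have equal length")
        if self.temperature.size > 1 and np.any(np.diff(self.temperature) <= 0):
            raise ValidationError("temperature grid must be strictly increasing")


@dataclass
class Transition:
    """One two-state unfolding transition.

    ``weight`` is the dimensionless share of the folded→unfolded signal change
    carried by this transition (weights sum to 1 across transitions);
    ``amplitude`` is the derived signal change in ellipticity units,
    weight × (B_u(Tm) − B_f(Tm)).
    """

    tm: float  # °C
    dh_vh: float  # van't Hoff enthalpy, kJ/mol
    weight: float = 1.0
    amplitude: float | None = None
    cooperative: bool | None = None

    def __post_init__(self) -> None:
        if not self.dh_vh > 0:
            raise ValidationError(f"dh_vh must be > 0, got {self.dh_vh}")
        if not 0 <= self.weight <= 1:
            raise ValidationError(f"weight must lie in [0, 1], got {self.weight}")


@dataclass
class MeltingFit:
    """Parameters of a one- or two-transition two-state melting decomposition."""

    transitions: tuple[Transition, ...]
    baseline_folded: tuple[float, float]  # intercept, slope (per °C)
    baseline_unfolded: tuple[float, float]
    rss: float = float("nan")
    converged: bool = True
    cooperativity_flag: bool = True  # False when any transition is amplitude-degenerate

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def __post_init__(self) -> None:
        self.transitions = tuple(self.transitions)
        tms = [t.tm for t in self.transitions]
        if any(b > a for a, b in zip(tms[1:], tms[:-1])):
            raise ValidationError("transitions must be ordered by increasing tm")


def _fraction_unfolded(temp_c: np.ndarray, tm_c: float, dh: float) -> np.ndarray:
    """Two-state unfolded fraction; 0.5 at Tm by construction."""
    t = np.asarray(temp_c, dtype=float) + _KELVIN
    tm = tm_c + _KELVIN
    arg = (dh / GAS_CONSTANT_KJ) * (1.0 / t - 1.0 / tm)
    return 1.0 / (1.0 + np.exp(np.clip(arg, -500, 500)))


def melting_model(fit: MeltingFit, temperature) -> np.ndarray:
    """Forward θ222 model; reduces to the folded baseline when all weights are zero."""
    t = np.asarray(temperature, dtype=float)
    bf = fit.baseline_folded[0] + fit.baseline_folded[1] * t
    bu = fit.baseline_unfolded[0] + fit.baseline_unfolded[1] * t
    total_w = sum(tr.weight for tr in fit.transitions)
    if total_w == 0:
        return bf
    f = np.zeros_like(t)
    for tr in fit.transitions:
        f += tr.weight * _fraction_unfolded(t, tr.tm, tr.dh_vh)
    return (1.0 - f) * bf + f * bu


def _pack(fit_bf, fit_bu, tms, dhs, w1=None) -> np.ndarray:
    p = [*fit_bf, *fit_bu]
    for tm, dh in zip(tms, dhs):
        p += [tm, dh]
    if w1 is not None:
        p.append(w1)
    return np.array(p, dtype=float)


def _unpack(p: np.ndarray, n: int) -> MeltingFit:
    bf, bu = (p[0], p[1]), (p[2], p[3])
    if n == 1:
        trs = [Transition(p[4], p[5], 1.0)]
    else:
        w1 = p[8]
        trs = [Transition(p[4], p[5], w1), Transition(p[6], p[7], 1.0 - w1)]
        trs.sort(key=lambda t: t.tm)
    return MeltingFit(tuple(trs), bf, bu)


def _melt_weights(y: np.ndarray) -> np.ndarray:
    """Inverse-magnitude residual weights for the multiplicative noise model.

    CD detector noise grows with signal magnitude, so residuals are scaled by
    1/|θ| (floored at 5% of the largest magnitude to avoid over-weighting
    near-zero slices).
    """
    return 1.0 / np.maximum(np.abs(y), 0.05 * np.abs(y).max())


def _multistart(t: np.ndarray, y: np.ndarray, n: int, tm_grid_step: float, w: np.ndarray):
    """Best bounded weighted least-squares fit over a grid of Tm starting values."""
    n_edge = max(2, int(0.15 * t.size))
    bf0 = np.polyfit(t[:n_edge], y[:n_edge], 1)[::-1]
    bu0 = np.polyfit(t[-n_edge:], y[-n_edge:], 1)[::-1]
    t_lo, t_hi = float(t.min()), float(t.max())
    grid = np.arange(np.ceil(t_lo / tm_grid_step) * tm_grid_step, t_hi, tm_grid_step)
    if grid.size == 0:
        grid = np.array([(t_lo + t_hi) / 2.0])

    if n == 1:
        starts = [(tm,) for tm in grid]
        lo = [-np.inf, -np.inf, -np.inf, -np.inf, t_lo, 5.0]
        hi = [np.inf, np.inf, np.inf, np.inf, t_hi, 3000.0]
    else:
        starts = [(a, b) for a, b in itertools.combinations(grid, 2) if b - a >= tm_grid_step - 1e-9]
        if not starts:
            starts = [(t_lo + (t_hi - t_lo) / 3, t_lo + 2 * (t_hi - t_lo) / 3)]
        lo = [-np.inf] * 4 + [t_lo, 5.0, t_lo, 5.0, 0.02]
        hi = [np.inf] * 4 + [t_hi, 3000.0, t_hi, 3000.0, 0.98]

    def residuals(p: np.ndarray) -> np.ndarray:
        return (melting_model(_unpack(p, n), t) - y) * w

    # cheap capped exploration from every start, then an uncapped polish of the winner
    best, best_cost = None, np.inf
    for tms in starts:
        p0 = _pack(bf0, bu0, tms, [300.0] * n, 0.5 if n == 2 else None)
        try:
            res = least_squares(residuals, p0, bounds=(lo, hi), max_nfev=120)
        except Exception:  # pragma: no cover - defensive
            continue
        if res.cost < best_cost:
            best, best_cost = res, res.cost
    if best is not None:
        polished = least_squares(residuals, best.x, bounds=(lo, hi))
        if polished.cost <= best.cost:
            best = polished
    return best, (tuple(bf0), tuple(bu0))


def _extra_transitions_significant(
    rss_reduced: float, rss_full: float, d_params: int, dof: float, scale: float
) -> bool:
    """F-test: do the extra transition parameters reduce the misfit significantly?"""
    floor = (1e-9 * scale) ** 2
    if rss_reduced - rss_full <= floor:
        return False
    f_stat = ((rss_reduced - rss_full) / d_params) / max(rss_full / dof, floor)
    return bool(f_dist.sf(f_stat, d_params, dof) < 0.01)


def fit_melting(curve: MeltingCurve, n_transitions: int = 1, tm_grid_step: float = 10.0) -> MeltingFit:
    """Nonlinear least-squares fit of the one- or two-transition melting model.

    The fit is multi-started over a grid of candidate Tm values (every
    ``tm_grid_step`` °C within the data range; ordered pairs for two
    transitions) to avoid local minima, and the best residual sum of squares
    wins.  Baselines are initialized from linear fits to the outer 15% of
    points.  Requires at least 20 points.  Residuals are weighted by inverse
    signal magnitude, matching the multiplicative detector-noise model (the
    folded-state signal is large and noisy; the unfolded baseline is small
    and quiet).  Failure of every start is reported as ``converged=False``,
    never an exception.

    A transition is flagged non-cooperative when any of these hold: its
    amplitude is below 3× the residual noise, its van't Hoff 10–90% width
    exceeds the measured temperature span (a baseline in disguise), or —
    for the smallest-amplitude transition — dropping one transition does not
    worsen the fit significantly (F-test against the reduced model at 1%).
    """
    if n_transitions not in (1, 2):
        raise ValidationError(f"n_transitions must be 1 or 2, got {n_transitions}")
    t, y = curve.temperature, curve.theta222
    if t.size < 20:
        raise ValidationError(f"need >= 20 points spanning both baselines, have {t.size}")
    t_lo, t_hi = float(t.min()), float(t.max())
    w = _melt_weights(y)

    best, (bf0, bu0) = _multistart(t, y, n_transitions, tm_grid_step, w)
    if best is None:  # pragma: no cover - least_squares is robust on bounded problems
        fit = MeltingFit((Transition((t_lo + t_hi) / 2, 100.0),), bf0, bu0)
        fit.converged = False
        return fit

    fit = _unpack(best.x, n_transitions)
    resid = melting_model(fit, t) - y
    fit.rss = float(np.sum(resid**2))
    noise = float(np.std(resid))
    signal_range = float(np.ptp(y))
    span = t_hi - t_lo
    n_params = 6 if n_transitions == 1 else 9

    # reduced model on the same weighted scale: a straight line for n=1, the
    # best 1-transition fit for n=2
    wrss_full = 2.0 * best.cost
    if n_transitions == 1:
        line = np.polyfit(t, y, 1, w=w)
        wrss_reduced, d_params = float(np.sum(((y - np.polyval(line, t)) * w) ** 2)), 4
    else:
        reduced, _ = _multistart(t, y, 1, tm_grid_step, w)
        wrss_reduced, d_params = 2.0 * reduced.cost, 3
    significant = _extra_transitions_significant(
        wrss_reduced, wrss_full, d_params, max(t.size - n_params, 1), float(np.ptp(y * w))
    )

    bf_i, bf_s = fit.baseline_folded
    bu_i, bu_s = fit.baseline_unfolded
    amps = []
    for tr in fit.transitions:
        amp = tr.weight * ((bu_i + bu_s * tr.tm) - (bf_i + bf_s * tr.tm))
        tr.amplitude = float(amp)
        # 10-90% transition width from the van't Hoff slope; a "transition"
        # broader than the measured range is a baseline in disguise
        width = np.log(81.0) * GAS_CONSTANT_KJ * (tr.tm + _KELVIN) ** 2 / tr.dh_vh
        tr.cooperative = bool(abs(amp) >= max(3.0 * noise, 1e-3 * signal_range) and width <= span)
        amps.append(abs(amp))
    if not significant:
        fit.transitions[int(np.argmin(amps))].cooperative = False
    fit.cooperativity_flag = all(tr.cooperative for tr in fit.transitions)
    fit.converged = bool(best.success) and all(t_lo <= tr.tm <= t_hi for tr in fit.transitions)
    if not fit.cooperativity_flag:
        logger.info("melting fit: at least one transition is amplitude- or width-degenerate")
    return fit


def tm_from_derivative(curve: MeltingCurve, window: int = 9, order: int = 3) -> float:
    """Alternative apparent-Tm estimator: temperature of the maximum of dθ/dT.

    Computed on the Savitzky–Golay-smoothed first derivative of the raw
    curve; useful as a model-free cross-check of the fitted midpoint.
    """
    dt = np.gradient(smooth_signal(curve.theta222, window, order), curve.temperature)
    return float(curve.temperature[int(np.argmax(dt))])


def delta_tm(fit_a: MeltingFit, fit_b: MeltingFit, transition: int = 0) -> float:
    """Melting-temperature difference tm_a − tm_b (°C) for a matched transition."""
    if fit_a.n_transitions != fit_b.n_transitions:
        raise ValidationError(
            f"transition counts differ ({fit_a.n_transitions} vs {fit_b.n_transitions}); fits are not comparable"
        )
    if not (0 <= transition < fit_a.n_transitions):
        raise ValidationError(f"transition index {transition} out of range")
    if not (fit_a.converged and fit_b.converged):
        raise ValidationError("both fits must have converged")
    return float(fit_a.transitions[transition].tm - fit_b.transitions[transition].tm)
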