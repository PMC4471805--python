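"""Mass-action equilibria of protein homo-oligomerization and SEC-MALS observables.

A self-associating protein is described by an :class:`AssemblyScheme`: an
indivisible *base unit* (a monomer, or an obligate dimer when one interface is
effectively infinitely tight) plus an ordered series of association steps with
stepwise dissociation constants.  Solving the mass-action system at a given
total protomer concentration yields the molar population of every oligomeric
species, from which the weight-average molecular weight — the quantity an
in-line multi-angle light-scattering (MALS) detector reports — follows as

    MW_w = sum_i c_i * M_i**2 / sum_i c_i * M_i

over species with molar concentrations ``c_i`` and masses ``M_i``.

The concentration dependence of MW_w over a dilution series is the binding
curve; its midpoint between the smallest and largest species masses defines
the model-free *apparent Kd*, the single number normally quoted for such
self-association experiments.  Schemes can be fitted to measured binding
curves by nonlinear least squares on the stepwise constants, with an optional
bootstrap for confidence intervals.

Units: concentrations are μM of protomer equivalents throughout (a hexamer at
1 μM contributes 6 μM protomer equivalents); masses are kDa; stepwise
dissociation constants are μM raised to the number of base units consumed in
the step (e.g. a direct monomer↔trimer step has kd = [M]^3/[T] in μM²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.optimize import brentq, least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "OutOfRangeError",
    "AssemblyScheme",
    "SpeciesDistribution",
    "BindingCurve",
    "AssociationFit",
    "build_scheme",
    "monomer_trimer",
    "monomer_dimer_trimer",
    "dimer_tetramer_hexamer",
    "kd3_for_apparent_kd",
    "solve_equilibrium",
    "weight_average_mw",
    "predict_binding_curve",
    "species_molar_ratio",
    "apparent_kd_from_inflection",
    "fit_association",
]

BaseUnit = Literal["monomer", "obligate_dimer"]

#: log10 bounds (μM-scale) applied to every free dissociation constant in fits.
KD_LOG10_BOUNDS = (-4.0, 4.0)

#: default bootstrap settings for association-fit confidence intervals
BOOTSTRAP_REPLICATES = 200
BOOTSTRAP_SEED = 1729


class ValidationError(ValueError):
    """An input violates a documented precondition; the message names the field."""


class OutOfRangeError(RuntimeError):
    """A requested quantity lies outside the span of the provided data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssemblyScheme:
    """A homo-oligomer association scheme.

    Parameters
    ----------
    name:
        Free-form label (e.g. the construct name).
    protomer_mass:
        Monomeric molecular weight in kDa.
    tag_mass:
        Additional per-protomer fusion-tag mass in kDa (0 for untagged).
    base_unit:
        ``"monomer"`` or ``"obligate_dimer"``.  An obligate dimer is treated as
        the indivisible unit of further assembly (its internal interface is
        modelled as infinitely tight).
    steps:
        Ordered ``(product_order, kd)`` pairs with strictly increasing protomer
        counts.  The first step assembles the product directly from the
        required number of base units; each later step adds base units to the
        previous product.  ``kd`` is in μM to the power of the number of base
        units consumed by the step.
    """

    name: str
    protomer_mass: float
    tag_mass: float = 0.0
    base_unit: BaseUnit = "monomer"
    steps: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.protomer_mass > 0:
            raise ValidationError(f"protomer_mass must be > 0, got {self.protomer_mass}")
        if self.tag_mass < 0:
            raise ValidationError(f"tag_mass must be >= 0, got {self.tag_mass}")
        if self.base_unit not in ("monomer", "obligate_dimer"):
            raise ValidationError(f"base_unit must be 'monomer' or 'obligate_dimer', got {self.base_unit!r}")
        object.__setattr__(self, "steps", tuple((int(o), float(k)) for o, k in self.steps))
        if len(self.steps) < 1:
            raise ValidationError("steps: a scheme needs at least two species (no association step given)")
        prev = self.base_order
        for order, kd in self.steps:
            if order <= prev:
                raise ValidationError(f"steps: product orders must be strictly increasing ({order} after {prev})")
            if (order - prev) % self.base_order != 0:
                raise ValidationError(
                    f"steps: order {order} is not reachable from {prev} by whole base units of {self.base_order}"
                )
            if not kd > 0:
                raise ValidationError(f"kd for product order {order} must be > 0, got {kd}")
            prev = order

    @property
    def base_order(self) -> int:
        """Protomer count of the indivisible base unit (1 or 2)."""
        return 2 if self.base_unit == "obligate_dimer" else 1

    @property
    def unit_mass(self) -> float:
        """Mass of one protomer including its tag, kDa."""
        return self.protomer_mass + self.tag_mass

    @property
    def orders(self) -> tuple[int, ...]:
        """Protomer counts of all species, base unit first."""
        return (self.base_order,) + tuple(o for o, _ in self.steps)

    @property
    def species_masses(self) -> np.ndarray:
        """Masses of all species in kDa, order × (protomer + tag)."""
        return np.array(self.orders, dtype=float) * self.unit_mass

    @property
    def kds(self) -> tuple[float, ...]:
        return tuple(k for _, k in self.steps)

    @property
    def step_units(self) -> tuple[int, ...]:
        """Number of base units consumed by each step."""
        units, prev = [], self.base_order
        for order, _ in self.steps:
            units.append((order - prev) // self.base_order)
            prev = order
        return tuple(units)

    def with_kds(self, kds: Sequence[float]) -> "AssemblyScheme":
        """Return a copy with the stepwise constants replaced (same orders)."""
        if len(kds) != len(self.steps):
            raise ValidationError(f"expected {len(self.steps)} kds, got {len(kds)}")
        return replace(self, steps=tuple((o, float(k)) for (o, _), k in zip(self.steps, kds)))


@dataclass(frozen=True)
class SpeciesDistribution:
    """Equilibrium molar concentrations of every species at one total concentration."""

    scheme: AssemblyScheme
    c_total: float
    concentrations: np.ndarray  # μM per species, aligned with scheme.orders

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        if np.any(conc < 0):
            raise ValidationError("concentrations must be nonnegative")

    def concentration_of(self, order: int) -> float:
        """Molar concentration (μM) of the species with the given protomer count."""
        try:
            i = self.scheme.orders.index(order)
        except ValueError:
            raise KeyError(f"no species of order {order} in scheme {self.scheme.name!r}") from None
        return float(self.concentrations[i])


@dataclass
class BindingCurve:
    """Paired (total concentration, weight-average MW) observations or predictions."""

    c_total: np.ndarray  # μM protomer-equivalent
    mw: np.ndarray  # kDa
    mw_sigma: np.ndarray | None = None
    provenance: Literal["measured", "simulated", "model"] = "measured"
    overloaded: np.ndarray | None = None  # bool per point; overloaded points excluded from fits

    def __post_init__(self) -> None:
        self.c_total = np.asarray(self.c_total, dtype=float)
        self.mw = np.asarray(self.mw, dtype=float)
        if self.c_total.shape != self.mw.shape:
            raise ValidationError("c_total and mw must have equal length")
        if self.c_total.size == 0:
            raise ValidationError("binding curve is empty")
        if np.any(self.c_total <= 0):
            raise ValidationError("all c_total must be > 0")
        if np.any(self.mw <= 0):
            raise ValidationError("all mw must be > 0")
        if self.mw_sigma is not None:
            self.mw_sigma = np.asarray(self.mw_sigma, dtype=float)
            if self.mw_sigma.shape != self.mw.shape:
                raise ValidationError("mw_sigma must match mw length")
        if self.overloaded is not None:
            self.overloaded = np.asarray(self.overloaded, dtype=bool)
            if self.overloaded.shape != self.mw.shape:
                raise ValidationError("overloaded must match mw length")

    def __len__(self) -> int:
        return int(self.c_total.size)


@dataclass
class AssociationFit:
    """Result of fitting an assembly scheme to a binding curve."""

    scheme: AssemblyScheme
    apparent_kd: float  # μM, midpoint of the fitted model curve
    apparent_kd_ci: tuple[float, float] | None
    rss: float  # kDa²
    converged: bool
    n_points: int


# ---------------------------------------------------------------------------
# scheme construction
# ---------------------------------------------------------------------------


def build_scheme(
    name: str,
    protomer_mass: float,
    tag_mass: float = 0.0,
    base_unit: BaseUnit = "monomer",
    steps: Sequence[tuple[int, float]] = (),
) -> AssemblyScheme:
    """Construct and validate an :class:`AssemblyScheme`.

    Raises :class:`ValidationError` naming the offending field for
    non-increasing orders, non-positive masses or dissociation constants, or a
    scheme with fewer than two species.
    """
    return AssemblyScheme(name, protomer_mass, tag_mass, base_unit, tuple(steps))


def kd3_for_apparent_kd(apparent_kd: float) -> float:
    """Overall monomer↔trimer constant (μM²) whose midpoint apparent Kd is the given value.

    For a direct monomer↔trimer equilibrium the weight-average MW crosses the
    midpoint (M1+M3)/2 when the monomer and trimer mass fractions are equal,
    i.e. [M] = 3[T]; with kd3 = [M]³/[T] this gives [M]² = kd3/3 and a total
    concentration c_mid = 2[M], hence kd3 = 3·(c_mid/2)².
    """
    if not apparent_kd > 0:
        raise ValidationError("apparent_kd must be > 0")
    return 3.0 * (apparent_kd / 2.0) ** 2


def monomer_trimer(protomer_mass: float = 12.5, kd3: float = 6.75, name: str = "monomer-trimer") -> AssemblyScheme:
    """Direct monomer↔trimer scheme (default mass: the 12.5 kDa coiled-coil construct).

    The default kd3 of 6.75 μM² places the binding-curve midpoint at 3 μM,
    the apparent Kd reported for the SAS-5 coiled coil.
    """
    return build_scheme(name, protomer_mass, 0.0, "monomer", [(3, kd3)])


def monomer_dimer_trimer(
    protomer_mass: float = 12.5,
    kd_dimer: float = 3.0,
    kd_trimer: float = 3.0,
    name: str = "monomer-dimer-trimer",
) -> AssemblyScheme:
    """Monomer→dimer→trimer scheme with an explicit dimer intermediate."""
    return build_scheme(name, protomer_mass, 0.0, "monomer", [(2, kd_dimer), (3, kd_trimer)])


def dimer_tetramer_hexamer(
    protomer_mass: float = 46.0,
    tag_mass: float = 16.0,
    kd_tetramer: float = 3.0,
    kd_hexamer: float = 3.0,
    name: str = "dimer-tetramer-hexamer",
) -> AssemblyScheme:
    """Obligate dimer → tetramer → hexamer scheme (MsyB-tagged full-architecture constructs)."""
    return build_scheme(name, protomer_mass, tag_mass, "obligate_dimer", [(4, kd_tetramer), (6, kd_hexamer)])


#: presets addressable by name (configuration files, CLI)
PRESETS = {
    "monomer_trimer": monomer_trimer,
    "monomer_dimer_trimer": monomer_dimer_trimer,
    "dimer_tetramer_hexamer": dimer_tetramer_hexamer,
}


# ---------------------------------------------------------------------------
# equilibrium solution
# ---------------------------------------------------------------------------


def _species_concentrations(scheme: AssemblyScheme, x: float) -> np.ndarray:
    """Molar concentration of every species as a function of the free base-unit level x."""
    conc = np.empty(len(scheme.orders))
    conc[0] = x
    p = x
    for i, (m, (_, kd)) in enumerate(zip(scheme.step_units, scheme.steps), start=1):
        p = p * x**m / kd
        conc[i] = p
    return conc


def solve_equilibrium(scheme: AssemblyScheme, c_total: float) -> SpeciesDistribution:
    """Solve the mass-action system at total protomer concentration ``c_total`` (μM).

    The total protomer concentration is a strictly increasing polynomial of
    the free base-unit concentration x, so the unique nonnegative root is
    bracketed in [0, c_total/base_order] and found by Brent's method; no
    starting guess is required and convergence is guaranteed for any valid
    scheme.  Mass conservation holds to ~1e-12 relative.
    """
    if c_total < 0:
        raise ValidationError(f"c_total must be >= 0, got {c_total}")
    orders = np.array(scheme.orders, dtype=float)
    if c_total == 0:
        return SpeciesDistribution(scheme, 0.0, np.zeros(len(orders)))

    x_hi = c_total / scheme.base_order

    def deficit(x: float) -> float:
        return float(orders @ _species_concentrations(scheme, x)) - c_total

    try:
        x = brentq(deficit, 0.0, x_hi, xtol=x_hi * 1e-16 + 5e-324, rtol=4 * np.finfo(float).eps)
    except Exception as exc:  # pragma: no cover - cannot occur for valid schemes
        raise RuntimeError(
            f"equilibrium solver failed for scheme {scheme.name!r} at c_total={c_total}: {exc}"
        ) from exc
    conc = _species_concentrations(scheme, x)
    dist = SpeciesDistribution(scheme, float(c_total), conc)
    resid = abs(float(orders @ conc) - c_total) / c_total
    if resid > 1e-9:  # pragma: no cover - numerical safety net
        raise RuntimeError(f"mass conservation violated (relative residual {resid:.2e})")
    return dist


def weight_average_mw(dist: SpeciesDistribution) -> float:
    """Weight-average molecular weight (kDa) of a species distribution.

    This is the MALS observable Σ cᵢMᵢ² / Σ cᵢMᵢ, bounded by the smallest and
    largest species masses.  Undefined at zero total concentration.
    """
    if dist.c_total <= 0:
        raise ValidationError("weight-average MW is undefined at zero total concentration")
    masses = dist.scheme.species_masses
    wm = dist.concentrations * masses
    return float(wm @ masses / wm.sum())


def predict_binding_curve(scheme: AssemblyScheme, c_grid: Sequence[float]) -> BindingCurve:
    """Model weight-average MW over a concentration grid (μM), provenance ``"model"``."""
    c = np.asarray(c_grid, dtype=float)
    if c.size == 0:
        raise ValidationError("c_grid is empty")
    if np.any(c <= 0):
        raise ValidationError("c_grid values must be > 0")
    mw = np.array([weight_average_mw(solve_equilibrium(scheme, ci)) for ci in c])
    return BindingCurve(c, mw, provenance="model")


def species_molar_ratio(dist: SpeciesDistribution, order_a: int, order_b: int) -> float:
    """Molar ratio [species of order_a] / [species of order_b].

    Raises ``KeyError`` for an absent species and ``ZeroDivisionError`` when
    the denominator species has zero concentration.
    """
    a = dist.concentration_of(order_a)
    b = dist.concentration_of(order_b)
    if b == 0:
        raise ZeroDivisionError(
            f"species of order {order_b} has zero concentration at c_total={dist.c_total} μM"
        )
    return a / b


# ---------------------------------------------------------------------------
# apparent Kd
# ---------------------------------------------------------------------------


def _model_mw(scheme: AssemblyScheme, c: float) -> float:
    return weight_average_mw(solve_equilibrium(scheme, c))


def _midpoint_crossing(scheme: AssemblyScheme) -> float:
    """Total concentration (μM) where the model MW crosses (M_min + M_max)/2."""
    masses = scheme.species_masses
    target = 0.5 * (masses.min() + masses.max())

    def g(log_c: float) -> float:
        return _model_mw(scheme, 10.0**log_c) - target

    lo, hi = -9.0, 1.0
    while g(hi) < 0:
        hi += 1.0
        if hi > 12:  # pragma: no cover - unreachable for valid schemes
            raise OutOfRangeError("model curve never reaches the midpoint below 1e12 μM")
    while g(lo) > 0:
        lo -= 1.0
        if lo < -15:  # pragma: no cover
            raise OutOfRangeError("model curve already above midpoint at 1e-15 μM")
    return float(10.0 ** brentq(g, lo, hi, rtol=4 * np.finfo(float).eps))


def _inflection_log10(scheme: AssemblyScheme, c_mid: float) -> float:
    """Zero of d²MW/d(log10 c)² nearest the midpoint, on a dense spline."""
    grid = np.linspace(np.log10(c_mid) - 3, np.log10(c_mid) + 3, 241)
    mw = np.array([_model_mw(scheme, 10.0**u) for u in grid])
    spline = CubicSpline(grid, mw)
    roots = spline.derivative(2).roots(extrapolate=False)
    if roots.size == 0:  # pragma: no cover - sigmoid always has an inflection
        raise OutOfRangeError("no inflection found on the model curve")
    return float(roots[np.argmin(np.abs(roots - np.log10(c_mid)))])


def apparent_kd_from_inflection(
    source: AssemblyScheme | BindingCurve,
    method: Literal["midpoint", "second_derivative"] = "midpoint",
    scale: Literal["protomer", "particle"] = "protomer",
    mw_limits: tuple[float, float] | None = None,
) -> float:
    """Apparent dissociation constant (μM) from the MW-vs-concentration transition.

    The default estimator is the total concentration at which the curve
    crosses the midpoint ``(M_min + M_max)/2`` between the smallest and largest
    species masses; ``method="second_derivative"`` instead locates the zero of
    the second derivative of MW against log10 concentration (the literal
    inflection of the sigmoid).  Both are reported as "apparent Kd".

    ``scale="protomer"`` (default) quotes the protomer-equivalent total
    concentration, matching how on-column concentrations are tabulated;
    ``scale="particle"`` instead quotes the total particle (molar species)
    concentration at the same point.

    For a measured/simulated :class:`BindingCurve` the curve must span from
    near the monomer limit past the midpoint of ``mw_limits`` (defaulting to
    the observed MW extremes); otherwise :class:`OutOfRangeError` asks for a
    wider concentration grid.
    """
    if isinstance(source, AssemblyScheme):
        c_mid = _midpoint_crossing(source)
        if method == "second_derivative":
            c_mid = 10.0 ** _inflection_log10(source, c_mid)
        if scale == "particle":
            dist = solve_equilibrium(source, c_mid)
            return float(dist.concentrations.sum())
        return c_mid

    curve = source
    lo, hi = mw_limits if mw_limits is not None else (curve.mw.min(), curve.mw.max())
    target = 0.5 * (lo + hi)
    order = np.argsort(curve.c_total)
    log_c, mw = np.log10(curve.c_total[order]), curve.mw[order]
    if mw.min() > target or mw.max() < target:
        raise OutOfRangeError(
            f"binding curve (MW {mw.min():.3g}–{mw.max():.3g} kDa) never crosses the midpoint "
            f"{target:.3g} kDa; measure a wider concentration range"
        )
    interp = PchipInterpolator(log_c, mw - target)
    roots = interp.roots(extrapolate=False)
    if roots.size == 0:  # pragma: no cover - guarded by the range check above
        raise OutOfRangeError("no midpoint crossing within the measured span")
    if method == "second_derivative":
        d2 = interp.derivative(2)
        cand = d2.roots(extrapolate=False)
        if cand.size:
            return float(10.0 ** cand[np.argmin(np.abs(cand - roots[0]))])
    return float(10.0 ** roots[0])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_association(
    data: BindingCurve,
    scheme_template: AssemblyScheme,
    free: Sequence[int] | None = None,
    bootstrap: int = 0,
    seed: int = BOOTSTRAP_SEED,
    exclude_overloaded: bool = True,
) -> AssociationFit:
    """Least-squares fit of a scheme's stepwise constants to a binding curve.

    Free constants (all by default; ``free`` gives step indices) are optimized
    in log10 space with bounds 1e-4–1e4 on the μM scale, starting from the
    template's values.  Residuals are weighted by ``mw_sigma`` when present.
    Overloaded points are excluded by default.  ``bootstrap`` > 0 resamples
    points with replacement that many times (seeded) and reports a 95%
    percentile interval on the apparent Kd.

    Non-convergence, or a constant pinned at a bound (as happens when the data
    show no association), is reported as ``converged=False`` rather than an
    exception.
    """
    free_idx = list(range(len(scheme_template.steps))) if free is None else list(free)
    if len(free_idx) < 1:
        raise ValidationError("at least one free kd is required")

    keep = np.ones(len(data), dtype=bool)
    if exclude_overloaded and data.overloaded is not None:
        keep &= ~data.overloaded
    c_obs, mw_obs = data.c_total[keep], data.mw[keep]
    sigma = data.mw_sigma[keep] if data.mw_sigma is not None else np.ones_like(mw_obs)
    if c_obs.size < 3:
        raise ValidationError(f"need >= 3 usable points, have {c_obs.size}")
    if c_obs.size <= len(free_idx):
        raise ValidationError(f"{c_obs.size} points cannot constrain {len(free_idx)} free constants")

    kds0 = np.array(scheme_template.kds, dtype=float)

    def scheme_for(p: np.ndarray) -> AssemblyScheme:
        kds = kds0.copy()
        kds[free_idx] = 10.0**p
        return scheme_template.with_kds(kds)

    def residuals(p: np.ndarray, c: np.ndarray, mw: np.ndarray, s: np.ndarray) -> np.ndarray:
        sch = scheme_for(p)
        model = np.array([_model_mw(sch, ci) for ci in c])
        return (model - mw) / s

    lo, hi = KD_LOG10_BOUNDS
    p0 = np.clip(np.log10(kds0[free_idx]), lo, hi)
    result = least_squares(residuals, p0, bounds=(lo, hi), args=(c_obs, mw_obs, sigma))
    fitted = scheme_for(result.x)
    at_bound = bool(np.any(result.x <= lo + 1e-6) or np.any(result.x >= hi - 1e-6))
    converged = bool(result.success) and not at_bound
    if at_bound:
        logger.warning("fit_association: a dissociation constant is pinned at its bound; data may show no association")

    model = np.array([_model_mw(fitted, ci) for ci in c_obs])
    rss = float(np.sum((model - mw_obs) ** 2))
    app_kd = apparent_kd_from_inflection(fitted)

    ci = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(bootstrap):
            idx = rng.integers(0, c_obs.size, c_obs.size)
            try:
                res_b = least_squares(
                    residuals, result.x, bounds=(lo, hi), args=(c_obs[idx], mw_obs[idx], sigma[idx])
                )
                draws.append(apparent_kd_from_inflection(scheme_for(res_b.x)))
            except Exception:  # pragma: no cover - degenerate resample
                continue
        if draws:
            ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))

    return AssociationFit(fitted, float(app_kd), ci, rss, converged, int(c_obs.size))
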