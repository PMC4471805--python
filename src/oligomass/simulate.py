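"""Synthetic-data generators mirroring the biophysical experimental designs.

Every input the processing modules consume can be generated here with the
statistical structure the analysis assumes: 1:1 dilution-series binding data
with multiplicative lognormal MW noise (MALS noise grows with signal), full
chromatograms with additive Gaussian detector noise, two-state melting curves,
CD spectra blended from basis components, and native-mass-spectrometry
charge-state peak positions.  Noiseless output is exactly the corresponding
forward model, and all randomness is reproducible from explicit seeds.

The module also ships the experimental-design reference table for the SAS-5
constructs (per-construct monomeric mass, SEC column and on-column
concentration range), used to parameterize realistic simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cdtherm import CDSpectrum, MeltingCurve, MeltingFit, SecondaryStructureFractions, melting_model, synthetic_basis
from .equilibrium import (
    AssemblyScheme,
    BindingCurve,
    ValidationError,
    predict_binding_curve,
    solve_equilibrium,
    weight_average_mw,
)
from .secmals import DEFAULT_DN_DC, Chromatogram

__all__ = [
    "SeriesDesign",
    "SEC_MALS_DESIGNS",
    "sec_mals_designs",
    "series_design_for",
    "simulate_binding_series",
    "simulate_chromatogram",
    "simulate_melting",
    "simulate_cd_spectrum",
    "MSPeak",
    "predict_native_ms_peaks",
    "PROTON_MASS_DA",
]

#: proton mass used for native-MS m/z prediction, Da
PROTON_MASS_DA = 1.00728


@dataclass
class SeriesDesign:
    """Design of a 1:1 SEC-MALS dilution series.

    11 dilution points span roughly three orders of magnitude in
    concentration, matching the tabulated experimental ranges; MW noise is
    multiplicative with a 3% default.
    """

    top_concentration: float  # μM protomer-equivalent of the first injection
    n_dilutions: int = 11
    replicates: int = 1
    noise_mw: float = 0.03  # relative
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.top_concentration > 0:
            raise ValidationError(f"top_concentration must be > 0, got {self.top_concentration}")
        if self.n_dilutions < 1:
            raise ValidationError(f"n_dilutions must be >= 1, got {self.n_dilutions}")
        if self.noise_mw < 0:
            raise ValidationError(f"noise_mw must be >= 0, got {self.noise_mw}")


# Experimental-design reference: construct, monomeric MW (kDa), SEC column,
# and on-column concentration range (μM) observed across each dilution series.
_DESIGN_ROWS = [
    ("SAS-5_FL", 46.0, "Superose 6", 0.10, 0.57),
    ("SAS-5_FLEX-MsyB", 62.0, "Superose 6", 0.03, 9.5),
    ("SAS-5_2-265-MsyB", 46.0, "Superose 6", 0.02, 41.0),
    ("SAS-5_2-265-MsyB_SD200", 46.0, "Superdex 200", 0.05, 41.0),
    ("SAS-5_2-265_L141E", 46.0, "Superdex 200", 1.32, 63.0),
    ("SAS-5_2-265_L141E_M167E", 46.0, "Superdex 200", 1.16, 63.0),
    ("SAS-5_2-265_I247E", 46.0, "Superdex 200", 0.05, 63.0),
    ("SAS-5_2-265_L141E_I247E", 46.0, "Superdex 200", 0.82, 63.0),
    ("SAS-5_Imp", 6.5, "Superdex 75", 2.9, 292.0),
    ("SAS-5_CC-L", 12.5, "Superdex 75", 0.18, 152.0),
    ("C.briggsae_SAS-5_96-199", 12.7, "Superdex 75", 0.10, 149.0),
    ("C.brenneri_SAS-5_1-82", 10.2, "Superdex 75", 0.21, 186.0),
    ("C.remanei_SAS-5_98-206", 13.0, "Superdex 75", 0.21, 146.0),
    ("C.sinica_SAS-5_94-204", 13.0, "Superdex 75", 0.16, 145.0),
    ("C.tropicalis_SAS-5_94-199", 12.5, "Superdex 75", 0.12, 152.0),
]

SEC_MALS_DESIGNS = pd.DataFrame(
    _DESIGN_ROWS, columns=["construct", "monomeric_mw_kda", "column", "min_um", "max_um"]
)


def sec_mals_designs() -> pd.DataFrame:
    """Copy of the per-construct SEC-MALS design table."""
    return SEC_MALS_DESIGNS.copy()


def series_design_for(construct: str, **overrides) -> SeriesDesign:
    """A :class:`SeriesDesign` whose top concentration matches a tabulated construct."""
    rows = SEC_MALS_DESIGNS[SEC_MALS_DESIGNS.construct == construct]
    if rows.empty:
        raise KeyError(f"unknown construct {construct!r}; see sec_mals_designs()")
    kwargs = {"top_concentration": float(rows.iloc[0].max_um)}
    kwargs.update(overrides)
    return SeriesDesign(**kwargs)


def simulate_binding_series(scheme: AssemblyScheme, design: SeriesDesign) -> BindingCurve:
    """Simulate a 1:1 dilution-series SEC-MALS experiment.

    Concentrations are ``top × 2^-i`` for i = 0…n−1, each measured
    ``replicates`` times; observed MW carries multiplicative lognormal noise
    of relative scale ``noise_mw``.  Noise 0 reproduces the model curve
    exactly; identical seeds give identical output.
    """
    c = design.top_concentration * 2.0 ** -np.arange(design.n_dilutions, dtype=float)
    c = np.repeat(c, design.replicates)
    mw_true = predict_binding_curve(scheme, c).mw
    rng = np.random.default_rng(design.seed)
    mw = mw_true * np.exp(rng.normal(0.0, design.noise_mw, size=c.size)) if design.noise_mw > 0 else mw_true
    sigma = design.noise_mw * mw_true if design.noise_mw > 0 else None
    return BindingCurve(c, mw, mw_sigma=sigma, provenance="simulated")


def simulate_chromatogram(
    scheme: AssemblyScheme,
    load_c: float,
    peak_center: float = 12.0,
    peak_width: float = 0.35,
    noise: float = 0.01,
    seed: int = 0,
    n_slices: int = 401,
    dn_dc: float = DEFAULT_DN_DC,
    ls_calib: float = 0.01,
    asymmetry: float = 1.0,
) -> Chromatogram:
    """Simulate one injection's detector traces under fast exchange.

    The molar concentration profile is a (split-)Gaussian peak with apex
    ``load_c`` μM; each slice's composition comes from the mass-action
    equilibrium at that slice's concentration, so the slice MW varies across
    the peak exactly as the fast-exchange assumption implies.  Detector
    forward models: ``Δn = c_mass(g/ml) × dn/dc`` and
    ``LS = ls_calib × c_mass(mg/ml) × MW``; additive Gaussian noise is scaled
    to each trace's apex signal.  ``asymmetry`` > 1 widens the trailing flank
    (column-overloading caricature).
    """
    if not load_c > 0:
        raise ValidationError(f"load_c must be > 0, got {load_c}")
    w_lead, w_trail = peak_width, peak_width * asymmetry
    volume = np.linspace(peak_center - 6 * w_lead, peak_center + 6 * w_trail, n_slices)
    width = np.where(volume < peak_center, w_lead, w_trail)
    c_molar = load_c * np.exp(-0.5 * ((volume - peak_center) / width) ** 2)

    mw = np.empty_like(c_molar)
    for i, ci in enumerate(c_molar):
        if ci <= 0:
            mw[i] = scheme.unit_mass * scheme.base_order
        else:
            mw[i] = weight_average_mw(solve_equilibrium(scheme, ci))

    c_mass = c_molar * scheme.unit_mass / 1000.0  # mg/ml
    dri = (c_mass / 1000.0) * dn_dc  # dimensionless Δn
    ls = ls_calib * c_mass * mw
    if noise > 0:
        rng = np.random.default_rng(seed)
        dri = dri + rng.normal(0.0, noise * dri.max(), dri.size)
        ls = ls + rng.normal(0.0, noise * ls.max(), ls.size)
    return Chromatogram(volume, ls, dri, dn_dc=dn_dc, ls_calib=ls_calib)


def simulate_melting(fitpars: MeltingFit, grid, noise: float = 0.02, seed: int = 0) -> MeltingCurve:
    """Two-state melting curve on a temperature grid with multiplicative noise."""
    t = np.asarray(grid, dtype=float)
    theta = melting_model(fitpars, t)
    if noise > 0:
        rng = np.random.default_rng(seed)
        theta = theta * (1.0 + rng.normal(0.0, noise, t.size))
    return MeltingCurve(t, theta)


def simulate_cd_spectrum(
    fractions: SecondaryStructureFractions,
    wavelengths=None,
    basis: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> CDSpectrum:
    """Linear blend of basis component spectra with multiplicative noise.

    With noise 0 the output is exactly ``fractions · basis``, the inverse pair
    of :func:`oligomass.cdtherm.deconvolute_secondary_structure`.
    """
    if wavelengths is None:
        wavelengths = np.arange(190.0, 251.0)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if basis is None:
        basis = synthetic_basis(wavelengths)
    mre = fractions.as_array() @ np.asarray(basis, dtype=float)
    if noise > 0:
        rng = np.random.default_rng(seed)
        mre = mre * (1.0 + rng.normal(0.0, noise, mre.size))
    return CDSpectrum(wavelengths, mre)


@dataclass(frozen=True)
class MSPeak:
    """One native-MS peak: oligomer order, charge, and predicted m/z."""

    order: int
    charge: int
    mz: float


def predict_native_ms_peaks(
    scheme: AssemblyScheme, orders: list[int] | None = None, z_range: tuple[int, int] = (10, 30)
) -> list[MSPeak]:
    """Forward-predict native electrospray charge-state series.

    m/z = (order × unit mass in Da + z × m_proton) / z for each requested
    oligomer order and charge.  Orders default to every species in the scheme.
    """
    if orders is None:
        orders = list(scheme.orders)
    zmin, zmax = z_range
    if zmin < 1:
        raise ValidationError(f"minimum charge must be >= 1, got {zmin}")
    peaks = []
    for order in orders:
        if order not in scheme.orders:
            raise KeyError(f"no species of order {order} in scheme {scheme.name!r}")
        mass_da = order * scheme.unit_mass * 1000.0
        for z in range(zmin, zmax + 1):
            peaks.append(MSPeak(order, z, (mass_da + z * PROTON_MASS_DA) / z))
    return peaks
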