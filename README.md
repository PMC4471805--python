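# oligomass

Mass-action analysis of protein homo-oligomerization from SEC-MALS and
circular-dichroism data.

Many proteins — coiled coils in particular — self-associate with
dissociation constants in the low-micromolar range, so their oligomeric
state depends on concentration. The canonical way to characterize such
systems is a 1:1 dilution series on a size-exclusion column with in-line
multi-angle light scattering (SEC-MALS): every injection yields an
on-column concentration (from the differential refractive index, with
dn/dc = 0.1850 ml/g) and a weight-average molecular weight

```
MW_w = Σᵢ cᵢ Mᵢ² / Σᵢ cᵢ Mᵢ
```

over the oligomeric species with molar concentrations cᵢ and masses Mᵢ.
`oligomass` models such systems as mass-action assembly schemes — a base
unit (monomer, or an obligate dimer when one interface is effectively
undissociable) plus ordered association steps with stepwise dissociation
constants — solves the equilibria exactly by bracketed root finding, fits
schemes to measured binding curves, and reports the model-free **apparent
Kd**: the total concentration at which MW_w crosses the midpoint between
the smallest and largest species masses. For a direct monomer↔trimer
equilibrium with kd₃ = [M]³/[T], the midpoint sits at c = 2·√(kd₃/3).

The package was built around the *C. elegans* centriolar protein SAS-5,
whose architecture combines a trimerizing coiled coil (apparent Kd ≈ 3 μM)
with a tightly dimerizing helical domain, so that tagged constructs climb
a dimer → tetramer → hexamer ladder with concentration. Schemes for all
of these ship as presets, but the machinery is generic.

It also covers the accompanying CD workflow: Savitzky–Golay smoothing,
high-tension-voltage truncation, mean-residue ellipticity conversion,
helix/strand/coil deconvolution by nonnegative least squares, and one- or
two-transition van't Hoff fits of θ₂₂₂ melting curves (linear baselines,
ΔCp = 0), with per-transition cooperativity diagnostics and ΔTm between
paired fits. Seeded generators simulate every input the pipeline consumes.

Intended users: structural biologists and biophysicists reducing SEC-MALS
dilution series or CD melts, and method developers who need a transparent,
scriptable alternative to closed instrument software.

## Worked example

Simulate the coiled-coil dilution series (11-point 1:1 series from 152 μM,
three replicates, 3% multiplicative MW noise) and fit it:

```python
import numpy as np
import oligomass as om

scheme = om.monomer_trimer(12.5, om.kd3_for_apparent_kd(3.0))
design = om.SeriesDesign(top_concentration=152.0, n_dilutions=11,
                         replicates=3, noise_mw=0.03, seed=1)
curve = om.simulate_binding_series(scheme, design)
fit = om.fit_association(curve, om.monomer_trimer(12.5, 1.0),
                         bootstrap=200, seed=1729)
print(f"apparent Kd = {fit.apparent_kd:.2f} uM "
      f"(95% CI {fit.apparent_kd_ci[0]:.2f}-{fit.apparent_kd_ci[1]:.2f})")
```

prints

```
apparent Kd = 3.07 uM  (95% CI 2.89-3.25)
```

i.e. the fit recovers the generative midpoint (3 μM) from noisy data, with
a bootstrap interval that brackets it. A two-step melting curve is fitted
the same way:

```python
grid = np.arange(4.0, 91.0)
params = om.MeltingFit((om.Transition(50.0, 250.0, 0.5),
                        om.Transition(70.0, 250.0, 0.5)),
                       baseline_folded=(-20000.0, 25.0),
                       baseline_unfolded=(-3000.0, -5.0))
melt = om.simulate_melting(params, grid, noise=0.02, seed=1)
mfit = om.fit_melting(melt, n_transitions=2)
for i, tr in enumerate(mfit.transitions, 1):
    print(f"transition {i}: Tm = {tr.tm:.1f} C, "
          f"dH_vH = {tr.dh_vh:.0f} kJ/mol, cooperative = {tr.cooperative}")
```

```
transition 1: Tm = 50.1 C, dH_vH = 236 kJ/mol, cooperative = True
transition 2: Tm = 70.2 C, dH_vH = 236 kJ/mol, cooperative = True
```

Both generative midpoints (50 and 70 °C) are recovered to within a few
tenths of a degree at 2% noise.

A CLI wraps the same machinery (`oligomass simulate|process|fit|melt|
deconvolute|mspeaks`); run `oligomass --help` for the subcommands.

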