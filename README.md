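# herbe — biological dose engine for helium-ion beams

Helium (⁴He) ion beams are entering clinical use, but unlike protons they
cannot be planned with a constant RBE: the relative biological effectiveness
of a helium field varies with dose-averaged LET, dose level and tissue
radiosensitivity, and different published models disagree by clinically
relevant margins.  `herbe` is a small, fully tested engine for exactly that
problem space, aimed at medical physicists and radiobiology researchers who
need reproducible RBE-weighted dose calculations outside a Monte-Carlo
treatment-planning system.

## The model

Cell survival follows the linear-quadratic (LQ) model,
S = exp(−(αD + βD²)).  RBE is the isoeffective dose ratio D_x/D_p between
the reference photon radiation and the particle radiation, which in the LQ
framework is a closed function of the photon ratio (α/β)_x, the particle
dose D, the initial RBE **RBE_α = α/α_x** and **R_β = β/β_x**:

    RBE = −(α/β)_x/(2D) + √((α/β)_x²/4 + RBE_α(α/β)_x·D + R_β·D²) / D

Three interchangeable parameterizations supply (RBE_α, R_β) from radiation
quality:

* **DDM** — a data-driven phenomenological fit: RBE_α = 1 + [k₀+(α/β)_x⁻¹]·
  k₁L\*·exp(−k₂L\*²) and a tissue-independent Gaussian R_β(L\*), with the
  published coefficients as defaults;
* **modified MKM** — RBE_α = 1 + z\*₁D/(α/β)_x from the saturation-corrected
  dose-mean specific energy of a microdosimetric domain (R_d = 0.3 µm,
  R_n = 3.6 µm), R_β = 1;
* **LEM (low-dose approximation)** — RBE_α = (1−e^(−α_z d₁))/(α_x d₁) from
  intrinsic tables, with β_z ≈ (s_max−α_z)/(2D_t) clamped at zero and
  R_β = (α/α_z)²(β_z/β_x).

Around the core sit: dose-weighted mixed-field LQ combination for Z=1/Z=2
components, depth-resolved forward D_RBE = RBE·D calculation, biological
SOBP weight optimization, EUD and DVH statistics (D_50%, D_5%, D_95%, I_5%),
weighted LQ fitting of clonogenic survival data, and a deterministic
synthetic generator for Bragg curves, LET_d profiles and Poisson-noise
well-plate assays.

## Worked example

RBE versus dose for a measured SOBP condition (LET_d ≈ 15 keV/µm helium
against its photon baseline, both from the packaged clonogenic LQ table):

```python
from herbe import helium_lq_row, rbe_experimental

tissue, ion = helium_lq_row("B", 15.37)
for d in (1.0, 2.0, 4.0):
    pt = rbe_experimental(tissue, ion, d)
    print(f"D = {d:.1f} Gy   RBE = {pt.rbe:.2f}   D_RBE = {pt.d_rbe:.2f} Gy (RBE)")
```

```
D = 1.0 Gy   RBE = 2.18   D_RBE = 2.18 Gy (RBE)
D = 2.0 Gy   RBE = 1.78   D_RBE = 3.56 Gy (RBE)
D = 4.0 Gy   RBE = 1.46   D_RBE = 5.84 Gy (RBE)
```

RBE falls with dose, as the quadratic photon term catches up — at 1 Gy this
radio-resistant line ((α/β)_x ≈ 2.2 Gy) is over twice as sensitive to helium
as to photons.

A biologically optimized 4-cm SOBP at 2 Gy (RBE), from synthetic kernels:

```python
from herbe import load_tissue, kernel_library, optimize_sobp, target_eud

water2 = load_tissue("water2")          # (alpha/beta)_x = 2 Gy
kernels = kernel_library(60.0, 100.0)   # Bragg peaks every 2 mm
res = optimize_sobp(kernels, 2.0, (60.0, 100.0),
                    model="ddm", tissue=water2, mode="biological")
curve = res.report.curves["ddm"]
sl = res.target_slice
print(f"converged in {res.iterations} iterations")
print(f"target D_RBE: {curve.d_rbe[sl].mean():.3f} +/- {curve.d_rbe[sl].std():.3f} Gy (RBE)")
print(f"entrance RBE {curve.rbe[0]:.2f} -> distal-target RBE {curve.rbe[sl][-1]:.2f}")
print(f"target EUD = {target_eud(res.report, water2, target=(60, 100)):.3f} Gy")
```

```
converged in 9 iterations
target D_RBE: 2.002 +/- 0.007 Gy (RBE)
entrance RBE 1.43 -> distal-target RBE 4.54
target EUD = 2.002 Gy
```

The biological dose is flat across the target to ~0.4%, while RBE climbs
with LET_d toward the distal edge — so the underlying physical dose slopes
downward, the signature of biological SOBP optimization.

The same machinery is scriptable from the shell (`herbe rbe-curve`,
`herbe sobp-forward`, `herbe sobp-optimize`, `herbe fit-survival`,
`herbe simulate`, `herbe dvh`); every run writes a `manifest.json` with the
configuration, package version and seed.

## Documentation

`docs/methods.md` describes the models, conventions, synthetic-data
assumptions and numerical choices in detail.
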