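# cestpipe

Postprocessing and quantification for CEST-MRI (chemical exchange
saturation transfer) z-spectra, aimed at preclinical amide-proton-transfer
weighted (APTw) and 2-deoxy-D-glucose (glucoCEST) imaging — for example
murine tumor studies at 9.4 T — and at the phantom experiments used to
validate them.

CEST selectively saturates labile solute protons (amide backbone protons at
+3.50 ppm, glucose hydroxyls at +0.66/+1.28/+2.08/+2.88 ppm) and detects
the transferred saturation as attenuation of the water signal. The
z-spectrum of a voxel is

    Z(Δω) = M_z(Δω) / M_z⁰,

the saturated image intensity at offset Δω normalized by an unsaturated
reference. The package implements the full chain from raw stacks to group
statistics:

1. **Normalization and spline smoothing** of z-spectra.
2. **B0 correction** from a WASSR scan (narrow, low-power water dip): the
   per-voxel water-resonance offset is located by spline-minimum search plus
   symmetry matching and the CEST spectrum is resampled so water sits at 0 ppm.
3. **Five-pool Lorentzian fitting**: Z(ω) = Z_base − Σₖ aₖ / (1 + 4((ω −
   ωₖᶜ)/σₖ)²) with APTw pools {water, amide (label), amine, MT, NOE} or
   glucoCEST pools {water, +0.66, +1.28 (label), +2.08, +2.88 ppm}.
4. **Four quantification metrics** per voxel at the label frequency δ:
   * MTR_asym(δ) = Z(−δ) − Z(+δ) (reported in %),
   * Lorentzian amplitude a_label,
   * MTR_REX(δ) = 1/Z_lab − 1/Z_ref, where Z_lab = Z_base − Σᵢ Lᵢ(δ) and
     Z_ref excludes the label pool (spillover-corrected),
   * AREX(δ) = MTR_REX(δ) / T1_obs, with T1_obs fitted per voxel from a
     variable-TR saturation-recovery series (T1-compensated).
5. **Delta maps** (post-challenge − baseline), two-ROI **CNR**
   |μ₁−μ₂|/√(σ₁²+σ₂²), ROI means, IQR outlier exclusion, and a
   normality-gated group comparison (Shapiro–Wilk → ANOVA + Tukey HSD, or
   Kruskal–Wallis + Benjamini–Hochberg-corrected rank-sum tests).

A synthetic-data module generates concentration phantoms, three-group tumor
cohorts, WASSR/T1 series, and smooth B0 fields, and includes an independent
Bloch–McConnell simulator used as a physics oracle in the tests.

## Worked example

```python
import cestpipe as cp
from cestpipe.synth import PhantomDesign, generate_phantom
from cestpipe.stats import roi_mean

design = PhantomDesign(grid_shape=(32, 32), vial_radius=2.0, preset="dg2")
bundle = generate_phantom(design, seed=1)          # 5 vials, 4.5-22.5 mM
result = cp.process_stack(bundle.cest, bundle.wassr, bundle.t1_series,
                          preset="dg2")
for name, pmap in result.maps.items():
    means = [roi_mean(pmap, bundle.roi_labels == v)[0] for v in range(1, 6)]
    print(name, [round(m, 4) for m in means])
```

prints

```
mtr_asym [1.0324, 2.0648, 3.0972, 4.1296, 5.1619]
lorentz_amp [0.009, 0.018, 0.027, 0.036, 0.045]
mtr_rex [0.0141, 0.0287, 0.0438, 0.0593, 0.0753]
arex [0.0071, 0.0144, 0.0219, 0.0296, 0.0377]
```

— each row is one metric's vial-ROI mean across the five 2-DG
concentrations. MTR_asym is in percent; the fitted label amplitude
reproduces the generator's amplitude-per-concentration slope (0.002 × 4.5
mM = 0.009, …); MTR_REX and AREX rise monotonically with concentration,
with AREX = MTR_REX / 2 s here since the phantom's T1 is uniform.

The same pipeline is available from the shell:

```sh
cestpipe simulate --kind phantom --preset dg2 --seed 1 --out sim/
cestpipe run config.yaml
cestpipe stats --cohort cohort.tsv --metric arex --out report.json
```

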