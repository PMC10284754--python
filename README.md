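# luquant

Quantification of ¹⁷⁷Lu activity concentration in sphere phantoms — the
measurement problem behind tumor dosimetry in ¹⁷⁷Lu radionuclide therapy
(PRRT, PSMA radioligand therapy).

When a tumor is not much larger than the SPECT resolution, and when ¹⁷⁷Lu
is also present in surrounding tissue, the apparent activity concentration
read from a reconstructed image is biased by spill-out and spill-in.
`luquant` implements and evaluates three practical measurement methods on
NEMA-IEC-style sphere phantoms (six spheres, ø10–37 mm, variable
sphere-to-background ratio):

1. **Large VOI** — a sphere of diameter *d* + 15 mm around the object,
   combined with the known object volume;
2. **Small VOI** — a ø10/15/20 mm sphere at the object center;
3. **Threshold VOI** — region grown at 40/50 % of the maximum voxel value
   (or 50/60 % of the 1 cm³ peak value), with partial-volume correction.

The partial-volume correction rests on two fitted models:

- the recovery-coefficient curve
  **RC(d) = 1 / (1 + (α/d)^β)**,
  fitted to background-free data, and
- the VOI-volume growth law
  **V_VOI(V) = V₀ + c·V·(1 − e^(−V/V₁))**, 0 < c ≤ 1,
  whose lookup-table inversion yields the volume scale v = V(V_VOI)/V_VOI,
  the effective diameter **d′ = (v·6V_VOI/π)^{1/3}**, and the corrected
  concentration **C = C_VOI / RC(d′)**. VOIs with V_VOI < V₀ are excluded.

Because raw SPECT acquisitions of such phantoms are rarely shared, the
package ships a synthetic phantom generator (`luquant.phantom`) producing
voxel images with known ground truth and the degradation characteristics of
three reconstruction families (sharp with edge ringing, Gaussian
post-filtered, and edge-preserving/anatomical-prior). Real quantitative
SPECT volumes in NIfTI are accepted by all analysis stages.

## Worked example

```python
from luquant import *

spec = make_phantom_series(default_phantom(), [9.5])[0]   # P_9.5 phantom
variant = default_variants()["smoothed"]                  # 10 mm post-filter
truth, img = simulate_phantom(spec, variant, seed=42)

sphere = [s for s in spec.spheres if s.diameter == 28][0]
dia = spherical_voi(img, sphere.center, sphere.diameter)
stats = voi_stats(img, dia)
bkg = voi_stats(img, background_voi(img, spec))
print(f"mean in VOI_dia      : {stats.mean:.1f} kBq/ml")
print(f"contrast             : {contrast(stats.mean, bkg.mean):.3f}")
print(f"measured SBVR        : {sbvr(stats.mean, bkg.mean):.2f}")

decision = check_criteria("threshold", tumor_diameter=28.0, tumor_to_background=9.5)
print(decision.eligible, decision.reason)
```

prints

```
mean in VOI_dia      : 262.1 kBq/ml
contrast             : 0.658
measured SBVR        : 4.85
False diameter not > 30 mm
```

The ø28 sphere is filled at 514 kBq/ml, but the diameter-matched VOI mean
reads only 262 kBq/ml: with a ~16 mm effective resolution roughly half of
the sphere signal spills out, which is exactly the bias the
recovery-coefficient machinery corrects. The measured sphere-to-background
voxel ratio (4.85) likewise sits well below the true fill ratio of 9.5.
The selection rule for the threshold method (diameter > 30 mm and
tumor-to-background ratio > 3) correctly rejects this 28 mm object.

The full sweep — four background ratios × three reconstructions × all
twelve methods, with repeated noise realizations — runs in well under a
minute:

```bash
luquant run --out results/           # tidy CSV tables + fitted models
luquant simulate --ratio 2.7 --variant sharp --seed 1 --out p27.nii.gz
luquant criteria --method small_voi --diameter 35 --ratio 2.5
```

`run` writes per-figure-family tables (`max_peak.csv`, `contrast_rc.csv`,
`threshold.csv`, `pvc.csv`, `cf_sbvr.csv`, …), `models.json` with fitted
(α, β) and (V₀, c, V₁) per reconstruction, and a run manifest; reruns with
the same config and seed are byte-identical.

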