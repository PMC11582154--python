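# ivimdrift

Signal drift — the slow, spatially varying change in image intensity over a
diffusion MRI (dMRI) scan — is a key confounder for quantitative dMRI of the
brain, and in particular for intravoxel incoherent motion (IVIM) imaging,
which relies on subtle signal variations at very low b-values. `ivimdrift`
provides a tested, reusable pipeline for characterizing and correcting
signal drift and for estimating IVIM parameters with three protocol-specific
estimators, together with a synthetic brain-like phantom generator so that
every stage is verifiable at desk scale without scanner data.

It is aimed at quantitative-MRI researchers who want to (a) correct drift in
their own dMRI acquisitions with interspersed b = 0 volumes, (b) study how
acquisition ordering converts drift into parameter bias, or (c) benchmark
IVIM estimators on controlled synthetic data.

## Models

**Drift corrections.** Using the b = 0 volumes interspersed in a scan, a
second-order temporal polynomial is fitted to the signal as a function of
acquisition index n,

    S(n | b_n = 0) = k0 + k1 n + k2 n²,

either once for the whole-mask median signal (*global*) or per voxel
(*voxelwise*). The *spatiotemporal* method instead fits, after voxelwise
normalization to the first b = 0 volume, a polynomial that is second order
in both time and space,

    S(n; x,y,z | b_n = 0) = p0(x,y,z) + p1(x,y,z)·n + p2(x,y,z)·n²,

where each p_i contains all spatial monomials x^a y^b z^g with a,b,g ≤ 2 —
81 coefficients in total — estimated by robust bisquare (Tukey biweight)
regression. All volumes, diffusion-weighted or not, are then divided by the
fitted polynomial (normalized to 1 at the first b = 0 acquisition so the
corrected data keep their physical scale).

**IVIM estimators.** After geometric direction-averaging,

* *sIVIM* (3 b-values, closed form): D = (ln S1 − ln S2)/(b2 − b1),
  A = S1 e^{b1 D}, f = 1 − A/S0;
* *diffusive regime* (10 b-values): bounded nonlinear least squares of
  S(b) = S0((1−f) e^{−bD} + f e^{−bD\*});
* *ballistic regime* (flow-compensated + non-flow-compensated bipolar
  encodings): bounded nonlinear least squares of
  S(b,c) = S0((1−f) e^{−bD} + f e^{−b D_b} e^{−c² v_d²}) with the blood
  diffusivity D_b fixed at 1.75 µm²/ms, where c is the flow-encoding factor
  (s/mm) and v_d the velocity dispersion of blood (mm/s).

The package also implements the acquisition-order simulation (re-sorting
spatiotemporally corrected data into ascending-b order and re-applying the
inverse drift), ROI drift summaries, test–retest repeatability records, and
exact (fully enumerated) Friedman and Wilcoxon signed-rank tests.

## Worked example

```python
import numpy as np
import ivimdrift as iv

phantom = iv.synthdata.make_phantom((32, 32, 8), seed=1)
scheme = iv.scheme.protocol_preset("diffusive")
clean = iv.synthdata.forward_signal(phantom.maps, scheme, "diffusive", phantom.mask)
drift = iv.synthdata.make_drift_model({"frontal": -5, "inferior": 5}, phantom, scheme)
series = iv.synthdata.add_noise(iv.synthdata.apply_drift(clean, drift),
                                sigma=iv.synthdata.sigma_for_snr(clean, 100), seed=2)

model = iv.driftcorr.fit_spatiotemporal(series)
corrected = iv.driftcorr.apply_correction(series, model)

for name, roi in phantom.roi_masks.items():
    before = iv.driftstats.drift_first_last(series, roi).value
    after = iv.driftstats.drift_first_last(corrected, roi).value
    print(f"{name}: drift {before:+.2f} -> {after:+.2f} %/5min")

fit = iv.ivimfit.fit_diffusive(iv.ivimfit.geometric_average(corrected))
for name, roi in phantom.roi_masks.items():
    print(f"{name}: D = {np.nanmedian(fit.maps.D[roi]):.2f} um2/ms, "
          f"f = {100*np.nanmedian(fit.maps.f[roi]):.1f} %, "
          f"D* = {np.nanmedian(fit.maps.Dstar[roi]):.1f} um2/ms")
```

prints

```
PFWM: drift -5.19 -> -0.24 %/5min
CS: drift +4.67 -> -0.40 %/5min
CB: drift +5.57 -> +0.54 %/5min
PFWM: D = 0.75 um2/ms, f = 4.2 %, D* = 21.4 um2/ms
CS: D = 0.76 um2/ms, f = 5.0 %, D* = 10.0 um2/ms
CB: D = 0.78 um2/ms, f = 3.8 %, D* = 15.2 um2/ms
```

The first block shows the ROI drift (percent signal change per 5 minutes,
from the first/last b = 0 volumes) before and after the spatiotemporal
correction: the imposed ±5 %/5 min drift in prefrontal white matter (PFWM)
and cerebellum (CB) is reduced to a fraction of a percent. The second block
gives ROI-median IVIM estimates from the corrected data, in the healthy-brain
ranges the phantom was built from.

The same stages are available from the shell:

```sh
ivimdrift simulate --protocol diffusive --seed 1 --out run/
ivimdrift correct --method spatiotemporal run/raw_0 --out run/corr_0
ivimdrift fit --regime diffusive run/corr_0 --out run/maps
ivimdrift run --config config.yaml     # full pipeline from YAML
```

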