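# psirsynth

Joint post-contrast T1/T2 cardiac relaxometry and **calculated bright-blood /
dark-blood PSIR LGE** from a single multi-parametric saturation-recovery
(mSASHA) acquisition.

## The problem

Late gadolinium enhancement (LGE) CMR nulls normal myocardium so that focal
scar appears bright, but conventional bright-blood LGE often has poor contrast
between subendocardial infarct and the adjacent blood pool, and quantitative
T1/T2 maps — needed for diffuse disease — require separate scans. A
multi-parametric saturation-recovery acquisition yields co-registered T1 and
T2 maps in one free-breathing scan (30 single-shot images over 45 heartbeats),
and both a bright-blood and a dark-blood phase-sensitive (PSIR) LGE image can
then be *calculated* from the maps, with no inversion-time scouting and all
four outputs intrinsically co-registered.

This package implements the full chain for simulation studies and map-based
synthesis: signal models, protocol scheduling, digital phantoms, the joint
pixel-wise fitter, PSIR synthesis, and Monte-Carlo SNR/CNR propagation.

## The model

Each mSASHA frame follows a saturation preparation; the pixel signal is

```
S_i = A (1 − exp(−τ_i / T1)) · exp(−TE_i / T2)
```

with τ_i the saturation-to-readout delay (TS = 300 ms for SR frames,
3·RR + TS for the long-recovery anchors) and TE_i the T2-preparation echo
time (55 ms where applied, else 0). A trust-region nonlinear least-squares
fit of (A, T1, T2) per pixel gives decoupled T1 and T2 maps.

The calculated PSIR images are formed in relaxation-rate units
(R1 = 1000/T1, R2 = 1000/T2, both in Hz), linear in gadolinium
concentration:

```
BB = R1 − R1m
DB = R1 − R1m / (a_DB · R2/R2m + (1 − a_DB))
a_DB = (R1m·R2m/(R1b − LGEb) − R2m) / (R2b − R2m)
```

where (R1m, R2m) and (R1b, R2b) are normal-myocardium and blood-pool
reference rates (map medians over segmentation masks) and LGEb (default
−0.5 Hz) fixes the blood level in the dark-blood image: normal myocardium is
nulled in both images, and the blood pool lands exactly at LGEb in DB.

## Worked example

```python
import numpy as np
from psirsynth import run_all

bundle = run_all("chronic_mi", snr=40, seed=1, out_dir="out")
print(bundle["results"].summary())
ref = bundle["reference"]
print(f"a_DB = {ref.a_db:.3f}")
for name in ("mi", "remote", "blood"):
    m = bundle["phantom"].mask(name)
    print(name, f"BB {np.nanmean(bundle['bb'].values[m]):+.3f} Hz",
          f"DB {np.nanmean(bundle['db'].values[m]):+.3f} Hz")
```

prints

```
Joint T1/T2 saturation-recovery fit
===========================================
protocol:        msasha-default (30 frames)
pixels fitted:   5024
converged:       5024 (100.0%)
median T1 [ms]:       482.7
median T2 [ms]:        50.5
median A:            0.9999
max RMS resid:    3.557e-02
a_DB = 0.617
mi BB +0.765 Hz DB +0.731 Hz
remote BB -0.006 Hz DB -0.001 Hz
blood BB +0.645 Hz DB -0.500 Hz
```

Reading this: a chronic-infarct phantom slice was simulated at anchor-image
SNR 40 and jointly fitted (every pixel converged). The scar (short T1 441 ms)
is bright in both calculated images (~+0.77 Hz, the R1 separation from remote
myocardium); remote myocardium is nulled (≈ 0); and the blood pool, bright in
BB (+0.65 Hz, barely distinguishable from scar), is pinned to the configured
LGEb = −0.5 Hz in DB — which is why dark-blood LGE recovers the
scar-to-blood contrast that bright-blood LGE lacks.

The same pipeline is available from the shell:

```bash
psirsynth run-all --scenario chronic_mi --snr 40 --seed 1 --out out/
psirsynth simulate --phantom t1mes --snr 40 --seed 0 --out sim/
psirsynth fit --series sim/ --mask sim/labels.nii.gz --out maps/
psirsynth attenuate --remote 600,42 --blood 400,150 --out att.json
```

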