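# dynpet

Quantification of **early-dynamic PET** acquisitions — the first ~30 minutes
after a bolus injection, binned into 1-minute frames — aimed at studies of
⁶⁸Ga-PSMA-11 uptake in primary prostate cancer and similar tracers.

Dynamic PET shows the distribution phase that a static scan at 45–60 min
cannot: the arterial first pass, how quickly blood pool and background
muscle settle, when urinary activity starts flooding the bladder, and
whether a lesion's time-activity curve (TAC) keeps climbing or levels off.
`dynpet` turns a 4-D PET volume plus a region label map into per-region
TACs and applies simple, operational curve-shape rules:

* **SUL normalization** — SUL = C · LBM/A₀, with C the region-mean
  activity concentration (Bq/mL), A₀ the injected activity (Bq) and LBM the
  lean body mass (Janmahasatian fat-free-mass formula by default);
* **plateau detection** — the earliest window from which the TAC slope
  stays at |dSUL/dt| ≤ 0.2 SUL·min⁻¹ (3-frame least-squares slope,
  sustained over all later windows);
* **bladder-filling onset** — the first frame where bladder SUL reaches
  2× the gluteal-muscle (background) SUL;
* **stable vs rising classification** — stable if a plateau is found at or
  before 10 min, rising otherwise;
* **test–retest repeatability** — per-subject percentage change
  |x₂ − x₁|/x₁ · 100 with cohort median (range), and the inter-subject
  coefficient of variation SD/mean · 100;
* **tumor-to-blood ratio (TBR)** — lesion SUL over image-derived arterial
  input (common iliac artery ROI).

Because no public dynamic dataset accompanies this kind of study, the
package ships a first-class **kinetic phantom**: a Feng-type arterial input
function, one-tissue-compartment regions with optional irreversible
trapping (Ki > 0 ⇒ curves that keep rising; Ki = 0 ⇒ curves that plateau),
a filling-bladder model, lognormal between-subject/between-visit parameter
variation, Gaussian frame noise, and a voxel renderer that writes
BIDS-PET-style NIfTI + JSON. Every detector is therefore testable against
known ground truth.

## Worked example

```python
import numpy as np
from dynpet import (default_scene, simulate_scene_tacs, detect_plateau,
                    bladder_onset, arterial_peak, classify_uptake,
                    tumor_to_blood)

tacs = simulate_scene_tacs(default_scene(alpha=0.01, seed=1))
peak_sul, peak_t = arterial_peak(tacs["artery"])
print(f"arterial peak SUL {peak_sul:.2f} at {peak_t:.1f} min")
for name in ("artery", "muscle"):
    r = detect_plateau(tacs[name])
    print(f"{name}: plateau at {r.plateau_time:.1f} min, level {r.plateau_level:.2f} SUL")
for name in ("tumor_stable", "tumor_rising"):
    print(f"{name}: {classify_uptake(tacs[name]).label}")
print(f"bladder filling onset {bladder_onset(tacs['bladder'], tacs['muscle']).onset_time:.1f} min")
print(f"rising-lesion TBR (last frame) {tumor_to_blood(tacs['tumor_rising'], tacs['artery'])[1]:.1f}")
```

prints

```
arterial peak SUL 4.17 at 0.5 min
artery: plateau at 5.5 min, level 1.22 SUL
muscle: plateau at 3.5 min, level 0.47 SUL
tumor_stable: stable
tumor_rising: rising
bladder filling onset 9.5 min
rising-lesion TBR (last frame) 9.6
```

Reading: the image-derived arterial input peaks in the first 1-minute frame
(SUL ≈ 4.2) and settles to its blood-pool plateau (≈ 1.2) around 5 min;
muscle background is flat (≈ 0.4–0.5) from about 3 min; the small
reversible lesion is classified *stable* while the large trapping lesion
keeps accumulating (*rising*); urine activity reaches twice background at
9.5 min.

## Command line

```bash
dynpet simulate --mode voxel --seed 1 --out scene/     # 4-D NIfTI + labels + sidecar
dynpet extract  --image scene/dynamic.nii.gz --sidecar scene/dynamic.json \
                --labels scene/labels.nii.gz --label-names scene/labels.json \
                --out tacs.csv
dynpet analyze  --tacs tacs.csv --out kinetics.csv
dynpet pipeline --seed 1 --subjects 5 --out run/       # cohort + repeatability report
dynpet report   --cohort run/ --out run/summary        # Table-style median (range) + CoV
```

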