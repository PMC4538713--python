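# navmc

Motion quality control and motion correction for simultaneous PET/MR brain
imaging using **sparsely sampled MR navigators**.

During a 30-minute brain PET acquisition on a PET/MR scanner, fast 3D MR
navigator volumes can be slotted into the gaps between diagnostic MR
sequences — six bursts of ten navigators is enough to characterise rigid
head motion without stealing MR time. `navmc` implements the full pipeline
around that idea, for physicists and methods researchers working on PET
motion correction:

1. **Registration** — each navigator is rigidly registered to the first
   (NCC metric, Gaussian pyramid, deterministic shrinking-step search).
2. **Motion QC** — the motion magnitude
   `‖T·(0, 60, 0)ᵀ − (0, 60, 0)ᵀ‖` of each navigator transform `T`
   (homogeneous coordinates) is traced at a frontal-cortex point 60 mm
   anterior of the scanner isocentre and at the isocentre itself;
   intra-burst spread flags registration noise; correction is recommended
   when the maximum exceeds 4 mm.
3. **Framing** — PET frames are split at midpoints between navigator start
   times, linking every event to its nearest motion sample.
4. **Correction (MAF)** — multiple-acquisition-frames: each frame is pulled
   back to the reference pose and the frames are duration-weighted
   averaged; frame 1 is the reference and carries no transform.
5. **Quantification** — SUVr = mean(target) / mean(cerebellum), with
   SUVr > 1.5 read as abnormal amyloid (PiB) uptake.

Because clinical navigator datasets are not redistributable, the package
ships a **synthetic session simulator**: an ellipsoidal digital head
phantom (cortical shell, white matter, cerebellum, ventricle) rendered
analytically under scripted rigid motion into navigator volumes (64×64×36
at 3 mm, SNR 20) and Poisson-noisy PET frames (5 mm FWHM PSF), with exact
ground-truth transforms for parameter-recovery testing. See
`docs/methods.md` for the model, parameter choices and limitations.

## Worked example

```python
import numpy as np
import navmc
from navmc import qc, suvr, synthetic

# a 30-min session with 8 mm of nod+slide head motion, known ground truth
sess = synthetic.preset_session(seed=7, max_motion_mm=8.0)

# register the representative navigator of each burst to the first
fixed = sess.navigators[0][0]
results = [navmc.register_rigid(b[0], fixed) for b in sess.navigators[1:]]
trace = qc.build_trace(results, [b[0] for b in sess.nav_times_s[1:]],
                       reference_time_s=sess.nav_times_s[0][0])
report = qc.decide_mc(trace)
print(f"max motion at frontal cortex: {trace.max_magnitude('frontal_cortex'):.2f} mm")
print(f"MC recommended (>4 mm rule):  {report.mc_recommended}")

# frame-by-frame correction and SUVr
transforms = [navmc.identity()] + [r.transform for r in results]
corr = navmc.correct_frames(sess.pet_frames, transforms)
cx = suvr.erode_mask(sess.masks["cortex"], 2)
cb = suvr.erode_mask(sess.masks["cerebellum"], 2)
print(f"SUVr: {suvr.compute_suvr(corr.volume, cx, cb, valid=corr.valid):.2f}")
```

prints

```
max motion at frontal cortex: 8.04 mm
MC recommended (>4 mm rule):  True
SUVr: 2.53
```

The trace reads the scripted 8 mm of motion back off the noisy navigators
to within ~0.05 mm, triggers the >4 mm correction rule, and the corrected
image recovers the phantom's amyloid-positive uptake ratio (set value 2.6,
blurred by the 5 mm PET resolution). Against the motion-free reference the
corrected image's RMSE is 0.0143 vs 0.1017 for the uncorrected average —
correction removes ~86% of the motion error.

A command-line interface mirrors the library:

```bash
navmc simulate --seed 7 --max-motion 8 --outdir session/
navmc register --fixed session/nav01_01.nii.gz --moving session/nav06_01.nii.gz --out T6.txt
navmc frames --timing session/timing.csv --out schedule.csv
navmc qc --timing session/timing.csv --navs session/nav0?_01.nii.gz --out qc.json --plot trace.svg
navmc correct --frames session/frame*.nii.gz --transforms T*.txt --out mc.nii.gz
navmc suvr --image mc.nii.gz --target session/mask_cortex.nii.gz --reference session/mask_cerebellum.nii.gz
```

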