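# fetalt2star

Regional T2* relaxometry of the fetal brain from motion-corrupted,
low-field multi-echo MRI — as a fully synthetic, testable pipeline.

## The problem

Effective transverse relaxation (T2*) of fetal brain tissue is an indirect
window on in-utero oxygenation (the BOLD effect) and on tissue maturation.
At low field (0.55 T) T2* values are long enough that even low-T2*
structures such as deep gray matter can be quantified. But fetal
acquisitions are coarse (3×3×3 mm multi-echo gradient-echo EPI, echo times
42/107/172 ms, 15–30 dynamics) and the fetus moves: every 2-D slice is
acquired at its own unknown rigid position. Turning such data into
per-region normative curves over gestation takes a chain of steps:

1. **phantom** — gestational-age-parameterized digital fetal-brain phantom
   (7 anatomical compartments), mono-exponential forward signal
   S(TE) = S0·exp(−TE/T2*), per-slice rigid motion, Rician noise;
2. **reconstruction** — multichannel rigid slice-to-volume
   super-resolution at 1.2 mm: per-slice registration on the best-contrast
   echo, motion shared across echoes, NCC-based slice/dynamic rejection,
   regularized least-squares inversion of the Gaussian/boxcar
   point-spread model;
3. **relaxometry** — voxelwise T2* mapping (log-linear OLS of ln S on TE
   by default, damped nonlinear least squares as an alternative), with
   validity masks instead of clamping;
4. **regional** — merging a 19-label parcellation into 7 categories
   (eCSF, gray matter, white matter, deep gray matter, ventricles,
   cerebellum+vermis, brainstem) and computing per-region mean T2* and
   volumes;
5. **normative** — degree-2 polynomial growth curves with joint F-tests,
   and 2-week-bin percentile tables (5th/50th/95th) over 20–40 weeks;
6. **cohort** — scan-level inclusion filtering and control/pathology
   stratification for a 193-scan recruitment manifest.

Because no public dataset accompanies this problem, the phantom module is
a first-class citizen: every quantitative claim is validated on synthetic
scans whose ground truth is known, with tissue T2* parameterized by a
published normative table (per-region means and percentiles in 2-week
gestational-age bins from 92 control scans).

## A worked example

```bash
python examples/03_normative_curves.py
```

prints (abridged):

```
cohort: 92 scans, GA 20.3-39.7 weeks
region              T2*@21wk  T2*@39wk      p(GA)    R^2
eCSF                   356.1     220.6   3.72e-37   0.85
gray_matter            278.1     187.8   2.67e-29   0.77
white_matter           311.1     223.9   3.58e-30   0.78
deep_gray_matter       228.6     165.2   1.75e-26   0.74
ventricles             416.3     339.2   3.69e-15   0.53
cerebellum             327.5     187.2   2.58e-42   0.88
brainstem              244.3     150.4   6.93e-44   0.89

brainstem 38-40 wk: n=11 mean=149.8 p5/p50/p95 = 137.4/147.4/161.6 ms
a brainstem T2* of 140 ms at 39 weeks sits at the 9th centile of controls
```

Every region's mean T2* declines over gestation (p ≪ 0.01), fastest for
the brainstem and cerebellum; the percentile table is the reference a
clinician would read a new measurement against, and `evaluate_centile`
performs that lookup.

`examples/02_reconstruct_and_fit.py` runs the imaging half: simulate a
motion-corrupted scan, reconstruct, fit T2*, and recover regional means to
within a few percent of the phantom ground truth.

A thin CLI mirrors the stages (`fetal-t2star simulate / reconstruct /
fit / regional / norms / cohort / run-all`); `fetal-t2star run-all
--out-dir out/` executes the whole chain with provenance.

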