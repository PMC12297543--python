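# ctfree-gfr

**CT-free quantitative kidney SPECT for glomerular filtration rate.**

Quantitative Tc-99m DTPA kidney SPECT/CT measures each kidney's percent
injected dose (%ID) and converts it to glomerular filtration rate (GFR), but
it needs the CT twice: for the attenuation map (µ-map) and as the anatomy on
which the kidneys are segmented — at the price of extra radiation and ~40 min
of manual contouring per case. This package implements the CT-free
alternative for researchers in quantitative nuclear medicine: one 3D U-Net
synthesizes the µ-map from the two emission windows, a second (residual,
attention-gated) U-Net segments the kidneys from that map, and the segmented
uptake converts to GFR by the established linear relation

```
GFR (mL/min) = 9.1462 × %ID + 23.0653        (per kidney, totals summed)
```

Because clinical SPECT/CT volumes cannot be redistributed, the package ships
a seeded digital torso phantom (categories: normal donor, renal tumor,
urinary stone, post partial / post total nephrectomy) that produces µ-maps,
kidney labels, two-window SPECT surrogates and exact ground-truth %ID, so the
whole pipeline is trainable and testable end to end. The networks run on a
compact numpy autodiff engine included in the package — no deep-learning
framework required. See `docs/methods.md` for the model details and the
limitations of the phantom.

## Worked example

```bash
python examples/simulate_and_quantify.py
```

```
category: normal, injected 370 MBq
ground-truth %ID  right 3.85  left 4.63
measured %ID      right 3.21  left 3.76
kidney volumes    right 193 mL  left 148 mL
GFR (mL/min)      right 52.4  left 57.5  total 109.9
```

The phantom's kidneys took up 3.85 % and 4.63 % of the injected activity;
quantifying the degraded (blurred, noisy) quantitative SPECT with the true
masks recovers slightly less (partial-volume loss at the organ boundary), and
the per-kidney GFRs sum to a total of 109.9 mL/min — a normal two-kidney
value. `examples/dose_comparison.py` prints the dosimetry side: dropping the
CT saves 45.3–78.8 % of the effective dose across typical abdominal DLPs
(3.313 mSv total at DLP 100 mGy·cm, 8.563 mSv at 450).

Training the two networks on phantom populations:

```bash
python examples/train_kidney_segmenter.py     # GDSC loss, DSC/VD report
python examples/train_mumap_generator.py      # MAE loss, R²/MSE/%NMAE report
```

## Command line

The same stages are available as a thin CLI:

```bash
ctfree-gfr simulate --n 20 --out cases/ --seed 1 --grid 32,48,48 --voxel-mm 6.9
ctfree-gfr train-seg --cases cases/ --out seg.npz --epochs 10
ctfree-gfr train-mumap --cases cases/ --out gen.npz --epochs 10
ctfree-gfr infer --model seg.npz --in cases/case_0000 --out pred.nii.gz
ctfree-gfr quantify --quant quant.nii.gz --labels pred.nii.gz \
    --injected-mbq 370 --out gfr.json
ctfree-gfr evaluate --pred preds/ --truth truths/ --out metrics.csv
ctfree-gfr dose-report --dlp 100 --dlp 450
```

Volumes are NIfTI-1 (`.nii.gz`); every command writes its resolved
configuration next to its outputs.

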