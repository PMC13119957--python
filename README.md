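# modrepair

Detect and repair missing sensor modalities in multimodal wearable time
series, using self-supervised learning only — no labels needed for
training.

Wearable systems record several synchronized streams (IMU motion, ECG,
electrodermal activity, respiration, skin temperature) and routinely lose
some of them: poor skin contact, motion artifacts, battery management,
hardware faults.  `modrepair` trains per-modality convolutional encoders
with an attention-fusion module under *simulated modality dropout*, so
that at inference time the model

1. **detects** which modality slots actually carry signal (a multi-label
   presence predictor on the fused embedding), and
2. **repairs** the missing streams (a masked decoder reconstructs every
   modality's window from the fused embedding of the present ones),

while the fused embedding stays useful for downstream state
classification even when half the sensors are gone.

## The objective

Training combines masked reconstruction with cross-modal contrastive
alignment:

```
L_total = λ_rec · L_masked + λ_con · L_contrastive (+ λ_pres · L_presence)

L_masked      = 1/|M_drop| Σ_{m ∈ M_drop} MSE( x(m), x̂(m) )
L_contrastive = mean over modality pairs of NT-Xent(z_i(m), z_i(m'))  (τ = 0.5)
```

with λ_rec = 1.0, λ_con = 0.5, trained with Adam (lr 1e-3, batch 32) in
three phases: unimodal SimCLR pretraining, masked multimodal
pretraining, and joint fine-tuning.  A small auxiliary binary
cross-entropy term (λ_pres = 0.1) trains the presence head.  See
`docs/methods.md` for the full model description and design rationale.

No external dataset is required: `modrepair.synthetic` generates
multimodal recordings in which a shared hidden Markov state drives every
modality (the cross-modal redundancy the method relies on), so the whole
pipeline is testable end to end on a laptop CPU.  The network runs on a
small numpy autodiff engine included in the package; runs are
bit-reproducible for a fixed seed.

## Worked example

```python
import numpy as np
from modrepair import (ModalityRepairModel, DropoutPolicy, TrainConfig,
                       default_config, generate_dataset, sample_mask,
                       apply_mask, presence_metrics)
from modrepair.evaluation import repair_rmse

# five synthetic subjects: IMU, ECG, EDA, RESP, TEMP at 10 Hz
recs = generate_dataset(default_config(n_subjects=5, duration_s=505.0,
                                       rate=10.0, seed=42))
train = ModalityRepairModel.prepare_batch(recs[:4])   # 400 windows
test = ModalityRepairModel.prepare_batch(recs[4:])    # held-out subject

cfg = TrainConfig(epochs_phase2=3, epochs_phase3=3, phases=(2, 3),
                  dropout=DropoutPolicy(rate=0.3, fill="gaussian-noise"))
result = ModalityRepairModel(train, cfg).fit()
print(result.summary())

# drop 30% of modalities on the held-out subject and repair
mask = sample_mask(DropoutPolicy(rate=0.3), test.n_windows,
                   test.n_modalities, np.random.default_rng(7))
for m, v in repair_rmse(result.net, test, mask).items():
    print(f"{m:5s} RMSE model {v['model']:.3f}  zeros {v['zeros']:.3f}")

# detect which modalities were corrupted (noise-filled)
pol = DropoutPolicy(rate=0.3, fill="gaussian-noise", seed=5)
corrupted = apply_mask(test, sample_mask(pol, test.n_windows, 5), pol)
pm = presence_metrics(result.detect_presence(corrupted.windows),
                      corrupted.presence, modalities=test.modalities)
print("presence macro-F1:", round(pm["macro"]["f1"], 3))
```

Output (~2.5 min on one CPU):

```
Modality repair model
==========================================================
modalities:           imu, ecg, eda, resp, temp
windows (train):      400
subjects:             4
parameters:           785282
ablation:             hybrid
dropout rate / fill:  0.3 / gaussian-noise
weights:              rec=1.0 con=0.5 pres=0.1
tau / momentum:       0.5 / 0.996
optimizer:            Adam lr=0.001 batch=32 seed=42
----------------------------------------------------------
 phase  epochs  final L_masked final L_total
     2       3          0.7330        0.7867
     3       3          0.7060        2.1103
imu   RMSE model 1.057  zeros 1.051
ecg   RMSE model 1.018  zeros 1.004
eda   RMSE model 0.837  zeros 1.059
resp  RMSE model 1.104  zeros 1.080
temp  RMSE model 0.671  zeros 0.974
presence macro-F1: 0.859
```

Reading the numbers: signals whose information is shared across
modalities at the window scale (the slow EDA / TEMP channels) are
reconstructed clearly better than zero-imputation (RMSE ≈ 1 on z-scored
data), while carrier-dominated signals (IMU oscillation phase, ECG beat
timing) cannot be recovered from other modalities and converge to the
conditional mean — the expected physical behaviour.  The presence head
identifies noise-corrupted slots well above chance.  Both repair quality
and detection improve further with more training data and epochs: the
acceptance run below (1000 training windows) reaches EDA RMSE ≈ 0.58
and detection macro-F1 ≈ 0.99 on the held-out subject.

## Command line

```bash
modrepair simulate   --config run.yaml --out data/    # synthetic dataset
modrepair train      --config run.yaml --out out/     # 3-phase training
modrepair evaluate   --config run.yaml --out out/     # JSON eval report
modrepair repair     --config run.yaml --manifest data/S04/manifest.json \
                     --model out/model.npz --out fixed/
modrepair visualize  --config run.yaml --model out/model.npz --out out/
```

`run.yaml` is validated strictly (unknown keys are errors); see
`modrepair/config.py` for the schema.  Recordings are described by a
JSON manifest pointing at one CSV (or HDF5) file per modality plus a
label file; see `modrepair/signal_io.py` for the exact format.

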