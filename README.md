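# gridbind

Voxel-grid deep learning on molecular-dynamics (MD) trajectories for
protein–ligand binding affinity prediction.

Predicting the binding affinity of a protein–ligand complex (reported here
on the pK scale, −log10 of Kd/Ki) is a core scoring task in structure-based
drug design.  Models trained on static crystal structures tend to memorize
dataset biases — patterns tied to the protein family or the ligand alone —
instead of learning from the interaction.  MD simulations offer a way out:
frames can serve as *data augmentation* for 3-D models, and whole
simulations carry temporal information (for instance how much the ligand
moves inside the site) that *spatio-temporal* models can exploit.

gridbind implements that method stack end to end at desk scale:

* **Featurization** — pocket extraction (residues within 12 Å of the
  ligand's geometric center in the crystal pose), 19-channel atom encoding,
  cubic-box voxelization (25 Å edge, 1 Å³ voxels, pocket-centered or
  ligand-tracking boxes), the 24 right-angle cube rotations for
  augmentation, and protein/ligand ablation masks.
* **Models** — a plain 3-D CNN, a dense-block CNN, an LRCN (per-frame CNN
  encoder + LSTM), and a ConvLSTM, all built on a small NumPy autodiff
  engine shipped with the package.
* **Training** — crystal-only, MD-augmented (every frame an independent
  sample labeled with the complex's affinity) and spatio-temporal (whole
  simulations, one random replicate per complex per epoch) regimes;
  per-complex averaging and multi-model consensus; hard train/val leakage
  guards.
* **Evaluation** — Pearson R, RMSE, Spearman ρ (overall and per cluster),
  the partner-ablation bias gap ΔR, ligand max-RMSD stability fractions,
  and leave-one-family-out splits.
* **Synthetic data** — a generator of pseudo-complexes and replicate
  trajectories with a planted, recoverable affinity signal
  (pK = a + b·contacts + noise) and affinity-dependent ligand drift, so the
  whole pipeline is testable without downloading anything.

See `docs/methods.md` for the model details and the generator's assumptions.

## Worked example

Generate a synthetic dataset, train a small CNN with MD data augmentation,
and evaluate it:

```python
import numpy as np
from gridbind import (SyntheticSpec, ModelConfig, build_dataset, pearson_r, rmse)
from gridbind.training import (AffinityData, TrainingConfig, consensus,
                               predict_entities, train)

dataset = build_dataset(SyntheticSpec(seed=1), n_replicates=1)
data = AffinityData.from_synthetic(dataset, frame_stride=10, replicates=1)

model_cfg = ModelConfig(family="cnn", conv_channels=(32, 64),
                        conv_strides=(2, 1), head_widths=(96,))
train_cfg = TrainingConfig(regime="md_augmented", epochs=12, batch_size=16,
                           learning_rate=3e-3, n_model_replicates=2, seed=1)
ensemble = train(model_cfg, train_cfg, data)

test_ids = data.manifest.ids("test")
labels = data.labels()
cons = consensus([predict_entities(m, data, test_ids, "frames", train_cfg)
                  for m in ensemble.models])
truth = np.array([labels[c] for c in cons.index])
print(f"test R = {pearson_r(cons.to_numpy(), truth):.2f}, "
      f"RMSE = {rmse(cons.to_numpy(), truth):.2f} pK")
```

```
test R = 0.86, RMSE = 1.74 pK
```

The consensus of the two model replicates recovers the planted
contact-count signal on the 24 held-out complexes; training the same model
on the ligand alone drops the test correlation to ≈ 0.2 or lower, which is
what the bias-gap protocol (ΔR = R_complex − R_ablated) measures.

The same pipeline is available from the shell:

```bash
gridbind simulate --out ds --seed 3
gridbind train --config run.yaml --data ds --manifest ds/manifest.csv --out run
gridbind predict --ensemble run --data ds --manifest ds/manifest.csv --out pred.csv
gridbind evaluate --predictions pred.csv --manifest ds/manifest.csv --out metrics.json
gridbind stability --trajectories ds/trajectories --manifest ds/manifest.csv --out stab.json
```

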