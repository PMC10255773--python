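"""Train the 1D CNN regressor at desk scale.

Builds the 931,889-parameter network (three kernel-5 convolutions with
64/32/16 filters, dropout 0.5, max-pool 2, dense 64/32/1), trains it with
Adam at learning rate 0.001 on the 1148/204 split of the augmented study
set, and reports the prediction R^2 and RMSEP.

Training 100 epochs takes on the order of ten minutes on one CPU; pass a
smaller --epochs for a quick look.
"""

import argparse

import ftirq
from ftirq import cnn1d
from ftirq.preprocess import PreprocessConfig, Preprocessor

parser = argparse.ArgumentParser()
parser.add_argument("--epochs", type=int, default=100)
args = parser.parse_args()

raw = ftirq.generate_dataset("melamine", noise=ftirq.NoiseConfig(seed=42))
aug = ftirq.dirichlet_augment(raw, ftirq.DirichletConfig(seed=7))
cal, val = ftirq.stratified_split(aug, ftirq.SplitPlan(scheme="cnn_1148_204", seed=1))

prep = Preprocessor(PreprocessConfig(method="snv"), axis_spacing=aug.axis.spacing)
X_cal = prep.fit_transform(cal.intensities)
X_val = prep.transform(val.intensities)

spec = cnn1d.CnnSpec(seed=5)
model = cnn1d.build(spec)
per_layer, total = cnn1d.param_count(model)
print(f"network: {total:,} trainable parameters "
      f"({', '.join(f'{k}={v:,}' for k, v in per_layer.items())})")

cnn1d.train(model, X_cal, cal.concentration, X_val, val.concentration,
            epochs=args.epochs, verbose=False)
for rec in model.training_history[:: max(1, args.epochs // 5)]:
    print(f"  epoch {rec['epoch']:4d}  train MSE {rec['train_loss']:.4f}  "
          f"val MSE {rec['val_loss']:.4f}")

pred = cnn1d.predict(model, X_val)
print(f"prediction set: R2 = {ftirq.r_squared(val.concentration, pred):.4f}, "
      f"RMSEP = {ftirq.rmse(val.concentration, pred):.4f}% w/w")
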