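"""Train the full DWT-CNN-Bi-LSTM pipeline on synthetic EEG, end to end.

Generates a two-class dataset whose positive class has a 3x alpha-band
amplitude boost, splits it 80/20 stratified, standardizes on the training
split, applies the db4 level-2 approximation cascade, trains the proposed
architecture for a short schedule and prints the held-out confusion metrics.
"""

from alcoeeg import experiment, synthgen
from alcoeeg.network import ModelConfig

config = synthgen.SynthConfig(n_subjects_per_class=4, trials_per_subject=6,
                              n_channels=8, effect=3.0, seed=7)
dataset = synthgen.generate(config)
print(f"dataset: {len(dataset)} trials x {dataset.trials[0].n_channels} channels "
      f"({config.effect}x alpha boost in the positive class)")

result = experiment.run_pipeline(
    dataset, "proposed",
    config=ModelConfig(epochs=10, batch_size=64),
    plan=experiment.SplitPlan(train_fraction=0.8, seed=0),
    seed=0,
)
r = result.report
print(f"confusion counts: TP={r.tp} FP={r.fp} TN={r.tn} FN={r.fn}")
print(f"accuracy {r.accuracy:.3f}  precision {r.precision:.3f}  "
      f"recall {r.recall:.3f}  F1 {r.f1:.3f}")
print("per-epoch training curve (last 3 rows):")
print(r.curves.tail(3).to_string(index=False))
# accuracy near 1.0 means the pipeline recovered the injected band-power
# difference from the denoised features alone.
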