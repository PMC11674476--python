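"""10-fold cross-validation in its two flavours.

``sample_shuffled`` mixes individual timepoint samples across folds, so
adjacent (nearly identical) timepoints of one trial can land on opposite
sides of the train/test boundary — the optimistic protocol.
``trial_grouped`` keeps whole trials together — the conservative one.
The gap between them estimates the temporal-adjacency leakage.
"""

from dacb import ModelConfig, SynthSpec, TrainConfig, generate_trialset
from dacb.experiments import run_kfold

data = generate_trialset(
    SynthSpec(
        n_subjects=5, n_trials_per_subject=8, n_channels=8,
        trial_length=60, segment_length=30, n_classes=3, snr=3.0, seed=3,
        subject_gain_jitter=0.2, trial_amp_jitter=0.3,
    )
)
model_cfg = ModelConfig(n_channels=8, n_classes=3, conv_filters=16, se_reduction=4,
                        lstm_units=8, fusion_width=16, fc1_units=16, fc2_units=8, seed=42)
train_cfg = TrainConfig(epochs=12, batch_size=256, seed=42)

for mode in ("sample_shuffled", "trial_grouped"):
    res = run_kfold(data, model_cfg, train_cfg, k=5, mode=mode, segment_length=30)
    m, s = res.mean_metrics, res.std_metrics
    print(f"{mode:16s}: accuracy {m['accuracy']:.3f} +- {s['accuracy']:.3f}, MCC {m['mcc']:.3f}")
print("expect sample_shuffled >= trial_grouped: unseen trials are harder than unseen timepoints")
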