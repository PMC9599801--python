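# Full-scale study conditions: 62-channel montage, 5-minute recordings at
# 1 kHz, 30 subjects per group, 10-fold CV, 5000 label permutations.
n_channels = 62
sampling_rate = 1000.0
duration = 300.0
include_aux = true
noise_sd = 1.0
noise_color = "pink"

n_per_group = 30
group_effect = 0.7
subject_coupling_sd = 0.2

bandpass_low = 0.1
bandpass_high = 30.0
notch_low = 48.0
notch_high = 52.0
downsample_to = 500.0
epoch_length = 3.0
reject_threshold = 100.0

feature_set = "pairs8+global"
n_folds = 10
n_permutations = 5000
chance_percentile = 95.0
seed = 0
out_dir = "results/study_full"
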