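# Reduced-channel configuration: same signal model and analysis chain on a
# 16-channel montage with shorter, lower-rate recordings and fewer label
# permutations.  Completes well within 15 minutes on one CPU and is the
# configuration exercised by the end-to-end reproducibility check.
n_channels = 16
sampling_rate = 250.0
duration = 180.0
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
downsample_to = 250.0
epoch_length = 3.0
reject_threshold = 100.0

feature_set = "pairs8+global"
n_folds = 10
n_permutations = 500
chance_percentile = 95.0
seed = 0
out_dir = "results/study_reduced"
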