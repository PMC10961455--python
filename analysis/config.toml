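# Run configuration for the demonstration analysis.
#
# A scaled-down cohort (4 subjects/strain, 20 regions, 300-volume series)
# keeps the full chain runnable in a few minutes on a laptop; the
# simulate section mirrors the study design otherwise (two strains, six
# monthly sessions, planted connectivity/intensity/volume effects in the
# epileptic group).

seed = 20260919

[paths]
data_dir = "results/cohort"
out_dir = "results"

[simulate]
n_per_strain = 4
sessions = [3, 4, 5, 6, 7, 8]
n_regions = 20
grid_shape = [16, 16, 6]
n_volumes = 300
tr = 1.0

[preprocess]
window_volumes = 240
fwhm_mm = 0.6
cutoff_hz = 0.1

[connectivity]
q = 0.05

[graph]
k = 6
k_range = [2, 7]  # above k~7 a 20-region FDR-thresholded matrix runs out of positive weights
n_random = 100

[nbs]
k = 6
primary_alpha = 0.05
n_perm = 500
alpha = 0.05

[community]
k = 6

[memri]
median_kernel = 3
n_perm = 30
percentile = 99.9
min_cluster_voxels = 20
region_alpha = 0.01
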