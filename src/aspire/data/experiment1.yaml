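# Default parameters of the 25-sample synthetic anomaly benchmark.
#
# Three normal global clusters in two dimensions, mutually separated by well
# over eight standard deviations; three isolated rare-population clusters;
# three "artifact" clusters derived from the normal ones by a four-standard-
# deviation mean shift and halving of the per-dimension standard deviations.
# Local cluster means are perturbed around the global means with
# random-effects scale kappa1_gen.

n_samples_normal: 10
n_anomalous_per_group: 5
events_per_sample: 1000
dim: 2
kappa1_gen: 0.05
rare_pop_size: 5

normal_means:
  - [0.0, 0.0]
  - [10.0, 0.0]
  - [0.0, 10.0]
normal_covs:
  - [[0.25, 0.075], [0.075, 0.25]]
  - [[0.30, -0.10], [-0.10, 0.20]]
  - [[0.18, 0.05], [0.05, 0.32]]
normal_proportions: [0.5, 0.3, 0.2]

# group 1: same clusters, permuted-and-tilted mixing proportions
group1_proportions: [0.2, 0.5, 0.3]

# group 2: three isolated rare populations (means far from every other
# cluster), each holding exactly rare_pop_size events per sample
rare_means:
  - [-8.0, -8.0]
  - [18.0, 8.0]
  - [8.0, 18.0]
rare_covs:
  - [[0.2, 0.0], [0.0, 0.2]]
  - [[0.2, 0.0], [0.0, 0.2]]
  - [[0.2, 0.0], [0.0, 0.2]]

# group 3: normal clusters shifted by about four standard deviations with
# per-dimension standard deviations halved (covariances scaled by 1/4)
group3_shifts:
  - [1.6, 1.2]
  - [-1.5, 1.4]
  - [1.5, -1.4]
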