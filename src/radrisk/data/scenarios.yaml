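# Study-condition configuration for the four breast-radiotherapy scenarios.
#
# tps: calibration targets for the TPS-style per-organ summed dose
#   distributions (total physical Dmean mean/sd in Gy over the cohort, plus
#   the mean-dose contribution of the boost course) together with the DVH
#   shape model: in-field fraction (~prescription dose), penumbra fraction
#   (20-80% of prescription), and the exponential out-of-field tail mean.
# tld: full-course mean organ doses (Gy) emulating phantom measurements,
#   per breast size. The large-breast ipsilateral lung case carries an
#   injected near-field outlier dosimeter.
generator_version: 1
voxels_per_organ: 5000
voxel_volume_cm3: 0.125
dvh_bin_width_gy: 0.1
tld:
  readings_per_organ: 5
  background_readings: 3
  noise_cv: 0.10
  background_gy_per_plan: 0.0002
  outlier_factor: 12.0
cohort_sizes:
  3dcrt_seq: 10
  3dcrt_brachy: 8
  imrt_brachy: 10
  imrt_sib: 10
scenarios:
  3dcrt_seq:
    label: "3D-CRT + sequential boost"
    wbi: {n_fractions: 25, dose_per_fraction: 2.0}
    boost: {n_fractions: 5, dose_per_fraction: 2.0, kind: teletherapy}
    organs:
      heart:
        total_dmean: {mean: 4.8, sd: 2.1}
        boost_dmean: 0.8
        in_field_fraction: {mean: 0.015, sd: 0.008}
        penumbra_fraction: {mean: 0.055, sd: 0.02}
        oof_mean_gy: 1.2
      lung_ipsi:
        total_dmean: {mean: 8.7, sd: 2.2}
        boost_dmean: 1.4
        in_field_fraction: {mean: 0.10, sd: 0.03}
        penumbra_fraction: {mean: 0.09, sd: 0.03}
        oof_mean_gy: 1.0
      lung_contra:
        total_dmean: {mean: 0.5, sd: 0.3}
        boost_dmean: 0.05
        in_field_fraction: {mean: 0.0, sd: 0.0}
        penumbra_fraction: {mean: 0.0, sd: 0.0}
        oof_mean_gy: 0.5
      breast_contra:
        total_dmean: {mean: 0.8, sd: 0.6}
        boost_dmean: 0.1
        in_field_fraction: {mean: 0.0, sd: 0.0}
        penumbra_fraction: {mean: 0.004, sd: 0.003}
        oof_mean_gy: 0.6
    tld:
      heart: {small: 1.9, large: 1.3}
      lung_ipsi: {small: 1.5, large: 2.0, outlier_large: true}
      lung_contra: {small: 0.5, large: 0.4}
      breast_contra: {small: 2.4, large: 1.2}
  3dcrt_brachy:
    label: "3D-CRT + brachytherapy"
    wbi: {n_fractions: 25, dose_per_fraction: 2.0}
    boost: {n_fractions: 2, dose_per_fraction: 6.0, kind: brachytherapy}
    organs:
      heart:
        total_dmean: {mean: 3.3, sd: 1.6}
        boost_dmean: 0.15
        in_field_fraction: {mean: 0.01, sd: 0.006}
        penumbra_fraction: {mean: 0.04, sd: 0.015}
        oof_mean_gy: 1.0
      lung_ipsi:
        total_dmean: {mean: 7.9, sd: 1.1}
        boost_dmean: 0.1
        in_field_fraction: {mean: 0.095, sd: 0.02}
        penumbra_fraction: {mean: 0.085, sd: 0.02}
        oof_mean_gy: 0.9
      lung_contra:
        total_dmean: {mean: 0.4, sd: 0.2}
        boost_dmean: 0.02
        in_field_fraction: {mean: 0.0, sd: 0.0}
        penumbra_fraction: {mean: 0.0, sd: 0.0}
        oof_mean_gy: 0.4
      breast_contra:
        total_dmean: {mean: 0.7, sd: 0.7}
        boost_dmean: 0.05
        in_field_fraction: {mean: 0.0, sd: 0.0}
        penumbra_fraction: {mean: 0.003, sd: 0.003}
        oof_mean_gy: 0.5
    tld:
      heart: {small: 0.6, large: 1.4}
      lung_ipsi: {small: 1.0, large: 2.0, outlier_large: true}
      lung_contra: {small: 0.2, large: 0.4}
      breast_contra: {small: 1.7, large: 1.0}
  imrt_brachy:
    label: "IMRT + brachytherapy"
    wbi: {n_fractions: 25, dose_per_fraction: 2.0}
    boost: {n_fractions: 2, dose_per_fraction: 6.0, kind: brachytherapy}
    organs:
      heart:
        total_dmean: {mean: 4.5, sd: 1.3}
        boost_dmean: 0.15
        in_field_fraction: {mean: 0.012, sd: 0.006}
        penumbra_fraction: {mean: 0.06, sd: 0.02}
        oof_mean_gy: 1.4
      lung_ipsi:
        total_dmean: {mean: 9.9, sd: 2.3}
        boost_dmean: 0.1
        in_field_fraction: {mean: 0.12, sd: 0.03}
        penumbra_fraction: {mean: 0.10, sd: 0.03}
        oof_mean_gy: 1.2
      lung_contra:
        total_dmean: {mean: 0.6, sd: 0.2}
        boost_dmean: 0.02
        in_field_fraction: {mean: 0.0, sd: 0.0}
        penumbra_fraction: {mean: 0.0, sd: 0.0}
        oof_mean_gy: 0.6
      breast_contra:
        total_dmean: {mean: 2.3, sd: 2.2}
        boost_dmean: 0.05
        in_field_fraction: {mean: 0.0, sd: 0.0}
        penumbra_fraction: {mean: 0.012, sd: 0.008}
        oof_mean_gy: 1.4
    tld:
      heart: {small: 1.1, large: 3.1}
      lung_ipsi: {small: 3.3, large: 9.0, outlier_large: true}
      lung_contra: {small: 0.4, large: 0.6}
      breast_contra: {small: 1.6, large: 1.2}
  imrt_sib:
    label: "IMRT + SiB"
    wbi: {n_fractions: 28, dose_per_fraction: 1.8}
    boost: null
    sib_boost_dose_per_fraction: 2.14
    organs:
      heart:
        total_dmean: {mean: 4.4, sd: 1.0}
        boost_dmean: 0.0
        in_field_fraction: {mean: 0.012, sd: 0.006}
        penumbra_fraction: {mean: 0.06, sd: 0.02}
        oof_mean_gy: 1.4
      lung_ipsi:
        total_dmean: {mean: 10.8, sd: 1.8}
        boost_dmean: 0.0
        in_field_fraction: {mean: 0.13, sd: 0.03}
        penumbra_fraction: {mean: 0.11, sd: 0.03}
        oof_mean_gy: 1.3
      lung_contra:
        total_dmean: {mean: 0.7, sd: 0.3}
        boost_dmean: 0.0
        in_field_fraction: {mean: 0.0, sd: 0.0}
        penumbra_fraction: {mean: 0.0, sd: 0.0}
        oof_mean_gy: 0.7
      breast_contra:
        total_dmean: {mean: 2.5, sd: 2.1}
        boost_dmean: 0.0
        in_field_fraction: {mean: 0.0, sd: 0.0}
        penumbra_fraction: {mean: 0.012, sd: 0.008}
        oof_mean_gy: 1.5
    tld:
      heart: {small: 1.7, large: 1.2}
      lung_ipsi: {small: 2.3, large: 2.4, outlier_large: true}
      lung_contra: {small: 0.5, large: 0.4}
      breast_contra: {small: 1.7, large: 1.0}
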