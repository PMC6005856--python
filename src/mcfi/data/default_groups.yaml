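# Default calibration targets for the four sex x genotype groups.
#
# slope          -- published rate of deficit accumulation (ln FI per 10 days)
# band_mean      -- published mean FI of mice assessed at 300-600 days of age
# mean_lifespan  -- published mean death day (uncensored), days
# age_range      -- uniform assessment-age window, days (chosen to match the
#                   published mean +/- SD of age at assessment per group)
# p_cens         -- published censoring fraction
# p_unknown      -- published fraction with unknown vital status
#
# gamma (Gompertz shape, per day) and beta (log-hazard per unit FI) are the
# simulator's free mortality-shape defaults, fixed once; the baseline hazard
# lambda0 and the trajectory (m, f0) are solved from the targets at load time.

fi_floor: 0.016129032258064516   # 1/62
f_ceiling: 0.70
gamma: 0.005
beta: 4.0

groups:
  male_wt:
    sex: M
    genotype: WT
    slope: 0.023
    band_mean: 0.15
    mean_lifespan: 571.3
    age_range: [30, 900]
    p_cens: 0.855
    p_unknown: 0.095
  male_tg:
    sex: M
    genotype: TG
    slope: 0.035
    band_mean: 0.21
    mean_lifespan: 386.9
    age_range: [30, 560]
    p_cens: 0.667
    p_unknown: 0.057
  female_wt:
    sex: F
    genotype: WT
    slope: 0.020
    band_mean: 0.12
    mean_lifespan: 548.1
    age_range: [30, 950]
    p_cens: 0.869
    p_unknown: 0.077
  female_tg:
    sex: F
    genotype: TG
    slope: 0.031
    band_mean: 0.10
    mean_lifespan: 517.1
    age_range: [30, 870]
    p_cens: 0.833
    p_unknown: 0.129
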