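parameters:
  c_day_icu:
    family: gamma
    mean: 7738.266732
    sd: 1160.74001
  c_day_ward:
    family: gamma
    mean: 2813.270239
    sd: 421.990536
  c_drug:
    family: gamma
    mean: 4106.635776
    sd: 615.995366
  le_post_icu:
    family: gamma
    mean: 10.013693
    sd: 1.502054
  le_post_ward:
    family: gamma
    mean: 16.895121
    sd: 2.534268
  los_icu:
    family: gamma
    mean: 12.099166
    sd: 1.814875
  los_ward:
    family: gamma
    mean: 6.163894
    sd: 0.924584
  p_death_28d_ctrl:
    family: beta
    mean: 0.227392
    sd: 0.022739
  p_icu:
    family: beta
    mean: 0.253957
    sd: 0.025396
  u_hosp:
    family: beta
    mean: 0.545899
    sd: 0.05459
  u_post_icu:
    family: beta
    mean: 0.790261
    sd: 0.079026
  u_post_ward:
    family: beta
    mean: 0.804362
    sd: 0.080436
provenance: synthetic stand-in parameter set (not a published parameter file)
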