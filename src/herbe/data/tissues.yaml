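# Photon LQ radiosensitivity parameters used in the in-silico studies.
# alpha_x [Gy^-1], beta_x [Gy^-2], alpha_beta_x [Gy] (as printed, may be a
# rounded ratio), d_t [Gy] (LEM transition dose).
water2:
  alpha_x: 0.2
  beta_x: 0.1
  alpha_beta_x: 2.0
  d_t: 6.2
  label: water, (alpha/beta)_x = 2 Gy (late-responding / radio-resistant surrogate)
  reference: hypothetical water case
water10:
  alpha_x: 0.2
  beta_x: 0.02
  alpha_beta_x: 10.0
  d_t: 15.0
  label: water, (alpha/beta)_x = 10 Gy (early-responding / tumor surrogate)
  reference: hypothetical water case
prostate:
  alpha_x: 0.036
  beta_x: 0.024
  alpha_beta_x: 1.5
  d_t: 5.65
  label: prostate PTV
  reference: Brenner and Hall (1999)
prostate_healthy:
  alpha_x: 0.089
  beta_x: 0.0287
  alpha_beta_x: 3.1
  d_t: 7.41
  label: healthy tissue surrounding prostate
  reference: Terry and Denekamp (1984)
head:
  alpha_x: 0.077
  beta_x: 0.009
  alpha_beta_x: 8.6
  d_t: 13.41
  label: glioma PTV
  reference: Jones and Sanghera (2007)
head_normal:
  alpha_x: 0.0499
  beta_x: 0.0238
  alpha_beta_x: 2.1
  d_t: 6.31
  label: brain outside PTV
  reference: Meeks et al. (2000)
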