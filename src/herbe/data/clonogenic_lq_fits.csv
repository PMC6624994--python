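# Clonogenic survival LQ fit parameters for photon (alpha_x, beta_x) and
# helium (alpha, beta) irradiation of Renca cells, with MC-derived LET_d.
# Parenthesized uncertainties of the source table are stored verbatim in the
# *_u columns without interpreting them as SE vs SD vs CI.
# Experiment A: pristine (monoenergetic) peaks; experiment B: SOBPs.
experiment,alpha_x,alpha_x_u,beta_x,beta_x_u,alpha_beta_x_printed,alpha,alpha_u,beta,beta_u,let_d
A,0.034,0.004,0.018,0.001,1.79,0.039,0.013,0.029,0.003,5.33
A,0.034,0.004,0.018,0.001,1.79,0.094,0.012,0.046,0.012,14.81
B,0.050,0.064,0.023,0.014,2.17,0.076,0.083,0.024,0.02,4.78
B,0.050,0.064,0.023,0.014,2.17,0.150,0.071,0.018,0.018,10.18
B,0.050,0.064,0.023,0.014,2.17,0.201,0.048,0.017,0.005,15.37
B,0.050,0.064,0.023,0.014,2.17,0.305,0.144,0.022,0.032,26.52
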