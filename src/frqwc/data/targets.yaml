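# Wild-type circadian target features for the qualitative cost function.
# target: expected value; scale: mismatch (h or dimensionless) that counts
# as one scaled unit; weight: relative importance.
targets:
  dd_period:              {target: 22.0, scale: 1.0, weight: 1.0}   # free-running period (h)
  dd_mf_peak:             {target: -5.0, scale: 1.5, weight: 1.0}   # frq mRNA peaks ~5 h before FRQ protein
  dd_pw_antiphase:        {target: 11.0, scale: 3.0, weight: 1.0}   # FRQ and WC-1 roughly in antiphase
  dd_mw_rel_amp:          {target: 0.0,  scale: 0.05, weight: 1.0}  # wc-1 mRNA nearly constant in DD
  ld_phi_minus_midnight:  {target: 0.0,  scale: 1.0, weight: 1.0}   # conidiation at midnight in 12:12 LD
  ld_mf_peak_minus_dawn:  {target: 0.0,  scale: 1.5, weight: 1.0}   # frq mRNA peak locked to dawn
  ld_mf_trough_minus_dusk: {target: 0.0, scale: 2.5, weight: 1.0}   # frq mRNA trough locked to dusk
penalty: 100.0
accept_threshold: 10.0
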