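# Shared run configuration for the tickertape CLI.
# Units are explicit in key names; e0 and m have no defaults and must be set.
kinetics:
  tau_e_ms: 1.0        # mean elongation dwell time
  tau_p_ms: 100.0      # mean pausing-path dwell time
  pause_prob: 0.0      # per-nucleotide pause probability
  # dissoc_prob: 0.001       # optional: per-nucleotide dissociation
  # tau_reassoc_ms: 2000.0   # required when dissoc_prob > 0
cmlf:
  e0: 0.005            # baseline misincorporation probability
  m: 0.025             # slope per unit scaled concentration (e_h = e0 + m)
# start:               # optional gamma-distributed start delays
#   mean_ms: 1000.0
#   shape: 8.0
seed: 1
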