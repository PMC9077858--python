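# Age-banded SIRS reference ranges (pediatric consensus-style bands).
# A criterion scores one point when the value falls outside [lo, hi]
# (or above hi where only hi is given).  Users may swap this file to use
# institution-specific bands.
# Units: age years, heart_rate bpm, resp_rate /min, temperature deg C,
# wbc 10^3/mm^3.
bands:
  - {age_lo: 0.0, age_hi: 1.0,
     heart_rate: {lo: 90, hi: 180}, resp_rate: {hi: 34},
     temperature: {lo: 36.0, hi: 38.5}, wbc: {lo: 5.0, hi: 17.5}}
  - {age_lo: 1.0, age_hi: 6.0,
     heart_rate: {lo: 60, hi: 140}, resp_rate: {hi: 22},
     temperature: {lo: 36.0, hi: 38.5}, wbc: {lo: 6.0, hi: 15.5}}
  - {age_lo: 6.0, age_hi: 13.0,
     heart_rate: {lo: 60, hi: 130}, resp_rate: {hi: 18},
     temperature: {lo: 36.0, hi: 38.5}, wbc: {lo: 4.5, hi: 13.5}}
  - {age_lo: 13.0, age_hi: 18.01,
     heart_rate: {lo: 60, hi: 110}, resp_rate: {hi: 14},
     temperature: {lo: 36.0, hi: 38.5}, wbc: {lo: 4.5, hi: 11.0}}
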