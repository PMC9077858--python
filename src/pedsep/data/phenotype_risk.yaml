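# Published outcome rates of the four PedSep phenotypes, used by the bedside
# assignment tool's risk annotation and by the printed-count rate checks.
# counts are numerator/denominator pairs from the derivation cohort (n=404).
phenotype_n: {A: 136, B: 102, C: 110, D: 56}
total_n: 404
outcomes:
  mortality:
    counts: {A: 3, B: 12, C: 11, D: 19}
    total: 45
  smof:
    counts: {A: 0, B: 0, C: 1, D: 6}
    total: 7
  tamof:
    counts: {A: 0, B: 6, C: 3, D: 28}
    total: 37
  ipmof:
    counts: {A: 12, B: 29, C: 22, D: 22}
    total: 85
  mas:
    counts: {A: 0, B: 3, C: 2, D: 19}
    total: 24
  npmof:
    counts: {A: 28, B: 25, C: 32, D: 32}
    total: 117
  crrt:
    counts: {A: 1, B: 7, C: 7, D: 37}
    total: 52
  ecmo:
    counts: {A: 5, B: 9, C: 6, D: 10}
    total: 30
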