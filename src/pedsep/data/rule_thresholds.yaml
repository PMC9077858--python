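# Thresholds for the rule-based computable MOF phenotypes and the per-organ
# failure index.  All inequalities are strict, exactly as the clinical
# definitions are written; boundary values do not fire a rule.
ferritin_mas: 500.0      # ng/mL, MAS requires ferritin > this
platelet_low: 100.0      # K/mm^3, hematologic failure / MAS / TAMOF
inr_high: 1.5            # hematologic failure / MAS
alt_high: 100.0          # U/L, hepatic failure / MAS / SMOF
bilirubin_high: 1.0      # mg/dL, hepatic failure / MAS / SMOF
creatinine_high: 1.0     # mg/dL, renal failure / TAMOF
oliguria: 0.5            # mL/kg/h, urine output below this
pf_low: 300.0            # PaO2/FiO2, pulmonary failure / SMOF
gcs_low: 12.0            # CNS failure when GCS below this without sedation
adamts13_low: 57.0       # % of control, TAMOF
tnf_low: 200.0           # pg/mL, IPMOF (ex vivo TNF response to endotoxin)
tnf_day: 3               # IPMOF requires day index strictly beyond this
sfasl_high: 200.0        # pg/mL, SMOF
smof_lag: 7              # days between hypoxemic day and liver-failure day
min_of_for_mof: 2        # organ failures required for IPMOF
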