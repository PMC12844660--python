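# Synthetic preset emulating the aggregated EudraVigilance extract of the
# five WHO Reserve-group cephalosporins (spontaneous reports submitted up to
# 26 January 2025): per-drug report totals, report-level category counts,
# demographic marginals (exact counts), and unfavorable-outcome counts per
# category, as published in the study's aggregate tables.
#
# Notes
#  - The ceftaroline / ceftolozane-tazobactam split of the 48 resistance
#    reports not attributed drug-by-drug in the source is an even 24/24
#    default; override via cephvig.simulate.reserve_fixture(resistance_split=...).
#  - Ceftobiprole's fatal ineffectiveness count is capped at its 2
#    ineffectiveness reports (the source aggregates are internally
#    inconsistent here; see docs/methods.md).
seed: 0
drugs:
  cefiderocol:
    abbrev: CFD
    n_total: 176
    categories:
      resistance: 52
      ineffectiveness: 25
      off_label: 16
    demographics:
      age_group:
        NS: 21
        0-1 Month: 0
        2 Months-2 Years: 0
        3-11 Years: 1
        12-17 Years: 6
        18-64 Years: 86
        65-85 Years: 58
        ">85 Years": 4
      sex: {Female: 71, Male: 101, NS: 4}
      origin: {EEA: 143, Non-EEA: 33, NS: 0}
      reporter: {HP: 175, Non-HP: 1, NS: 0}
    outcomes:
      resistance: {Fatal: 1, NotRecovered: 2}
      ineffectiveness: {Fatal: 1, NotRecovered: 2}
  ceftaroline:
    abbrev: CTR
    n_total: 559
    categories:
      resistance: 24
      ineffectiveness: 63
      off_label: 118
    demographics:
      age_group:
        NS: 107
        0-1 Month: 1
        2 Months-2 Years: 4
        3-11 Years: 5
        12-17 Years: 18
        18-64 Years: 233
        65-85 Years: 163
        ">85 Years": 28
      sex: {Female: 215, Male: 308, NS: 36}
      origin: {EEA: 213, Non-EEA: 346, NS: 0}
      reporter: {HP: 548, Non-HP: 11, NS: 0}
    outcomes:
      resistance: {Fatal: 2, NotRecovered: 1}
      ineffectiveness: {Fatal: 14, NotRecovered: 1}
      off_label: {Fatal: 1, NotRecovered: 3}
  ceftazidime/avibactam:
    abbrev: CEFAVI
    n_total: 904
    categories:
      resistance: 93
      ineffectiveness: 85
      off_label: 118
    demographics:
      age_group:
        NS: 155
        0-1 Month: 2
        2 Months-2 Years: 15
        3-11 Years: 13
        12-17 Years: 15
        18-64 Years: 348
        65-85 Years: 279
        ">85 Years": 77
      sex: {Female: 295, Male: 539, NS: 70}
      origin: {EEA: 399, Non-EEA: 505, NS: 0}
      reporter: {HP: 793, Non-HP: 111, NS: 0}
    outcomes:
      resistance: {Fatal: 9, NotRecovered: 1}
      ineffectiveness: {Fatal: 21, NotRecovered: 5, RecoveredWithSequelae: 1}
      off_label: {Fatal: 4, NotRecovered: 1}
  ceftobiprole:
    abbrev: CFB
    n_total: 146
    categories:
      resistance: 0
      ineffectiveness: 2
      off_label: 30
    demographics:
      age_group:
        NS: 13
        0-1 Month: 0
        2 Months-2 Years: 0
        3-11 Years: 0
        12-17 Years: 0
        18-64 Years: 48
        65-85 Years: 71
        ">85 Years": 14
      sex: {Female: 62, Male: 79, NS: 5}
      origin: {EEA: 118, Non-EEA: 28, NS: 0}
      reporter: {HP: 146, Non-HP: 0, NS: 0}
    outcomes:
      ineffectiveness: {Fatal: 2}
      off_label: {NotRecovered: 2}
  ceftolozane/tazobactam:
    abbrev: CTZTAZ
    n_total: 560
    categories:
      resistance: 24
      ineffectiveness: 60
      off_label: 154
    demographics:
      age_group:
        NS: 169
        0-1 Month: 0
        2 Months-2 Years: 3
        3-11 Years: 6
        12-17 Years: 10
        18-64 Years: 183
        65-85 Years: 164
        ">85 Years": 25
      sex: {Female: 194, Male: 308, NS: 58}
      origin: {EEA: 312, Non-EEA: 248, NS: 0}
      reporter: {HP: 552, Non-HP: 8, NS: 0}
    outcomes:
      resistance: {Fatal: 3, NotRecovered: 2}
      ineffectiveness: {Fatal: 7}
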