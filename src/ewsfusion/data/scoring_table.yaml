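# Band/weight definitions for the two component early warning scores.
#
# Convention: every band is lower-inclusive, upper-exclusive on the measured
# scale ([lower, upper, weight]); `.inf`/`-.inf` mark open ends.  Printed
# inclusive cut-offs from score charts are converted to this convention once,
# here, so scoring code never reasons about boundary inclusion.  Values that
# fall exactly on a chart cut-off score in the higher-risk band (conservative
# for a safety score).  Temperature is scored at 0.1 degC resolution.
#
# NEWS bands are the published Royal College of Physicians NEWS weightings
# (aggregate maximum 20).  The laboratory bands are this package's default
# transcription of the LDT-EWS chart: clinically conventional cut-offs,
# sex-specific for creatinine and haemoglobin, with per-analyte maxima summing
# to the declared aggregate maximum of 15.  Supply your own file to use a
# different chart.

news:
  max_aggregate: 20
  components:
    respiratory_rate:
      unit: breaths/min
      bands:
        - [-.inf, 9, 3]
        - [9, 12, 1]
        - [12, 21, 0]
        - [21, 25, 2]
        - [25, .inf, 3]
    spo2:
      unit: "%"
      bands:
        - [-.inf, 92, 3]
        - [92, 94, 2]
        - [94, 96, 1]
        - [96, .inf, 0]
    temperature:
      unit: degC
      bands:
        - [-.inf, 35.1, 3]
        - [35.1, 36.1, 1]
        - [36.1, 38.1, 0]
        - [38.1, 39.1, 1]
        - [39.1, .inf, 2]
    systolic_bp:
      unit: mmHg
      bands:
        - [-.inf, 91, 3]
        - [91, 101, 2]
        - [101, 111, 1]
        - [111, 220, 0]
        - [220, .inf, 3]
    heart_rate:
      unit: beats/min
      bands:
        - [-.inf, 41, 3]
        - [41, 51, 1]
        - [51, 91, 0]
        - [91, 111, 1]
        - [111, 131, 2]
        - [131, .inf, 3]
  supplemental_oxygen_weight: 2
  consciousness_weights:
    A: 0
    V: 3
    P: 3
    U: 3

# Glasgow Coma Scale to AVPU conversion, as [low, high, level] inclusive
# integer ranges covering 3..15.
gcs_to_avpu:
  - [15, 15, A]
  - [13, 14, V]
  - [9, 12, P]
  - [3, 8, U]

ldtews:
  max_aggregate: 15
  analytes:
    albumin:
      unit: g/L
      bands:
        - [-.inf, 18, 3]
        - [18, 27, 2]
        - [27, 34, 1]
        - [34, .inf, 0]
    creatinine:
      unit: umol/L
      male:
        bands:
          - [-.inf, 110, 0]
          - [110, 200, 1]
          - [200, .inf, 2]
      female:
        bands:
          - [-.inf, 90, 0]
          - [90, 170, 1]
          - [170, .inf, 2]
    haemoglobin:
      unit: g/L
      male:
        bands:
          - [-.inf, 100, 1]
          - [100, 180, 0]
          - [180, .inf, 1]
      female:
        bands:
          - [-.inf, 95, 1]
          - [95, 165, 0]
          - [165, .inf, 1]
    potassium:
      unit: mmol/L
      bands:
        - [-.inf, 2.9, 2]
        - [2.9, 3.4, 1]
        - [3.4, 5.5, 0]
        - [5.5, 6.0, 1]
        - [6.0, .inf, 2]
    sodium:
      unit: mmol/L
      bands:
        - [-.inf, 126, 2]
        - [126, 133, 1]
        - [133, 146, 0]
        - [146, 152, 1]
        - [152, .inf, 2]
    urea:
      unit: mmol/L
      bands:
        - [-.inf, 7.5, 0]
        - [7.5, 14, 1]
        - [14, 23, 2]
        - [23, .inf, 3]
    wcc:
      unit: 1e9 cells/L
      bands:
        - [-.inf, 2, 2]
        - [2, 4, 1]
        - [4, 12, 0]
        - [12, 20, 1]
        - [20, .inf, 2]
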