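# Expected fractional LDLC reduction by statin type and daily dose (mg).
#
# External-knowledge defaults compiled from standard dose-response
# summaries of statin efficacy trials; editable. eLDLC = LDLC / (1 - r).
# Combination therapy (statin + ezetimibe/fenofibrate) falls back to the
# statin-only factor unless a "<statin>+<agent>" entry is added.
atorvastatin:
  10: 0.37
  20: 0.43
  40: 0.49
  80: 0.55
simvastatin:
  10: 0.27
  20: 0.32
  40: 0.37
  80: 0.42
rosuvastatin:
  5: 0.38
  10: 0.43
  20: 0.48
  40: 0.53
pravastatin:
  10: 0.20
  20: 0.24
  40: 0.29
fluvastatin:
  20: 0.21
  40: 0.27
  80: 0.33
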