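# Default measurement-feedback CIM schedule (calibrated operating point).
# Pump ramps linearly from below to above the DOPO threshold (threshold at 1.0).
rounds: 1000
pump_start: 0.5
pump_end: 1.5
feedback_gain: 0.1
noise: 0.3
dt: 0.4
clip: 0.6
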