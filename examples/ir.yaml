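# Acute unit-dose ionizing-radiation exposure (DR = 1, T = 1), default model.
model: reference
protocol:
  agent: IR
  dose_rate: 1.0
  exposure_time: 1.0
t_span: [0.0, 100.0]
grid_points: 501
solver:
  method: BDF
  rtol: 1.0e-6
  atol: 1.0e-9
output_dir: results
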