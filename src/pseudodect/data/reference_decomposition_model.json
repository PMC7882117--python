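{
  "description": "Example two-material (aluminum/acrylic) decomposition model parameterized on step-wedge projections of a clinical dual-source scanner at 80/Sn140 kVp. Shipped for worked examples and desk checks; simulated workflows fit their own model.",
  "a": [0.952, 1.116, -2.353, -0.023, 0.098, -0.104],
  "b": [-0.020, 0.042],
  "c": [-2.319, -2.882, 8.509, 0.088, -0.448, 0.558],
  "d": [-0.035, 0.079],
  "domain": {"L": [0.0, 8.0], "H": [0.0, 5.0]},
  "meta": {"low_kvp": 80, "high_kvp": "Sn140"}
}
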