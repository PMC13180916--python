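[
  {"keyword": "niño", "ciu_id": "boy", "x": 0.18, "y": 0.25, "quadrant": "UL"},
  {"keyword": "niña", "ciu_id": "girl", "x": 0.30, "y": 0.35, "quadrant": "UL"},
  {"keyword": "taburete", "ciu_id": "stool", "x": 0.15, "y": 0.62, "quadrant": "LL"},
  {"keyword": "tarro de galletas", "ciu_id": "cookie_jar", "x": 0.24, "y": 0.12, "quadrant": "UL"},
  {"keyword": "galleta", "ciu_id": "cookie", "x": 0.27, "y": 0.20, "quadrant": "UL"},
  {"keyword": "armario", "ciu_id": "cupboard", "x": 0.20, "y": 0.08, "quadrant": "UL"},
  {"keyword": "madre", "ciu_id": "mother", "x": 0.70, "y": 0.30, "quadrant": "UR"},
  {"keyword": "plato", "ciu_id": "plate", "x": 0.78, "y": 0.42, "quadrant": "UR"},
  {"keyword": "fregadero", "ciu_id": "sink", "x": 0.72, "y": 0.55, "quadrant": "LR"},
  {"keyword": "agua", "ciu_id": "water", "x": 0.76, "y": 0.68, "quadrant": "LR"},
  {"keyword": "suelo", "ciu_id": "floor", "x": 0.50, "y": 0.90, "quadrant": "LL"},
  {"keyword": "ventana", "ciu_id": "window", "x": 0.88, "y": 0.18, "quadrant": "UR"},
  {"keyword": "cortina", "ciu_id": "curtains", "x": 0.93, "y": 0.22, "quadrant": "UR"},
  {"keyword": "jardín", "ciu_id": "garden", "x": 0.90, "y": 0.35, "quadrant": "UR"},
  {"keyword": "paño", "ciu_id": "dishcloth", "x": 0.66, "y": 0.38, "quadrant": "UR"}
]
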