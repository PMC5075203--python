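{
 "note": "Default organelle feature distributions. These are NOT published fits: the source fits are shown only as curves, so these values were chosen once for plausibility. Count means follow the reported per-cell object totals (~5.6 nucleoli, ~41 golgi, ~177 vesicles per cell); size/shape/position parameters respect the observed area anchors (golgi up to ~4%, vesicles ~6% of cell area, nucleoli up to 19.3% of nuclear area).",
 "pdfs": [
  {"organelle": "nucleoli", "feature": "count", "family": "gamma", "params": [2.8, 2.0], "support": [0.0, null], "log_likelihood": null},
  {"organelle": "nucleoli", "feature": "position", "family": "gamma", "params": [9.0, 0.08], "support": [0.0, 1.0], "log_likelihood": null},
  {"organelle": "nucleoli", "feature": "minor_axis_ratio", "family": "gamma", "params": [6.0, 0.025], "support": [0.0, 1.0], "log_likelihood": null},
  {"organelle": "nucleoli", "feature": "axes_ratio", "family": "gamma", "params": [14.0, 0.05], "support": [0.0, 1.0], "log_likelihood": null},
  {"organelle": "golgi", "feature": "count", "family": "gamma", "params": [4.2, 10.0], "support": [0.0, null], "log_likelihood": null},
  {"organelle": "golgi", "feature": "position", "family": "t_location_scale", "params": [1.05, 0.08, 5.0], "support": [0.0, 2.0], "log_likelihood": null},
  {"organelle": "golgi", "feature": "minor_axis_ratio", "family": "gamma", "params": [4.0, 0.018], "support": [0.0, 1.0], "log_likelihood": null},
  {"organelle": "golgi", "feature": "axes_ratio", "family": "gamma", "params": [7.0, 0.08], "support": [0.0, 1.0], "log_likelihood": null},
  {"organelle": "vesicles", "feature": "count", "family": "gamma", "params": [3.5, 50.0], "support": [0.0, null], "log_likelihood": null},
  {"organelle": "vesicles", "feature": "position", "family": "t_location_scale", "params": [1.1, 0.12, 4.0], "support": [0.0, 2.0], "log_likelihood": null},
  {"organelle": "vesicles", "feature": "minor_axis_ratio", "family": "gamma", "params": [3.5, 0.013], "support": [0.0, 1.0], "log_likelihood": null},
  {"organelle": "vesicles", "feature": "axes_ratio", "family": "gamma", "params": [10.0, 0.075], "support": [0.0, 1.0], "log_likelihood": null}
 ]
}
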