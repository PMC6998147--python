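{
  "model_smk": {
    "intercept": 1.6715,
    "coefficients": {
      "ADM": -2.2568,
      "AREG": 2.0152,
      "CXCR4": -3.1177,
      "EFNA1": 3.7889,
      "EGLN3": -4.0571,
      "FBXO32": -3.8824,
      "HILPDA": 3.2193,
      "IGFBP3": -8.2992,
      "SLC7A11": -3.5355,
      "TXNIP": -5.6745,
      "WNT5A": 2.7391
    }
  },
  "model_copd": {
    "intercept": -0.8555,
    "coefficients": {
      "AREG": -1.3039,
      "DUSP6": 1.4688,
      "EFNA1": 2.3861,
      "TXNIP": -0.8847
    }
  },
  "scaling_note": "Coefficients were fitted on GC-RMA normalized expression values of the pooled public cohorts; applying them to differently scaled data may require affine recalibration."
}
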