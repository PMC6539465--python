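{
  "intercept": 2.712,
  "terms": [
    {"name": "S_EP-C88.75", "coef": -0.185, "t": -6.582},
    {"name": "S_EP-C35.25", "coef": -0.266, "t": -6.731},
    {"name": "S_EP-C36.25", "coef": 0.361, "t": 10.565},
    {"name": "S_EP-C82.75", "coef": -0.213, "t": -10.501},
    {"name": "S_EP-C31.25", "coef": -0.289, "t": -7.917},
    {"name": "S_EP-C89.75", "coef": 0.133, "t": 4.936},
    {"name": "S_EP-C64.25", "coef": 0.204, "t": 7.241},
    {"name": "S_EP-C53.25", "coef": -0.142, "t": -5.498},
    {"name": "S_σ-C0.013", "coef": 0.537, "t": 18.957},
    {"name": "S_σ-C-0.012", "coef": -0.102, "t": -9.583},
    {"name": "S_σ-C-0.016", "coef": 0.234, "t": 8.303}
  ],
  "meta": {
    "endpoint": "logEC50 (AChE), EC50 in uM",
    "note": "Reported 11-descriptor stepwise MLR model for ionic-liquid toxicity toward acetylcholinesterase; all surviving descriptors are cation features."
  }
}
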