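"""Evaluate the published 11-descriptor linear toxicity model.

The reported stepwise-MLR model predicts logEC50 toward acetylcholinesterase
from 8 cation ESP surface-area bins and 3 cation σ-profile bins.  Descriptor
values are bin areas in Å²; larger logEC50 means lower toxicity.
"""

import pandas as pd

from iltox import descriptor_names, predict_linear, published_model

model = published_model()
print(f"intercept P0 = {model.intercept}")
print(f"{model.n_terms} terms; most influential (|t|):")
for name in sorted(model.t_values, key=lambda n: -abs(model.t_values[n]))[:3]:
    print(f"  {name:14s} coef {model.coefficients[name]:+.3f} "
          f"t {model.t_values[name]:+.3f}")

# An all-zero descriptor row evaluates to the intercept:
zeros = pd.Series(0.0, index=descriptor_names())
print(f"prediction on zero row: {predict_linear(model, zeros)}")

# One square Angstrom of cation surface in the sigma bin [0.013, 0.014):
row = zeros.copy()
row["S_σ-C0.013"] = 1.0
print(f"with 1 A^2 in S_σ-C0.013: {predict_linear(model, row)}")
# 2.712 + 0.537: more HB-acceptor cation surface raises logEC50,
# i.e. lowers the toxicity of the ionic liquid.
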