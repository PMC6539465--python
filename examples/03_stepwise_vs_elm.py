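"""Fit and compare the linear and nonlinear models on a synthetic study.

Generates a 160-sample descriptor table whose activity is exactly linear in
11 known descriptors (plus noise), splits it 80/20, stepwise-selects the MLR
model, sweeps the ELM neuron count, and prints the usual comparison table
(R², AARD%, RMSE per set).  Because the ground truth here is linear, the MLR
is expected to win; on real activity data with curvature the ELM can.
"""

from iltox import (
    QSARGenSpec,
    StepwiseConfig,
    auto_sweep,
    fit_elm,
    gen_qsar_dataset,
    split_train_test,
    stepwise_select,
    validation_report,
)

table, truth = gen_qsar_dataset(QSARGenSpec(seed=7))
train, test = split_train_test(table, 0.8, seed=7)
print(f"{len(table)} ILs -> {len(train)} train / {len(test)} test")

model, trace = stepwise_select(train, StepwiseConfig(max_terms=11))
hits = len(set(model.names) & set(truth.names))
print(f"stepwise selected {model.n_terms} descriptors "
      f"({hits}/{truth.n_terms} of the true ones)")

sweep = auto_sweep(train[model.names], train["logEC50"],
                   test[model.names], test["logEC50"], seed=7)
elm = fit_elm(train[model.names], train["logEC50"],
              n_hidden=sweep.best_n, seed=7)
print(f"ELM neuron sweep: best count {sweep.best_n} (minimum test AARD%)")

print(f"\n{'model':6s} {'set':6s} {'N':>4s} {'R2':>8s} {'AARD%':>7s} {'RMSE':>7s}")
for name, mdl in (("MLR", model), ("ELM", elm)):
    rep = validation_report(mdl, train, test)
    for label in ("train", "test", "total"):
        m = rep["metrics"][label]
        print(f"{name:6s} {label:6s} {m['n']:4d} {m['r2']:8.4f} "
              f"{m['aard_pct']:7.2f} {m['rmse']:7.4f}")
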