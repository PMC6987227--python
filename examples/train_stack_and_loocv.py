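"""Feature selection, stacking, and leave-one-out evaluation.

Generates a synthetic feature table with a planted linear signal (two
informative features among twelve), then runs the honest pipeline: for every
held-out complex, correlation ranking, greedy forward selection and the
two-layer stack (GBRT + AdaBoost + bagged trees under an XGBoost meta-model)
are refit on the remaining rows.
"""

from predba import greedy_select, loocv_evaluate
from predba.synthetic import SyntheticTableSpec, make_synthetic_table

spec = SyntheticTableSpec(
    n_rows=30, n_features=12, informative_weights=(2.0, 1.0),
    noise_sd=0.1, seed=1,
)
table, y, truth = make_synthetic_table(spec)

selection = greedy_select(table, y)
print(f"planted features   : {sorted(truth.informative)}")
print(f"greedy selection   : {selection.selected}")
print(f"objective trace    : {[round(v, 4) for v in selection.objective_trace]}")

report = loocv_evaluate(table, y, mode="honest", seed=1)
print(f"LOOCV over {report.n} rows: r = {report.r:.3f}, "
      f"MAE = {report.mae:.3f} kcal/mol, R2 = {report.r2:.3f}")
# r is the Pearson correlation between held-out predictions and the true dG;
# values near 1 mean the pipeline recovered the planted signal.
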