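"""Render the two HTML report types from one classification evaluation.

The method report summarises the whole evaluation (configuration, per-size
tables, performance-vs-size figures with the best model flagged in red); the
model report describes the selected best model (confusion matrix, per-class
metrics, ROC, PCA of the model's features, per-class violins). Both are
self-contained static HTML files written to ./example_reports/.
"""

import os

import replearn as rl

ds, _ = rl.simulate_classification(n_obs=120, n_features=15, n_informative=3,
                                   effect_size=2.0, seed=4)
spec = rl.LearnerSpec("random_forest", "classification",
                      {"n_estimators": [100], "max_depth": [None]})
ev = rl.evaluate_method(ds, spec, rl.SizeGrid(sizes=(60, 90), n_repeats=4),
                        metric="err", seed=4)

out = "example_reports"
os.makedirs(out, exist_ok=True)
ev.save(out)
rl.render_method_report(ev, os.path.join(out, "report_method.html"))

best = rl.select_best_model(ev, "err")
rl.render_model_report(best, ds, os.path.join(out, "report_model.html"))

print(f"wrote {out}/report_method.html and {out}/report_model.html")
print(f"best model: size {best.size}, test err {best.scores['test']['err']:.3f}")
print("evaluation.json / summaries.csv / models.csv sit alongside, and every "
      "number in the reports is recomputable from them")
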