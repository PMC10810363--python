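"""Static, self-contained HTML reports.

Two report types mirror the two evaluation granularities:

* the **method report** summarises one learning-method evaluation -- the
  configuration (learner, sampling, screening, tuning, metric, seed), the
  per-size mean/SD/SEM/CI tables for the train/test/full slices, and a
  performance-vs-size figure (per-model dots, boxplots, mean line, CI band)
  with the automatically selected best model highlighted in red;
* the **model report** describes a single model -- confusion matrix, per-class
  and averaged metrics, ROC curve (binary, when the learner exposes a
  continuous decision value), a PCA scatter restricted to the model's own
  features, per-class violin plots of the first principal-component score,
  and an external-evaluation table when an external dataset is supplied.

Reports are pure with respect to the evaluation: every number is read from
the (serializable) MethodEvaluation, and figures embed inline SVG with no
network assets. A plot-data JSON is written alongside each figure so the
graphics can be re-rendered or made interactive elsewhere.
"""

from __future__ import annotations

import html
import io
import json
import math
import os
from typing import Optional

import matplotlib

matplotlib.use("Agg")
# deterministic SVG output: fixed element-id salt, no embedded creation date
matplotlib.rcParams["svg.hashsalt"] = "replearn"
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datasets import Dataset
from .evaluation import SLICES, MethodEvaluation, ModelRecord, select_best_model
from .metrics import (
    CLASSIFICATION_METRICS,
    classification_score,
    confusion_matrix,
    get_metric,
    multiclass_average,
    score_predictions,
)

__all__ = ["render_method_report", "render_model_report"]

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em auto; max-width: 70em; color: #222; }}
table {{ border-collapse: collapse; margin: 1em 0; }}
th, td {{ border: 1px solid #bbb; padding: 0.3em 0.7em; text-align: right; }}
th {{ background: #eef; }}
td.l, th.l {{ text-align: left; }}
h1 {{ border-bottom: 2px solid #447; }}
.fig {{ margin: 1em 0; }}
.note {{ color: #666; font-size: 0.9em; }}
</style></head><body>
<h1>{title}</h1>
{body}
</body></html>
"""


def _fig_to_svg(fig) -> str:
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    svg = buf.getvalue()
    return svg[svg.find("<svg") :]


def _table(df: pd.DataFrame, floatfmt: str = "{:.4g}") -> str:
    head = "".join(f"<th class='l'>{html.escape(str(c))}</th>" for c in df.columns)
    rows = []
    for _, row in df.iterrows():
        cells = []
        for v in row:
            if isinstance(v, float):
                txt = "&mdash;" if math.isnan(v) else floatfmt.format(v)
                cells.append(f"<td>{txt}</td>")
            else:
                cells.append(f"<td class='l'>{html.escape(str(v))}</td>")
        rows.append("<tr>" + "".join(cells) + "</tr>")
    return f"<table><tr>{head}</tr>{''.join(rows)}</table>"


def _write_aux(out_path, name: str, svg: str, plotdata: dict) -> None:
    base = os.path.dirname(os.path.abspath(out_path))
    figdir = os.path.join(base, "figures")
    datadir = os.path.join(base, "plotdata")
    os.makedirs(figdir, exist_ok=True)
    os.makedirs(datadir, exist_ok=True)
    with open(os.path.join(figdir, f"{name}.svg"), "w") as fh:
        fh.write(svg)
    with open(os.path.join(datadir, f"{name}.json"), "w") as fh:
        json.dump(plotdata, fh, sort_keys=True, indent=1)


def _method_figure(ev: MethodEvaluation, metric: str, data_slice: str,
                   best: Optional[ModelRecord]):
    sizes = list(ev.sizes)
    per_size_scores = {
        s: [r.scores[data_slice].get(metric, math.nan)
            for r in ev.records if r.size == s and not r.failed]
        for s in sizes
    }
    summ = ev.summaries[metric][data_slice]
    means = [summ[s].mean for s in sizes]
    lo = [summ[s].ci_low for s in sizes]
    hi = [summ[s].ci_high for s in sizes]

    fig, ax = plt.subplots(figsize=(7, 4.2))
    ax.fill_between(sizes, lo, hi, color="#ffb", alpha=0.8, zorder=1,
                    label=f"{int(100 * summ[sizes[0]].confidence)}% CI")
    clean = [[v for v in per_size_scores[s] if not math.isnan(v)] for s in sizes]
    span = (max(sizes) - min(sizes)) or 1
    ax.boxplot(clean, positions=sizes, widths=0.04 * span,
               manage_ticks=False, zorder=2)
    for s in sizes:
        vals = [v for v in per_size_scores[s] if not math.isnan(v)]
        ax.plot([s] * len(vals), vals, "o", color="#2a2", ms=4, alpha=0.6, zorder=3)
    ax.plot(sizes, means, "-o", color="#e80", lw=2, zorder=4, label="mean")
    if best is not None and data_slice == "test":
        ax.plot([best.size], [best.scores["test"][metric]], "o", color="red",
                ms=10, mfc="none", mew=2, zorder=5, label="best model")
    ax.set_xlabel("training-set size")
    ax.set_ylabel(f"{metric} ({data_slice})")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    plotdata = {
        "metric": metric, "slice": data_slice, "sizes": sizes,
        "scores": {str(s): per_size_scores[s] for s in sizes},
        "mean": means, "ci_low": lo, "ci_high": hi,
        "best": None if best is None else {"size": best.size,
                                           "repeat_id": best.repeat_id},
    }
    return _fig_to_svg(fig), plotdata


def render_method_report(ev: MethodEvaluation, out_path) -> str:
    """Render the learning-methodology report; returns the output path."""
    primary = ev.metrics[0]
    try:
        best = select_best_model(ev, primary)
    except ValueError:
        best = None
    parts = ["<h2>Methodology</h2>"]
    cfg = ev.config
    meta = pd.DataFrame(
        [("learner", f"{cfg['learner']['family']} ({cfg['learner']['task']})"),
         ("hyperparameter grid", json.dumps(cfg["learner"]["grid"])),
         ("sampling", f"{cfg['sampling']['scheme']} / allocation {cfg['sampling']['allocation']}"),
         ("tuning", f"inner {cfg['tuning']['inner_scheme']} (k={cfg['tuning']['inner_k']}), rule {cfg['tuning']['rule']}"),
         ("supervised screening", json.dumps(cfg["screening"]) if cfg["screening"] else "none"),
         ("metric", cfg["metric"]),
         ("confidence level", cfg["confidence"]),
         ("training-set sizes", str(list(ev.sizes))),
         ("repeats per size", ev.n_repeats),
         ("seed", cfg["seed"]),
         ("dataset digest", ev.dataset_digest)],
        columns=["setting", "value"],
    )
    parts.append(_table(meta))

    if best is not None:
        parts.append("<h2>Overall best model</h2>")
        parts.append(_table(pd.DataFrame([{
            "size": best.size, "repeat": best.repeat_id,
            "configuration": json.dumps(best.configuration, sort_keys=True),
            f"test {primary}": best.scores["test"][primary],
            "features": len(best.selected_features),
        }])))

    sf = ev.summaries_frame()
    for metric in ev.metrics:
        parts.append(f"<h2>Per-size summaries &mdash; {metric}</h2>")
        for sl in SLICES:
            sub = sf[(sf["metric"] == metric) & (sf["slice"] == sl)]
            parts.append(f"<h3>{sl} slice</h3>")
            parts.append(_table(sub.drop(columns=["metric", "slice"])))
        for sl in SLICES:
            svg, plotdata = _method_figure(ev, metric, sl, best)
            _write_aux(out_path, f"method_{metric}_{sl}", svg, plotdata)
            parts.append(f"<div class='fig'>{svg}</div>")

    parts.append("<h2>Models</h2>")
    parts.append(_table(ev.models_frame()))
    parts.append("<p class='note'>Every value above is recomputable from the "
                 "serialized evaluation; report generation performs no model "
                 "fitting or scoring.</p>")
    with open(out_path, "w") as fh:
        fh.write(_PAGE.format(title="Learning-method evaluation report",
                              body="\n".join(parts)))
    return out_path


def _roc_points(y_true, score, positive) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y_true) == positive
    order = np.argsort(-np.asarray(score, dtype=float), kind="stable")
    y = y[order]
    tps = np.concatenate([[0], np.cumsum(y)])
    fps = np.concatenate([[0], np.cumsum(~y)])
    tpr = tps / max(tps[-1], 1)
    fpr = fps / max(fps[-1], 1)
    return fpr, tpr


def _pca_scores(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centered = M - M.mean(axis=0)
    U, S, _ = np.linalg.svd(centered, full_matrices=False)
    var = S**2
    frac = var / var.sum() if var.sum() > 0 else var
    return U * S, frac


def render_model_report(
    record: ModelRecord,
    dataset: Dataset,
    out_path,
    external: Optional[tuple] = None,
    positive=None,
) -> str:
    """Render the single-model report; returns the output path.

    ``external`` is an optional (X_ext, y_ext) pair evaluated without any
    refitting. Classification panels (confusion matrix, per-class metrics,
    ROC) appear only for classification tasks.
    """
    model = record.model
    if model is None:
        raise ValueError("the record carries no in-memory fitted model")
    task = model.spec.task
    cols = record.selected_features
    X = dataset.X
    y = np.asarray(dataset.y)
    held = record.held_out_idx
    pred_held = model.predict(X.iloc[held][cols])
    parts = ["<h2>Model</h2>"]
    parts.append(_table(pd.DataFrame([{
        "learner": model.spec.family, "task": task,
        "configuration": json.dumps(record.configuration, sort_keys=True),
        "training size": record.size, "repeat": record.repeat_id,
        "features": len(cols),
    }])))

    if task == "classification":
        labels = list(np.unique(y))
        pos = positive if positive is not None else labels[-1]
        parts.append("<h2>Confusion matrix (held-out data)</h2>")
        cm_rows = []
        for lab_t in labels:
            row = {"actual \\ predicted": lab_t}
            for lab_p in labels:
                row[str(lab_p)] = int(np.sum((y[held] == lab_t) & (pred_held == lab_p)))
            cm_rows.append(row)
        parts.append(_table(pd.DataFrame(cm_rows)))

        parts.append("<h2>Per-class metrics (held-out data)</h2>")
        rows = []
        for lab in labels:
            cm = confusion_matrix(y[held], pred_held, lab)
            rows.append({"class": str(lab), **{
                m: classification_score(cm, m) for m in CLASSIFICATION_METRICS
            }})
        avg = {"class": "macro average", **{
            m: multiclass_average([r[m] for r in rows]) for m in CLASSIFICATION_METRICS
        }}
        parts.append(_table(pd.DataFrame(rows + [avg])))

        score = model.decision_value(X.iloc[held][cols])
        if score is not None and len(labels) == 2:
            fpr, tpr = _roc_points(y[held], score, pos)
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.plot(fpr, tpr, "-", color="#447")
            ax.plot([0, 1], [0, 1], "--", color="#999")
            ax.set_xlabel("false positive rate")
            ax.set_ylabel("true positive rate")
            ax.set_title(f"ROC (positive = {pos})")
            fig.tight_layout()
            svg = _fig_to_svg(fig)
            _write_aux(out_path, "model_roc", svg,
                       {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "positive": str(pos)})
            parts.append(f"<div class='fig'>{svg}</div>")
        else:
            parts.append("<p class='note'>ROC omitted: no continuous decision "
                         "value available or more than two classes.</p>")
    else:
        parts.append("<h2>Held-out metrics</h2>")
        parts.append(_table(pd.DataFrame(
            [{"metric": m, "value": v} for m, v in record.scores["test"].items()]
        )))

    # PCA restricted to the model's own features
    M = X[cols].to_numpy(dtype=float)
    if M.shape[1] >= 2:
        scores_pc, frac = _pca_scores(M)
        fig, ax = plt.subplots(figsize=(5, 4))
        if task == "classification":
            for lab in np.unique(y):
                sel = y == lab
                ax.plot(scores_pc[sel, 0], scores_pc[sel, 1], "o", ms=4,
                        alpha=0.6, label=str(lab))
            ax.legend(fontsize=8)
        else:
            sc = ax.scatter(scores_pc[:, 0], scores_pc[:, 1], c=y, s=14, cmap="viridis")
            fig.colorbar(sc, ax=ax, label="response")
        ax.set_xlabel(f"PC1 ({100 * frac[0]:.1f}% var)")
        ax.set_ylabel(f"PC2 ({100 * frac[1]:.1f}% var)")
        ax.set_title("PCA of the model's features")
        fig.tight_layout()
        svg = _fig_to_svg(fig)
        _write_aux(out_path, "model_pca", svg,
                   {"variance_fractions": frac.tolist()})
        parts.append(f"<div class='fig'>{svg}</div>")

        if task == "classification":
            # violin of the first principal-component score per class
            fig, ax = plt.subplots(figsize=(5, 3.5))
            groups = [scores_pc[y == lab, 0] for lab in np.unique(y)]
            ax.violinplot(groups, showmedians=True)
            ax.set_xticks(range(1, len(groups) + 1),
                          [str(lab) for lab in np.unique(y)])
            ax.set_ylabel("PC1 score of model features")
            fig.tight_layout()
            svg = _fig_to_svg(fig)
            _write_aux(out_path, "model_violin", svg,
                       {"classes": [str(lab) for lab in np.unique(y)]})
            parts.append(f"<div class='fig'>{svg}</div>")

    metric_names = (CLASSIFICATION_METRICS if task == "classification"
                    else tuple(record.scores["test"]))
    internal = pd.DataFrame([
        {"metric": m,
         "value": score_predictions(y[held], pred_held, get_metric(m), task, positive)}
        for m in metric_names
    ])
    parts.append("<h2>Internal evaluation (held-out data)</h2>")
    parts.append(_table(internal))
    if external is not None:
        X_ext, y_ext = external
        pred_ext = model.predict(X_ext)
        ext = pd.DataFrame([
            {"metric": m,
             "value": score_predictions(np.asarray(y_ext), pred_ext,
                                        get_metric(m), task, positive)}
            for m in metric_names
        ])
        parts.append("<h2>External evaluation</h2>")
        parts.append(_table(ext))

    with open(out_path, "w") as fh:
        fh.write(_PAGE.format(title="Model evaluation report",
                              body="\n".join(parts)))
    return out_path
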