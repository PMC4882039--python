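"""End-to-end workflows: train, predict, evaluate.

Training mirrors the identification workflow: clean both FASTA pools with the
strict length window, extract the 89 features, rank them by FSC and keep the
top p, pick L representative transcripts per class with the SOM, drop
non-coding examples answered by the short-ORF shortcut, and fit the forest.
Prediction cleans leniently (alphabet normalization only; out-of-window
records are flagged, not dropped — a deployed classifier must answer for
arbitrary user input), extracts features, applies shortcut + forest and
writes the TSV report.  Every run emits a machine-readable provenance block
(config hash, stage seeds, per-stage counts).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier, evaluation, feature_selection, sequence_io, som
from .config import RunConfig
from .errors import ValidationError
from .features import feature_frame
from .sequence_io import CODING, NONCODING


def _provenance(config: RunConfig, stage_counts: dict) -> dict:
    return {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "stage_seeds": config.stage_seeds(),
        "stage_counts": stage_counts,
    }


def load_training_pools(config: RunConfig, coding_fasta, noncoding_fasta):
    """Read, label and strictly clean the two training FASTA pools."""
    counts = {}
    pools = {}
    for label, path in ((CODING, coding_fasta), (NONCODING, noncoding_fasta)):
        records = sequence_io.read_fasta(path)
        for r in records:
            r.label = label
        kept, report = sequence_io.clean_transcripts(
            records, min_len=config.min_len, max_len=config.max_len
        )
        pools[label] = kept
        counts[label] = {
            "input": report.total,
            "kept": report.kept,
            "rejected_alphabet": report.rejected_alphabet,
            "rejected_length": report.rejected_length,
            "rejected_duplicate": report.rejected_duplicate,
        }
    return pools, counts


def run_train(
    config: RunConfig,
    coding_fasta,
    noncoding_fasta,
    out_model,
    log_path=None,
    som_subsample: bool = True,
) -> classifier.CodingPotentialResults:
    """Full training workflow; persists the model bundle and a run log."""
    seeds = config.stage_seeds()
    pools, stage_counts = load_training_pools(config, coding_fasta, noncoding_fasta)

    transcripts = pools[CODING] + pools[NONCODING]
    X, y = feature_frame(transcripts)
    stage_counts["features"] = {"rows": int(len(X)), "columns": int(X.shape[1])}

    ranking = feature_selection.fsc_scores(X, y)
    selected = feature_selection.select_top(ranking, config.p)
    stage_counts["feature_selection"] = {
        "input_dim": int(X.shape[1]),
        "selected_dim": len(selected),
    }

    if som_subsample:
        pos_mask = (y == NONCODING).to_numpy()
        X_sel = X[selected]
        pos_ids, neg_ids = som.select_training_set(
            X_sel.loc[pos_mask].to_numpy(),
            X_sel.loc[~pos_mask].to_numpy(),
            L=min(config.L, int(pos_mask.sum()), int((~pos_mask).sum())),
            seed=seeds["som"],
            rows=config.som_rows,
            cols=config.som_cols,
            epochs=config.som_epochs,
            positive_ids=list(X.index[pos_mask]),
            negative_ids=list(X.index[~pos_mask]),
        )
        chosen = list(pos_ids) + list(neg_ids)
        X_train, y_train = X.loc[chosen], y.loc[chosen]
        stage_counts["som_sampling"] = {
            "positive_selected": len(pos_ids),
            "negative_selected": len(neg_ids),
        }
    else:
        X_train, y_train = X, y

    model = classifier.CodingPotentialModel(
        X_train,
        y_train,
        selected_features=selected,
        n_trees=config.n_trees,
        orf_shortcut=config.orf_shortcut,
        decision_threshold=config.decision_threshold,
    )
    results = model.fit(seed=seeds["forest"])
    results.ranking = ranking
    results.metadata["provenance"] = _provenance(config, stage_counts)
    stage_counts["train"] = {
        "used": results.metadata["n_train_used"],
        "shortcut_filtered": results.metadata["n_shortcut_filtered"],
    }
    results.save(out_model)
    if log_path is not None:
        Path(log_path).write_text(
            json.dumps(_provenance(config, stage_counts), indent=2) + "\n"
        )
    return results


def run_predict(
    config: RunConfig,
    model_path,
    fasta,
    out_tsv,
    log_path=None,
) -> list[classifier.Prediction]:
    """Score a FASTA file with a persisted model and write the report."""
    results = (
        model_path
        if isinstance(model_path, classifier.CodingPotentialResults)
        else classifier.CodingPotentialResults.load(model_path)
    )
    records = sequence_io.read_fasta(fasta)
    kept, report = sequence_io.clean_transcripts(
        records,
        min_len=config.min_len,
        max_len=config.max_len,
        drop_duplicates=False,
        length_action="flag",
    )
    X, _ = feature_frame(kept)
    predictions = results.predict(X)
    sequence_io.write_report(predictions, out_tsv)
    if report.rejections:
        sequence_io.write_rejection_log(
            report, Path(out_tsv).with_suffix(".rejected.tsv")
        )
    if log_path is not None:
        counts = {
            "input": report.total,
            "scored": len(predictions),
            "rejected_alphabet": report.rejected_alphabet,
            "flagged_length": report.flagged_length,
            "shortcut_calls": int(sum(p.shortcut_applied for p in predictions)),
        }
        Path(log_path).write_text(
            json.dumps(_provenance(config, {"predict": counts}), indent=2) + "\n"
        )
    return predictions


def run_evaluate(report_tsv, labels_tsv, out_metrics=None):
    """Compare a prediction report against a label table.

    Returns (ConfusionCounts, MetricSet); AUC excludes shortcut rows (their
    score is degenerate).  Ids present in the report but absent from the
    label table are an error.
    """
    rep = pd.read_csv(report_tsv, sep="\t", dtype={"id": str})
    labels = sequence_io.read_labels(labels_tsv)
    missing = [i for i in rep["id"] if i not in labels]
    if missing:
        raise ValidationError(
            f"ids missing from label table: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    y_true = np.array([labels[i] for i in rep["id"]])
    y_pred = rep["predicted_class"].to_numpy()
    c = evaluation.confusion(y_true, y_pred)
    m = evaluation.metrics(c)
    shortcut = rep["shortcut_applied"].astype(str).str.lower() == "true"
    keep = ~shortcut.to_numpy()
    if keep.any() and len(set(y_true[keep])) == 2:
        m.auc = evaluation.roc_auc(
            rep["noncoding_score"].to_numpy()[keep], y_true[keep]
        )
    if out_metrics is not None:
        evaluation.write_metrics(c, m, out_metrics)
    return c, m
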