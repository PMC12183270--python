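"""End-to-end pipeline: harmonize → CV folds → SMOTE → graphs → GATs → ensembles.

For each stratified CV iteration the held-out fold is the (real-only) test
set; the remaining folds are re-split 8:1 per class into training and
validation, both oversampled by class-wise SMOTE; per-atlas GAT models are
trained and their softmax outputs combined by majority vote, probability sum
and accuracy-weighted sum. All randomness descends from ``config.seed``
through named substreams, so two runs with the same seed and config are
identical.
"""

from __future__ import annotations

import logging
from typing import Dict, List

import numpy as np

from ._rng import substream, substream_seed
from .cohort import Cohort, PipelineConfig, SubjectRecord
from .connectome import build_graph_dataset
from .ensemble import PredictionSet, majority_vote, sum_vote, weighted_sum_vote
from .evaluation import (ConfusionCounts, CVSummary, MetricReport, compute_metrics,
                         stratified_kfold, summarize_cv, train_val_split)
from .gat import TrainedAtlasModel, train_gat
from .harmonization import harmonize
from .oversampling import SmoteSpec, oversample_split

logger = logging.getLogger(__name__)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _subset(cohort: Cohort, records: List[SubjectRecord]) -> Cohort:
    return Cohort(cohort.atlases, records, cohort.t_points)


def run_fold(cohort: Cohort, train_ids: List[str], test_ids: List[str],
             config: PipelineConfig, fold: int) -> Dict[str, MetricReport]:
    """One CV iteration; returns per-atlas and per-ensemble-method reports."""
    by_id = {s.subject_id: s for s in cohort.subjects}
    fold_seed = substream_seed(config.seed, "fold", str(fold))

    trainval = [by_id[i] for i in train_ids]
    tr_ids, va_ids = train_val_split(trainval, seed=fold_seed)
    train = [by_id[i] for i in tr_ids]
    val = [by_id[i] for i in va_ids]
    test = [by_id[i] for i in test_ids]
    assert not any(s.is_synthetic for s in test)

    min_class = min(sum(1 for s in part if s.label == lab)
                    for part in (train, val) for lab in (0, 1))
    k_eff = min(config.smote_k, min_class - 1)
    if k_eff < config.smote_k:
        logger.warning("fold %d: smote_k clamped to %d (smallest class has %d subjects)",
                       fold, k_eff, min_class)
    if k_eff >= 1:
        spec = SmoteSpec(k_neighbors=k_eff, multiplier=config.smote_multiplier,
                         gap_mode=config.gap_mode)
        train_plus, val_plus = oversample_split(train, val, spec,
                                                rng=substream(fold_seed, "smote"))
    else:
        logger.warning("fold %d: class too small for SMOTE; sets left unchanged", fold)
        train_plus, val_plus = list(train), list(val)

    test_labels = np.array([s.label for s in test])
    test_sids = [s.subject_id for s in test]
    probs: Dict[str, np.ndarray] = {}
    accs: Dict[str, float] = {}
    reports: Dict[str, MetricReport] = {}
    for atlas in cohort.atlas_names:
        tr_graphs = build_graph_dataset(_subset(cohort, train_plus), atlas,
                                        config.knn_k, metric=config.knn_metric)
        va_graphs = build_graph_dataset(_subset(cohort, val_plus), atlas,
                                        config.knn_k, metric=config.knn_metric)
        te_graphs = build_graph_dataset(_subset(cohort, test), atlas,
                                        config.knn_k, metric=config.knn_metric)
        model = train_gat(tr_graphs, va_graphs, config, atlas=atlas, seed=fold_seed)
        accs[atlas] = model.val_accuracy
        p = model.predict_proba(te_graphs)
        probs[atlas] = p
        pred = np.where(p[:, 1] >= p[:, 0], 1, 0)
        reports[atlas] = compute_metrics(ConfusionCounts.from_labels(test_labels, pred))

    preds = PredictionSet(subject_ids=test_sids, probabilities=probs,
                          val_accuracies=accs, model_order=cohort.atlas_names)
    for name, res in (("majority", majority_vote(preds)),
                      ("sum", sum_vote(preds)),
                      ("weighted_sum", weighted_sum_vote(preds))):
        reports[name] = compute_metrics(
            ConfusionCounts.from_labels(test_labels, res.final_labels))
    return reports


def run_pipeline(config: PipelineConfig, cohort: Cohort) -> CVSummary:
    """The full protocol; bit-reproducible for a fixed seed and config."""
    labels = [s.label for s in cohort.real_subjects()]
    if min(labels.count(0), labels.count(1)) < 2:
        raise ValueError("need at least 2 real subjects per class")

    work = cohort
    n_sites = len({s.site_id for s in cohort.subjects})
    if config.harmonize and n_sites >= 2:
        work = _stage("harmonize")(harmonize)(cohort)[0]
    elif config.harmonize:
        logger.info("single site: harmonization skipped")

    folds = _stage("kfold")(stratified_kfold)(work, k=config.n_folds, seed=config.seed)
    fold_reports: Dict[str, List[MetricReport]] = {}
    for i, (train_ids, test_ids) in enumerate(folds):
        reports = _stage(f"fold{i}")(run_fold)(work, train_ids, test_ids, config, i)
        for name, rep in reports.items():
            fold_reports.setdefault(name, []).append(rep)
        logger.info("fold %d: %s", i,
                    {k: round(v.acc, 3) for k, v in reports.items()})
    return summarize_cv(fold_reports)
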