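#!/usr/bin/env python
"""Augment, train and validate the diagnostic network.

Binomial-thinning augmentation expands the 3+3 WGBS parents into 21
control and 60 case sub-samples; a stratified 0.6666 split feeds the
three-hidden-layer network; validation runs on the held-out sub-samples,
on an independent array cohort projected through the same regions, and
against a label-shuffle control.  The score is also correlated with the
per-sample activity score on the array cohort.
"""

import importlib
import json

import numpy as np
import pandas as pd

from cflmd.classifier import NetSpec, roc_auc, score, scores_frame, spearman, split_train_val, train_nn
from cflmd.feature_integration import build_feature_matrix_wgbs, project_features_array
from cflmd.io_formats import CASE, read_beta_matrix
from cflmd.wgbs_dmr import augment_subsamples

from common import OUT_DIR, STUDY_SEED, load_annotation, load_wgbs_tables, validation_paths

load_dmrs = importlib.import_module("04_integrate_features").load_dmrs

N_SHUFFLE_SEEDS = 10


def _model_regions():
    keep = set(pd.read_csv(OUT_DIR / "model_regions.csv")["region_id"])
    return [d for d in load_dmrs() if d.region_id in keep]


def main() -> None:
    regions = _model_regions()
    subs = augment_subsamples(load_wgbs_tables(), seed=STUDY_SEED)
    fm = build_feature_matrix_wgbs(regions, subs)
    train, val = split_train_val(fm, seed=STUDY_SEED)
    model = train_nn(train, NetSpec(seed=STUDY_SEED))

    val_scores = scores_frame(score(model, val))
    val_scores.to_csv(OUT_DIR / "validation_scores_wgbs.csv")
    auc_wgbs = roc_auc(val_scores["score"], val_scores["group"] == CASE)

    val_beta = read_beta_matrix(*validation_paths())
    arr_fm = project_features_array(regions, val_beta, load_annotation())
    arr_scores = scores_frame(score(model, arr_fm))
    arr_scores.to_csv(OUT_DIR / "validation_scores_array.csv")
    auc_array = roc_auc(arr_scores["score"], arr_scores["group"] == CASE)
    rho, rho_p = spearman(arr_scores["score"], arr_scores["activity"])

    shuffled_aucs = []
    for s in range(N_SHUFFLE_SEEDS):
        rng = np.random.default_rng(1000 + s)
        labels = train.groups.to_numpy().copy()
        rng.shuffle(labels)
        shuffled = train_nn(
            type(train)(values=train.values,
                        groups=pd.Series(labels, index=train.groups.index)),
            NetSpec(seed=1000 + s),
        )
        sf = scores_frame(score(shuffled, val))
        shuffled_aucs.append(roc_auc(sf["score"], sf["group"] == CASE))

    metrics = {
        "n_train": len(train.values),
        "n_val": len(val.values),
        "n_model_regions": len(regions),
        "validation_auc_wgbs": auc_wgbs,
        "validation_auc_array": auc_array,
        "score_activity_spearman": rho,
        "score_activity_p": rho_p,
        "shuffled_auc_mean": float(np.mean(shuffled_aucs)),
    }
    (OUT_DIR / "classifier_metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
    print(json.dumps(metrics, indent=2))


if __name__ == "__main__":
    main()
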