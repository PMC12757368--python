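"""End-to-end composition of the diagnostic pipeline on a simulated study.

The sequence mirrors the full analysis: consensus DEGs from the expression
cohorts and consensus DMPs/DMGs from the array cohorts; DMP/DMR calling on
the WGBS parents; the cross-platform screen for model regions; subsample
augmentation (7x controls / 20x cases) of the WGBS samples into the
training pool; a stratified 0.6666 split; the three-hidden-layer network;
and validation both on held-out WGBS sub-samples and on an independent
array cohort projected through the same regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import CASE
from .synthetic_data import SimulatedStudy, StudyConfig, simulate_multiomics_study
from .diff_consensus import (
    consensus_features,
    map_probes_to_genes,
    moderated_t_test,
    select_degs,
    select_dmps,
)
from .wgbs_dmr import augment_subsamples, bb_wald_test, call_dmps, call_dmrs
from .feature_integration import (
    build_feature_matrix_wgbs,
    project_features_array,
    screen_model_regions,
)
from .classifier import (
    NetSpec,
    roc_auc,
    score,
    scores_frame,
    spearman,
    split_train_val,
    train_nn,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces, for reporting and testing."""

    deg_genes: set
    dmg_genes: set
    model_regions: list
    validation_auc_wgbs: float
    validation_auc_array: float
    score_activity_spearman: float
    score_activity_p: float
    val_scores: pd.DataFrame
    array_scores: pd.DataFrame
    n_train: int
    n_val: int
    truth_genes: frozenset = frozenset()


def consensus_deg_genes(expr_datasets, min_datasets: int = 3) -> set:
    """Consensus differentially expressed genes across expression cohorts."""
    selections = []
    for expr in expr_datasets:
        stats = moderated_t_test(expr)
        selections.append(select_degs(stats))
    return consensus_features(selections, min_datasets=min_datasets).selected


def consensus_dmg_genes(beta_datasets, annotation, min_datasets: int = 3) -> set:
    """Consensus differentially methylated probes, mapped to genes (DMGs)."""
    selections = []
    for beta in beta_datasets:
        stats = moderated_t_test(beta)
        selections.append(select_dmps(stats))
    probes = consensus_features(selections, min_datasets=min_datasets).selected
    return map_probes_to_genes(probes, annotation)


def run_cflmd(
    study: SimulatedStudy,
    seed: int = 0,
    min_datasets: int = 3,
    reps_control: int = 7,
    reps_case: int = 20,
    thin_fraction: float = 0.5,
    split_fraction: float = 0.6666,
    net_spec: Optional[NetSpec] = None,
    shuffle_labels: bool = False,
) -> PipelineResult:
    """Run the whole screen -> augment -> train -> validate pipeline.

    ``shuffle_labels`` permutes the training labels (permutation control:
    validation AUC should collapse to ~0.5).
    """
    rng = np.random.default_rng(seed)

    deg = consensus_deg_genes(study.expr_datasets, min_datasets=min_datasets)
    dmg = consensus_dmg_genes(study.beta_datasets, study.annotation, min_datasets=min_datasets)

    records = bb_wald_test(
        [t for t in study.wgbs_tables if t.group == CASE],
        [t for t in study.wgbs_tables if t.group != CASE],
    )
    dmrs = call_dmrs(call_dmps(records))
    regions = screen_model_regions(deg, dmg, dmrs, study.annotation)
    if not regions:
        raise RuntimeError("no model regions survived the screen")

    # regions with no covering array probes are dropped from BOTH the WGBS
    # training matrix and the array validation projection, keeping the
    # feature spaces aligned
    arr_fm = project_features_array(regions, study.validation_beta, study.annotation)
    regions = [r for r in regions if r.region_id in set(arr_fm.region_ids)]
    if not regions:
        raise RuntimeError("no model region is covered by array probes")

    subs = augment_subsamples(
        study.wgbs_tables,
        reps_control=reps_control,
        reps_case=reps_case,
        thin_fraction=thin_fraction,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    fm = build_feature_matrix_wgbs(regions, subs)
    train, val = split_train_val(
        fm, fraction=split_fraction, seed=int(rng.integers(0, 2**31 - 1))
    )
    if shuffle_labels:
        shuffled = train.groups.to_numpy().copy()
        rng.shuffle(shuffled)
        train.groups = pd.Series(shuffled, index=train.groups.index)

    spec = net_spec or NetSpec(seed=int(rng.integers(0, 2**31 - 1)))
    model = train_nn(train, spec)

    val_scores = scores_frame(score(model, val))
    auc_wgbs = roc_auc(val_scores["score"], val_scores["group"] == CASE)

    array_scores = scores_frame(score(model, arr_fm))
    auc_array = roc_auc(array_scores["score"], array_scores["group"] == CASE)

    # activity correlation on the independent array cohort: its samples are
    # distinct patients with per-sample activity, unlike the augmented WGBS
    # sub-samples which replicate only the few parents' activity values
    act = array_scores["activity"]
    if act.notna().all():
        rho, rho_p = spearman(array_scores["score"], act)
    else:
        rho, rho_p = float("nan"), float("nan")

    return PipelineResult(
        deg_genes=deg,
        dmg_genes=dmg,
        model_regions=regions,
        validation_auc_wgbs=auc_wgbs,
        validation_auc_array=auc_array,
        score_activity_spearman=rho,
        score_activity_p=rho_p,
        val_scores=val_scores,
        array_scores=array_scores,
        n_train=len(train.values),
        n_val=len(val.values),
        truth_genes=study.truth.true_genes,
    )


def run_cflmd_from_config(cfg: StudyConfig, seed: Optional[int] = None, **kwargs) -> PipelineResult:
    """Simulate a study under ``cfg`` and run the pipeline on it."""
    study = simulate_multiomics_study(cfg)
    return run_cflmd(study, seed=cfg.seed if seed is None else seed, **kwargs)
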