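"""Cross-platform model-region screening and feature-matrix construction.

The model's features are WGBS DMRs that survive a two-way screen: (i) genes
called differentially expressed (consensus DEGs) *and* differentially
methylated on the array side (consensus DMGs) define the disease-specific
gene set; (ii) DMRs overlapping those genes' loci become the model regions.
Gene loci are taken as the span of the gene's annotated array probes padded
by ``padding_bp`` (default 2 kb) — this uses only inputs the pipeline
already has and needs no external gene model.

For modelling, each sample is summarised per region:

* WGBS samples: the coverage-weighted pooled ratio
  ``sum(n_meth) / sum(n_total)`` over CpGs inside the region (a region with
  zero coverage in a sample is missing and then mean-imputed within group);
* array samples: the unweighted mean beta of probes located inside the
  region (regions covering no probes are dropped, and must be dropped from
  every matrix that feeds the same model to keep feature spaces aligned).

Interval overlap uses 0-based half-open semantics throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import BetaMatrix, GenomicInterval, ProbeAnnotation
from .wgbs_dmr import DMRRecord

log = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Samples x model-region mean-methylation values.

    ``values`` is indexed by sample id with one column per region id
    (``chrom:start-end``); ``groups``/``activity`` carry per-sample labels.
    """

    values: pd.DataFrame
    groups: Optional[pd.Series] = None
    activity: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if pd.Index(self.values.columns).has_duplicates:
            raise ValueError("duplicate region ids")
        vals = self.values.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            raise ValueError("feature values must lie in [0,1] or be missing")
        if self.groups is not None:
            self.groups = pd.Series(self.groups).reindex(self.values.index)
        if self.activity is not None:
            self.activity = pd.Series(self.activity, dtype=float).reindex(
                self.values.index
            )

    @property
    def region_ids(self) -> list:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)


# ---------------------------------------------------------------------------
# interval machinery
# ---------------------------------------------------------------------------

def intersect_intervals(a, b) -> list:
    """All overlapping pairs between two interval lists (>= 1 bp overlap).

    Inputs are :class:`GenomicInterval` lists (0-based half-open).  Returns
    ``(a_index, b_index)`` pairs sorted lexicographically.
    """
    trees: dict = {}
    for j, iv in enumerate(b):
        iv.validate()
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    pairs = []
    for i, iv in enumerate(a):
        iv.validate()
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            pairs.append((i, hit.data))
    pairs.sort()
    return pairs


def _dmr_interval(d: DMRRecord, payload=None) -> GenomicInterval:
    # internal 1-based inclusive -> 0-based half-open
    return GenomicInterval(chrom=d.chrom, start=d.start - 1, end=d.end, payload=payload)


def gene_loci(genes, ann: ProbeAnnotation, padding_bp: int = 2000) -> list:
    """Probe-span intervals (padded) for each gene present in the annotation."""
    ent = ann.entries[ann.entries["gene"].isin(set(genes))]
    out = []
    for gene, sub in ent.groupby("gene", sort=True):
        for chrom, subc in sub.groupby("chrom", sort=True):
            lo = int(subc["pos"].min()) - 1 - padding_bp
            hi = int(subc["pos"].max()) + padding_bp
            out.append(GenomicInterval(chrom=chrom, start=max(lo, 0), end=hi, payload=gene))
    return out


def screen_model_regions(
    deg_genes, dmg_genes, dmrs, ann: ProbeAnnotation, padding_bp: int = 2000
) -> list:
    """DMRs overlapping loci of genes that are both DEGs and DMGs.

    Returns the retained :class:`DMRRecord` list sorted by (chrom, start);
    empty (with a warning) when the gene intersection is empty.
    """
    selected_genes = set(deg_genes) & set(dmg_genes)
    if not selected_genes:
        log.warning("DEG/DMG gene intersection is empty; no model regions")
        return []
    loci = gene_loci(selected_genes, ann, padding_bp=padding_bp)
    dmr_ivs = [_dmr_interval(d) for d in dmrs]
    hits = {i for i, _ in intersect_intervals(dmr_ivs, loci)}
    kept = [dmrs[i] for i in sorted(hits)]
    kept.sort(key=lambda d: (d.chrom, d.start))
    return kept


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

def build_feature_matrix_wgbs(regions, tables, impute_within_group: bool = True) -> FeatureMatrix:
    """Region-level pooled methylation per WGBS sample.

    Cell value = ``sum(n_meth) / sum(n_total)`` over CpGs with 1-based
    position inside the region.  Regions without coverage in a sample are
    missing and, when ``impute_within_group``, replaced by the group mean of
    that region (left missing if the whole group lacks coverage).
    """
    region_ids = [r.region_id for r in regions]
    rows, sample_ids, groups, activity = [], [], [], []
    for t in tables:
        rec = t.records
        vals = []
        for r in regions:
            sel = (rec["chrom"] == r.chrom) & (rec["pos"] >= r.start) & (rec["pos"] <= r.end)
            tot = int(rec.loc[sel, "n_total"].sum())
            vals.append(rec.loc[sel, "n_meth"].sum() / tot if tot > 0 else np.nan)
        rows.append(vals)
        sample_ids.append(t.sample_id)
        groups.append(t.group)
        activity.append(t.activity if t.activity is not None else np.nan)
    values = pd.DataFrame(rows, index=sample_ids, columns=region_ids)
    groups = pd.Series(groups, index=sample_ids)
    act = pd.Series(activity, index=sample_ids, dtype=float)
    if values.isna().any().any() and impute_within_group:
        for g in groups.unique():
            sel = groups == g
            values.loc[sel] = values.loc[sel].fillna(values.loc[sel].mean())
    return FeatureMatrix(values=values, groups=groups, activity=act)


def project_features_array(regions, beta: BetaMatrix, ann: ProbeAnnotation) -> FeatureMatrix:
    """Project model regions onto an array cohort.

    Cell value = unweighted mean beta of probes whose annotated position
    falls inside the region (1-based inclusive).  Regions covering no probe
    are dropped from the output (logged); callers training on multiple
    matrices must drop those regions everywhere to keep features aligned.
    """
    ent = ann.entries
    cols, kept_ids, dropped = [], [], []
    for r in regions:
        sel = (ent["chrom"] == r.chrom) & (ent["pos"] >= r.start) & (ent["pos"] <= r.end)
        probes = ent.index[sel].intersection(beta.values.index)
        if len(probes) == 0:
            dropped.append(r.region_id)
            continue
        cols.append(beta.values.loc[probes].mean(axis=0))
        kept_ids.append(r.region_id)
    if dropped:
        log.info("%d region(s) without covering probes dropped: %s",
                 len(dropped), dropped[:5])
    values = (
        pd.concat(cols, axis=1, keys=kept_ids)
        if cols
        else pd.DataFrame(index=beta.values.columns)
    )
    return FeatureMatrix(
        values=values,
        groups=None if beta.groups is None else beta.groups.copy(),
        activity=None if beta.activity is None else beta.activity.copy(),
    )


def align_feature_spaces(*matrices) -> list:
    """Restrict several feature matrices to their common region set (in order)."""
    common = [r for r in matrices[0].region_ids if all(r in m.region_ids for m in matrices)]
    return [
        FeatureMatrix(values=m.values[common], groups=m.groups, activity=m.activity)
        for m in matrices
    ]


# ---------------------------------------------------------------------------
# annotation summaries
# ---------------------------------------------------------------------------

def annotate_dmr_context(dmrs, ann: ProbeAnnotation, tss_table: pd.DataFrame) -> pd.DataFrame:
    """Per-DMR distance to nearest TSS and probe region-class tally.

    ``tss_table`` needs columns ``chrom`` and ``pos`` (1-based TSS).  The
    distance is 0 when a TSS lies inside the region, otherwise the gap to
    the nearest region edge.  The region class is the majority class of the
    probes inside the region (``intergenic`` when none).  Also flags whether
    the DMR is within 200 kb of a TSS.
    """
    if tss_table is None or len(tss_table) == 0:
        raise ValueError("empty TSS table")
    ent = ann.entries
    rows = []
    for d in dmrs:
        tss = tss_table.loc[tss_table["chrom"] == d.chrom, "pos"].to_numpy()
        if len(tss) == 0:
            dist = np.inf
        else:
            dist = int(
                np.min(np.where(tss < d.start, d.start - tss,
                                np.where(tss > d.end, tss - d.end, 0)))
            )
        sel = (ent["chrom"] == d.chrom) & (ent["pos"] >= d.start) & (ent["pos"] <= d.end)
        classes = ent.loc[sel, "region_class"]
        region_class = classes.mode().iloc[0] if len(classes) else "intergenic"
        rows.append(
            {
                "region_id": d.region_id,
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "direction": d.direction,
                "tss_distance": dist,
                "within_200kb_tss": dist <= 200_000,
                "region_class": region_class,
            }
        )
    return pd.DataFrame(rows)
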