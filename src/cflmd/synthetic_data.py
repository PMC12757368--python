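"""Synthetic cohorts with planted differential-methylation signal.

Everything downstream of the readers is exercised against data generated
here, with known ground truth: which probes/regions truly differ between
case and control, what the mixture proportions of a deconvolution input
were, and how a SLEDAI-like disease-activity score couples to the planted
signal.

Three generators cover the pipeline's input classes:

* :func:`simulate_array_cohort` — HM450-style beta matrices (Beta-distributed
  around group means, so values stay on [0,1] without clipping artifacts)
  with a paired log-scale expression matrix in which truly hypomethylated
  genes are up-regulated and truly hypermethylated genes down-regulated.
* :func:`simulate_wgbs_cohort` — per-CpG binomial count tables on synthetic
  chromosomes, with planted differentially methylated regions as runs of
  consecutive CpGs whose methylation probability is shifted in cases.
* :func:`simulate_mixtures` — noisy linear mixtures of a cell-type
  methylation signature with known proportions, for deconvolution recovery.

:func:`simulate_multiomics_study` ties the three platforms to one shared
gene layout so the full screening pipeline (consensus DEGs/DMGs -> WGBS DMRs
-> model regions -> classifier) can be run end to end against truth.

The defaults are hypo-methylation dominant (more planted hypo- than
hyper-methylated features), mirroring the global hypomethylation typically
seen in lupus methylomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CASE,
    CONTROL,
    BetaMatrix,
    CpGCountTable,
    ExprMatrix,
    GenomicInterval,
    ProbeAnnotation,
    SignatureMatrix,
)

log = logging.getLogger(__name__)

HYPO = "hypo"
HYPER = "hyper"


@dataclass
class SimConfig:
    """Knobs for a single simulated cohort.

    effect_size is the planted case-minus-control shift of the methylation
    fraction (hypo features shift down, hyper features up).  Array beta
    values are drawn Beta-reparameterized around the group mean with
    ``precision`` pseudo-observations; WGBS per-sample methylation
    probabilities get a milder Beta jitter (``wgbs_precision``) before
    binomial read sampling at Poisson(``depth_mean``) coverage.

    The activity score emulates SLEDAI: ``activity_baseline`` plus
    ``activity_slope`` times the sample's mean planted-feature deviation in
    the case direction, plus Gaussian noise — so a positive slope yields a
    known positive score/activity association for downstream checks.
    """

    seed: int = 0
    n_control: int = 20
    n_case: int = 20
    n_probes: int = 300
    n_cpgs: int = 500
    n_true_hypo: int = 25
    n_true_hyper: int = 15
    effect_size: float = 0.3
    baseline_alpha: float = 2.0
    baseline_beta: float = 2.0
    precision: float = 30.0
    wgbs_precision: float = 100.0
    depth_mean: float = 30.0
    dmr_width_cpgs: int = 8
    activity_slope: float = 30.0
    activity_baseline: float = 2.0
    activity_noise_sd: float = 1.0
    expr_effect_size: Optional[float] = None  # default: 4 x effect_size (log2)
    expr_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size < 1.0:
            raise ValueError("effect_size must lie in [0, 1)")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if self.n_true_hypo + self.n_true_hyper > self.n_probes:
            raise ValueError("more planted features than probes")
        if self.dmr_width_cpgs < 1:
            raise ValueError("dmr_width_cpgs must be >= 1")
        if self.expr_effect_size is None:
            self.expr_effect_size = 4.0 * self.effect_size

    @property
    def expr_shift(self) -> float:
        return float(self.expr_effect_size)


@dataclass
class TruthSet:
    """Ground truth emitted alongside simulated data."""

    true_hypo_ids: frozenset = frozenset()
    true_hyper_ids: frozenset = frozenset()
    true_dmr_intervals: list = field(default_factory=list)
    true_mix_proportions: Optional[pd.DataFrame] = None
    activity: Optional[pd.Series] = None
    true_hypo_genes: frozenset = frozenset()
    true_hyper_genes: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.true_hypo_ids & self.true_hyper_ids:
            raise ValueError("hypo and hyper truth sets overlap")

    @property
    def true_dmp_ids(self) -> frozenset:
        return self.true_hypo_ids | self.true_hyper_ids

    @property
    def true_genes(self) -> frozenset:
        return self.true_hypo_genes | self.true_hyper_genes


# ---------------------------------------------------------------------------
# low-level draws
# ---------------------------------------------------------------------------

def _feasible_baselines(rng, n, alpha, beta, delta, lo=0.02, hi=0.98, max_iter=200):
    """Beta(alpha, beta) baselines conditioned on mu +/- delta staying in [lo, hi].

    A planted shift of size delta can only exist where the unit interval
    allows it; rejection sampling keeps the baseline distribution shape
    while guaranteeing feasibility.  Falls back to clipping (with a count)
    if the acceptance region is essentially empty.
    """
    if n == 0:
        return np.empty(0), 0
    mu = rng.beta(alpha, beta, size=n)
    bad = (mu - delta < lo) | (mu + delta > hi)
    it = 0
    while bad.any() and it < max_iter:
        mu[bad] = rng.beta(alpha, beta, size=int(bad.sum()))
        bad = (mu - delta < lo) | (mu + delta > hi)
        it += 1
    n_clipped = int(bad.sum())
    if n_clipped:
        mu[bad] = np.clip(mu[bad], lo + delta, hi - delta)
        if n_clipped > 0.1 * n:
            log.warning(
                "planted shift %.3g infeasible for %d/%d features; clipped",
                delta, n_clipped, n,
            )
    return mu, n_clipped


def _beta_around(rng, mean, precision, size=None):
    """Beta draw reparameterized by (mean, precision); degenerate means pass through."""
    mean = np.clip(mean, 1e-6, 1 - 1e-6)
    return rng.beta(mean * precision, (1.0 - mean) * precision, size=size)


def _activity(rng, deviation, cfg: SimConfig) -> np.ndarray:
    act = (
        cfg.activity_baseline
        + cfg.activity_slope * deviation
        + rng.normal(0.0, cfg.activity_noise_sd, size=deviation.shape)
    )
    return np.clip(act, 0.0, None)


# ---------------------------------------------------------------------------
# array + expression cohort
# ---------------------------------------------------------------------------

def simulate_array_cohort(
    cfg: SimConfig, gene_of_probe: Optional[dict] = None
):
    """Simulate a case/control HM450-style cohort plus paired expression.

    Returns ``(BetaMatrix, ExprMatrix, TruthSet)``.  Probe ids are
    ``cg<i>``; by default each probe maps 1:1 to gene ``G<i>`` (pass
    ``gene_of_probe`` to override).  Hypo-planted genes receive a positive
    expression shift in cases, hyper-planted genes a negative one.
    Deterministic under ``cfg.seed``.
    """
    if cfg.n_case < 1 or cfg.n_control < 1:
        raise ValueError("need at least one case and one control sample")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_probes
    probe_ids = [f"cg{i:06d}" for i in range(n)]
    if gene_of_probe is None:
        gene_of_probe = {p: f"G{i:05d}" for i, p in enumerate(probe_ids)}

    order = rng.permutation(n)
    hypo_idx = order[: cfg.n_true_hypo]
    hyper_idx = order[cfg.n_true_hypo : cfg.n_true_hypo + cfg.n_true_hyper]
    planted = np.zeros(n, dtype=bool)
    planted[hypo_idx] = True
    planted[hyper_idx] = True

    mu = rng.beta(cfg.baseline_alpha, cfg.baseline_beta, size=n)
    mu_planted, _ = _feasible_baselines(
        rng, int(planted.sum()), cfg.baseline_alpha, cfg.baseline_beta, cfg.effect_size
    )
    mu[planted] = mu_planted

    case_mu = mu.copy()
    case_mu[hypo_idx] = np.clip(case_mu[hypo_idx] - cfg.effect_size, 0.01, 0.99)
    case_mu[hyper_idx] = np.clip(case_mu[hyper_idx] + cfg.effect_size, 0.01, 0.99)

    controls = [f"ctrl{j:03d}" for j in range(cfg.n_control)]
    cases = [f"case{j:03d}" for j in range(cfg.n_case)]
    beta_ctrl = _beta_around(rng, mu[:, None], cfg.precision, size=(n, cfg.n_control))
    beta_case = _beta_around(rng, case_mu[:, None], cfg.precision, size=(n, cfg.n_case))
    values = pd.DataFrame(
        np.hstack([beta_ctrl, beta_case]), index=probe_ids, columns=controls + cases
    )
    groups = pd.Series(
        [CONTROL] * cfg.n_control + [CASE] * cfg.n_case, index=values.columns
    )

    # activity couples to the realized planted-signal deviation per sample
    sign = np.zeros(n)
    sign[hypo_idx] = -1.0
    sign[hyper_idx] = 1.0
    if planted.any():
        dev = (sign[planted, None] * (values.to_numpy()[planted] - mu[planted, None])).mean(
            axis=0
        )
    else:
        dev = np.zeros(values.shape[1])
    activity = pd.Series(_activity(rng, dev, cfg), index=values.columns)

    beta = BetaMatrix(values=values, groups=groups, activity=activity)

    # paired expression: one value per distinct gene
    genes = sorted(set(gene_of_probe.values()))
    gene_index = {g: i for i, g in enumerate(genes)}
    base_expr = rng.normal(6.0, 1.5, size=len(genes))
    shift = np.zeros(len(genes))
    for i in hypo_idx:
        shift[gene_index[gene_of_probe[probe_ids[i]]]] = cfg.expr_shift
    for i in hyper_idx:
        shift[gene_index[gene_of_probe[probe_ids[i]]]] = -cfg.expr_shift
    e_ctrl = rng.normal(base_expr[:, None], cfg.expr_noise_sd, size=(len(genes), cfg.n_control))
    e_case = rng.normal(
        (base_expr + shift)[:, None], cfg.expr_noise_sd, size=(len(genes), cfg.n_case)
    )
    expr = ExprMatrix(
        values=pd.DataFrame(
            np.hstack([e_ctrl, e_case]), index=genes, columns=controls + cases
        ),
        groups=groups.copy(),
    )

    truth = TruthSet(
        true_hypo_ids=frozenset(probe_ids[i] for i in hypo_idx),
        true_hyper_ids=frozenset(probe_ids[i] for i in hyper_idx),
        activity=activity,
        true_hypo_genes=frozenset(gene_of_probe[probe_ids[i]] for i in hypo_idx),
        true_hyper_genes=frozenset(gene_of_probe[probe_ids[i]] for i in hyper_idx),
    )
    return beta, expr, truth


# ---------------------------------------------------------------------------
# WGBS cohort
# ---------------------------------------------------------------------------

def _layout_positions(rng, cfg: SimConfig):
    """Lay CpGs on up to 3 chromosomes: isolated blocks + background runs.

    Planted DMRs occupy whole blocks of ``dmr_width_cpgs`` consecutive CpGs
    (intra-block spacing ~50 bp).  Blocks are separated from background CpGs
    by >=400 bp so that window smoothing never mixes block and background
    sites.  An equal number of unplanted blocks keeps block structure from
    being a giveaway.  Background CpGs have geometric inter-CpG gaps
    (mean ~100 bp).
    """
    n_blocks = 2 * (cfg.n_true_hypo + cfg.n_true_hyper)
    n_bg = cfg.n_cpgs
    bg_per_gap = max(1, n_bg // max(n_blocks + 1, 1)) if n_blocks else n_bg

    chroms, positions, block_ranges = [], [], []
    chrom_names = ["chr1", "chr2", "chr3"]
    per_chrom = max(1, (n_blocks + len(chrom_names) - 1) // len(chrom_names))

    def emit_background(chrom, pos, count):
        for _ in range(count):
            pos += int(rng.geometric(1.0 / 100.0))
            chroms.append(chrom)
            positions.append(pos)
        return pos

    block_i = 0
    for ci, chrom in enumerate(chrom_names):
        pos = 1000
        blocks_here = min(per_chrom, n_blocks - block_i) if n_blocks else 0
        if n_blocks == 0 and ci == 0:
            emit_background(chrom, pos, n_bg)
        for _ in range(blocks_here):
            pos = emit_background(chrom, pos, bg_per_gap)
            pos += 400 + int(rng.geometric(1.0 / 50.0))  # margin before block
            start_idx = len(positions)
            for k in range(cfg.dmr_width_cpgs):
                if k:
                    pos += int(rng.integers(30, 71))
                chroms.append(chrom)
                positions.append(pos)
            block_ranges.append((start_idx, len(positions)))
            pos += 400 + int(rng.geometric(1.0 / 50.0))  # margin after block
            block_i += 1
        if blocks_here:
            emit_background(chrom, pos, bg_per_gap)
        if block_i >= n_blocks:
            break
    return np.array(chroms), np.array(positions, dtype=np.int64), block_ranges


def simulate_wgbs_cohort(cfg: SimConfig):
    """Simulate case/control WGBS count tables with planted DMRs.

    Returns ``(list of CpGCountTable, TruthSet)``.  Per-site coverage is
    Poisson(``depth_mean``) (floored at 1); methylated counts are binomial
    with a per-sample Beta-jittered success probability.  Planted DMRs are
    runs of ``dmr_width_cpgs`` consecutive CpGs whose probability is shifted
    by ``effect_size`` in cases.  Deterministic under ``cfg.seed``.
    """
    if cfg.n_case < 1 or cfg.n_control < 1:
        raise ValueError("need at least one case and one control sample")
    rng = np.random.default_rng(cfg.seed)
    chroms, positions, block_ranges = _layout_positions(rng, cfg)
    n_sites = len(positions)

    pi = rng.beta(cfg.baseline_alpha, cfg.baseline_beta, size=n_sites)
    n_planted = cfg.n_true_hypo + cfg.n_true_hyper
    planted_blocks = list(rng.choice(len(block_ranges), size=n_planted, replace=False)) if n_planted else []
    directions = [HYPO] * cfg.n_true_hypo + [HYPER] * cfg.n_true_hyper

    case_pi = pi.copy()
    truth_intervals = []
    block_mu, _ = _feasible_baselines(
        rng, n_planted, cfg.baseline_alpha, cfg.baseline_beta, cfg.effect_size
    )
    site_sign = np.zeros(n_sites)
    for b, direction, mu_b in zip(planted_blocks, directions, block_mu):
        lo_i, hi_i = block_ranges[b]
        jitter = rng.normal(0.0, 0.03, size=hi_i - lo_i)
        base = np.clip(mu_b + jitter, 0.02 + cfg.effect_size, 0.98 - cfg.effect_size)
        pi[lo_i:hi_i] = base
        s = -1.0 if direction == HYPO else 1.0
        case_pi[lo_i:hi_i] = np.clip(base + s * cfg.effect_size, 0.01, 0.99)
        site_sign[lo_i:hi_i] = s
        truth_intervals.append(
            GenomicInterval(
                chrom=str(chroms[lo_i]),
                start=int(positions[lo_i]) - 1,
                end=int(positions[hi_i - 1]),
                payload=direction,
            )
        )

    tables, deviations, ids, grps = [], [], [], []
    planted_mask = site_sign != 0
    for group, count in ((CONTROL, cfg.n_control), (CASE, cfg.n_case)):
        target = pi if group == CONTROL else case_pi
        for j in range(count):
            p_s = _beta_around(rng, target, cfg.wgbs_precision)
            depth = np.maximum(1, rng.poisson(cfg.depth_mean, size=n_sites))
            meth = rng.binomial(depth, p_s)
            sid = f"{'ctrl' if group == CONTROL else 'case'}{j:03d}"
            tables.append(
                CpGCountTable(
                    records=pd.DataFrame(
                        {"chrom": chroms, "pos": positions, "n_total": depth, "n_meth": meth}
                    ),
                    sample_id=sid,
                    group=group,
                )
            )
            frac = meth / depth
            dev = (
                float((site_sign[planted_mask] * (frac - pi)[planted_mask]).mean())
                if planted_mask.any()
                else 0.0
            )
            deviations.append(dev)
            ids.append(sid)
            grps.append(group)

    activity = pd.Series(_activity(rng, np.array(deviations), cfg), index=ids)
    for t in tables:
        t.activity = float(activity[t.sample_id])

    hypo_ids, hyper_ids = set(), set()
    for iv in truth_intervals:
        tgt = hypo_ids if iv.payload == HYPO else hyper_ids
        sel = (chroms == iv.chrom) & (positions >= iv.start + 1) & (positions <= iv.end)
        for c, p in zip(chroms[sel], positions[sel]):
            tgt.add(f"{c}:{p}")

    truth = TruthSet(
        true_hypo_ids=frozenset(hypo_ids),
        true_hyper_ids=frozenset(hyper_ids),
        true_dmr_intervals=truth_intervals,
        activity=activity,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# deconvolution mixtures
# ---------------------------------------------------------------------------

def make_signature(
    n_markers: int = 100,
    cell_types: Sequence[str] = ("Tcell", "Bcell", "NK", "Monocyte", "Neutrophil"),
    seed: int = 0,
) -> SignatureMatrix:
    """A synthetic full-rank cell-type methylation signature.

    Each cell type gets an independent Beta(0.5, 0.5) profile (U-shaped, like
    real CpG methylation), which is full column rank with overwhelming
    probability; rank is asserted.
    """
    rng = np.random.default_rng(seed)
    vals = rng.beta(0.5, 0.5, size=(n_markers, len(cell_types)))
    sig = SignatureMatrix(
        values=pd.DataFrame(
            vals,
            index=[f"mk{i:05d}" for i in range(n_markers)],
            columns=list(cell_types),
        )
    )
    if np.linalg.matrix_rank(vals) < len(cell_types):
        raise RuntimeError("synthetic signature is rank deficient; change seed")
    return sig


def simulate_mixtures(
    sig: SignatureMatrix, proportions, noise_sd: float = 0.0, seed: int = 0
) -> BetaMatrix:
    """Linear mixtures of signature columns with known proportions.

    ``proportions`` is samples x cell-types (DataFrame or array); every row
    must lie on the simplex.  Observed values are
    ``signature . proportions^T`` plus Gaussian noise, clipped to [0, 1].
    """
    if isinstance(proportions, pd.DataFrame):
        P = proportions.loc[:, sig.cell_types].to_numpy(dtype=float)
        sample_ids = list(proportions.index)
    else:
        P = np.asarray(proportions, dtype=float)
        sample_ids = [f"mix{i:03d}" for i in range(P.shape[0])]
    if P.ndim != 2 or P.shape[1] != len(sig.cell_types):
        raise ValueError("proportions must be samples x cell-types")
    if (P < -1e-12).any() or np.abs(P.sum(axis=1) - 1.0).max() > 1e-8:
        raise ValueError("each proportion row must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    clean = sig.values.to_numpy() @ P.T
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
    return BetaMatrix(
        values=pd.DataFrame(
            np.clip(noisy, 0.0, 1.0), index=sig.marker_ids, columns=sample_ids
        )
    )


# ---------------------------------------------------------------------------
# coordinated multi-platform study
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Layout and sizes for the coordinated multi-platform simulation.

    One shared gene map underlies everything: each gene owns a run of
    ``cpgs_per_gene`` CpGs (the WGBS side; planted genes become true DMRs)
    and ``probes_per_gene`` HM450 probes placed exactly on a subset of those
    CpG positions (the array side), so array and WGBS features for the same
    gene measure the same methylation state.
    """

    seed: int = 0
    n_genes: int = 60
    n_true_hypo: int = 10
    n_true_hyper: int = 6
    effect_size: float = 0.3
    cpgs_per_gene: int = 8
    probes_per_gene: int = 3
    n_array_datasets: int = 3
    n_expr_datasets: int = 3
    array_n_control: int = 20
    array_n_case: int = 20
    wgbs_n_control: int = 3
    wgbs_n_case: int = 3
    depth_mean: float = 30.0
    precision: float = 30.0
    wgbs_precision: float = 100.0
    activity_slope: float = 30.0
    gene_spacing_bp: int = 6000
    n_genes_per_chrom: int = 30

    def __post_init__(self) -> None:
        if self.n_true_hypo + self.n_true_hyper > self.n_genes:
            raise ValueError("more planted genes than genes")
        if self.probes_per_gene > self.cpgs_per_gene:
            raise ValueError("probes_per_gene cannot exceed cpgs_per_gene")


@dataclass
class SimulatedStudy:
    beta_datasets: list
    expr_datasets: list
    validation_beta: BetaMatrix
    wgbs_tables: list
    annotation: ProbeAnnotation
    tss_table: pd.DataFrame
    truth: TruthSet


def simulate_multiomics_study(cfg: StudyConfig) -> SimulatedStudy:
    """Simulate the whole study: arrays, transcriptomes, WGBS, annotation.

    Planted genes carry concordant signal on every platform: shifted beta
    values on their probes, shifted expression, and a true DMR over their
    CpG run.  The returned probe annotation and TSS table tie the platforms
    together for screening and context annotation.
    """
    rng = np.random.default_rng(cfg.seed)

    # --- shared genome / gene layout -------------------------------------
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    gene_chrom, gene_tss, gene_cpg_pos = {}, {}, {}
    for i, g in enumerate(genes):
        chrom = f"chr{i // cfg.n_genes_per_chrom + 1}"
        tss = 5000 + (i % cfg.n_genes_per_chrom) * cfg.gene_spacing_bp
        offsets = np.cumsum(np.r_[0, rng.integers(30, 71, size=cfg.cpgs_per_gene - 1)])
        gene_chrom[g], gene_tss[g] = chrom, tss
        gene_cpg_pos[g] = tss + offsets

    probe_rows, gene_of_probe = [], {}
    classes = ["promoter", "body", "body"]
    for g in genes:
        picks = np.linspace(0, cfg.cpgs_per_gene - 1, cfg.probes_per_gene).round().astype(int)
        for j, k in enumerate(np.unique(picks)):
            pid = f"cg_{g}_{j}"
            probe_rows.append(
                {
                    "probe_id": pid,
                    "chrom": gene_chrom[g],
                    "pos": int(gene_cpg_pos[g][k]),
                    "gene": g,
                    "region_class": classes[j % len(classes)],
                }
            )
            gene_of_probe[pid] = g
    annotation = ProbeAnnotation(
        entries=pd.DataFrame(probe_rows).set_index("probe_id")
    )
    tss_table = pd.DataFrame(
        {"chrom": [gene_chrom[g] for g in genes], "pos": [gene_tss[g] for g in genes],
         "gene": genes}
    )

    order = rng.permutation(cfg.n_genes)
    hypo_genes = frozenset(genes[i] for i in order[: cfg.n_true_hypo])
    hyper_genes = frozenset(
        genes[i] for i in order[cfg.n_true_hypo : cfg.n_true_hypo + cfg.n_true_hyper]
    )

    # shared per-gene baseline methylation, feasible for the planted shift
    mu_gene = rng.beta(2.0, 2.0, size=cfg.n_genes)
    planted_list = sorted(hypo_genes | hyper_genes)
    mu_planted, _ = _feasible_baselines(rng, len(planted_list), 2.0, 2.0, cfg.effect_size)
    mu_map = dict(zip(genes, mu_gene))
    mu_map.update(dict(zip(planted_list, mu_planted)))
    shift_map = {g: (-cfg.effect_size if g in hypo_genes else cfg.effect_size if g in hyper_genes else 0.0) for g in genes}

    probe_ids = list(annotation.entries.index)
    probe_mu = np.array([mu_map[gene_of_probe[p]] for p in probe_ids])
    probe_shift = np.array([shift_map[gene_of_probe[p]] for p in probe_ids])

    def one_beta_dataset(ds_seed, n_control, n_case, tag):
        r = np.random.default_rng(ds_seed)
        ctrl = _beta_around(r, probe_mu[:, None], cfg.precision, size=(len(probe_ids), n_control))
        case_mu = np.clip(probe_mu + probe_shift, 0.01, 0.99)
        case = _beta_around(r, case_mu[:, None], cfg.precision, size=(len(probe_ids), n_case))
        cols = [f"{tag}_ctrl{j:03d}" for j in range(n_control)] + [
            f"{tag}_case{j:03d}" for j in range(n_case)
        ]
        values = pd.DataFrame(np.hstack([ctrl, case]), index=probe_ids, columns=cols)
        groups = pd.Series([CONTROL] * n_control + [CASE] * n_case, index=cols)
        sign = np.sign(probe_shift)
        mask = sign != 0
        dev = (
            (sign[mask, None] * (values.to_numpy()[mask] - probe_mu[mask, None])).mean(axis=0)
            if mask.any()
            else np.zeros(len(cols))
        )
        scfg = SimConfig(seed=0, effect_size=cfg.effect_size, activity_slope=cfg.activity_slope)
        activity = pd.Series(_activity(r, dev, scfg), index=cols)
        return BetaMatrix(values=values, groups=groups, activity=activity)

    def one_expr_dataset(ds_seed, tag):
        r = np.random.default_rng(ds_seed)
        base = r.normal(6.0, 1.5, size=cfg.n_genes)
        # hypo-methylated genes are up-regulated, hyper-methylated down
        shift = np.array(
            [4.0 * cfg.effect_size if g in hypo_genes else -4.0 * cfg.effect_size if g in hyper_genes else 0.0 for g in genes]
        )
        nc, na = cfg.array_n_control, cfg.array_n_case
        ctrl = r.normal(base[:, None], 0.5, size=(cfg.n_genes, nc))
        case = r.normal((base + shift)[:, None], 0.5, size=(cfg.n_genes, na))
        cols = [f"{tag}_ctrl{j:03d}" for j in range(nc)] + [f"{tag}_case{j:03d}" for j in range(na)]
        return ExprMatrix(
            values=pd.DataFrame(np.hstack([ctrl, case]), index=genes, columns=cols),
            groups=pd.Series([CONTROL] * nc + [CASE] * na, index=cols),
        )

    child = rng.integers(0, 2**31 - 1, size=cfg.n_array_datasets + cfg.n_expr_datasets + 2)
    beta_datasets = [
        one_beta_dataset(child[i], cfg.array_n_control, cfg.array_n_case, f"arr{i}")
        for i in range(cfg.n_array_datasets)
    ]
    expr_datasets = [
        one_expr_dataset(child[cfg.n_array_datasets + i], f"exp{i}")
        for i in range(cfg.n_expr_datasets)
    ]
    validation_beta = one_beta_dataset(
        child[-2], cfg.array_n_control, cfg.array_n_case, "val"
    )

    # --- WGBS side over the same gene CpG runs + intergenic background ----
    wr = np.random.default_rng(int(child[-1]))
    chroms_l, pos_l, pi_l, sign_l = [], [], [], []
    truth_intervals = []
    for g in genes:
        cpg = gene_cpg_pos[g]
        base = np.clip(mu_map[g] + wr.normal(0.0, 0.03, size=len(cpg)), 0.02, 0.98)
        if shift_map[g] != 0.0:
            base = np.clip(base, 0.02 + cfg.effect_size, 0.98 - cfg.effect_size)
            truth_intervals.append(
                GenomicInterval(
                    chrom=gene_chrom[g],
                    start=int(cpg[0]) - 1,
                    end=int(cpg[-1]),
                    payload=HYPO if g in hypo_genes else HYPER,
                )
            )
        chroms_l.extend([gene_chrom[g]] * len(cpg))
        pos_l.extend(cpg.tolist())
        pi_l.extend(base.tolist())
        sign_l.extend([np.sign(shift_map[g])] * len(cpg))
        # a short intergenic background run well clear of the gene block
        bg_start = int(cpg[-1]) + 600
        bg = bg_start + np.cumsum(wr.geometric(1.0 / 100.0, size=5))
        chroms_l.extend([gene_chrom[g]] * len(bg))
        pos_l.extend(bg.tolist())
        pi_l.extend(wr.beta(2.0, 2.0, size=len(bg)).tolist())
        sign_l.extend([0.0] * len(bg))

    chroms_a = np.array(chroms_l)
    pos_a = np.array(pos_l, dtype=np.int64)
    pi_a = np.array(pi_l)
    sign_a = np.array(sign_l)
    case_pi = np.clip(pi_a + sign_a * cfg.effect_size, 0.01, 0.99)

    order_idx = np.lexsort((pos_a, chroms_a))
    chroms_a, pos_a, pi_a, case_pi, sign_a = (
        chroms_a[order_idx], pos_a[order_idx], pi_a[order_idx], case_pi[order_idx], sign_a[order_idx]
    )

    wgbs_tables, dev_list, sids = [], [], []
    planted_mask = sign_a != 0
    for group, count in ((CONTROL, cfg.wgbs_n_control), (CASE, cfg.wgbs_n_case)):
        target = pi_a if group == CONTROL else case_pi
        for j in range(count):
            p_s = _beta_around(wr, target, cfg.wgbs_precision)
            depth = np.maximum(1, wr.poisson(cfg.depth_mean, size=len(pos_a)))
            meth = wr.binomial(depth, p_s)
            sid = f"wgbs_{'ctrl' if group == CONTROL else 'case'}{j}"
            wgbs_tables.append(
                CpGCountTable(
                    records=pd.DataFrame(
                        {"chrom": chroms_a, "pos": pos_a, "n_total": depth, "n_meth": meth}
                    ),
                    sample_id=sid,
                    group=group,
                )
            )
            frac = meth / depth
            dev_list.append(float((sign_a[planted_mask] * (frac - pi_a)[planted_mask]).mean()))
            sids.append(sid)
    scfg = SimConfig(seed=0, effect_size=cfg.effect_size, activity_slope=cfg.activity_slope)
    wgbs_activity = pd.Series(_activity(wr, np.array(dev_list), scfg), index=sids)
    for t in wgbs_tables:
        t.activity = float(wgbs_activity[t.sample_id])

    hypo_probes = frozenset(p for p in probe_ids if gene_of_probe[p] in hypo_genes)
    hyper_probes = frozenset(p for p in probe_ids if gene_of_probe[p] in hyper_genes)
    truth = TruthSet(
        true_hypo_ids=hypo_probes,
        true_hyper_ids=hyper_probes,
        true_dmr_intervals=truth_intervals,
        activity=validation_beta.activity,
        true_hypo_genes=hypo_genes,
        true_hyper_genes=hyper_genes,
    )
    return SimulatedStudy(
        beta_datasets=beta_datasets,
        expr_datasets=expr_datasets,
        validation_beta=validation_beta,
        wgbs_tables=wgbs_tables,
        annotation=annotation,
        tss_table=tss_table,
        truth=truth,
    )
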