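"""WGBS differential methylation: smoothed beta-binomial Wald tests, DMP/DMR
calling with the pipeline's significance and effect thresholds, and the
subsample augmentation scheme.

Model
-----
Methylated read counts at a CpG are modelled beta-binomially: sample ``i`` of
group ``g`` contributes ``x_i ~ BetaBin(n_i, pi_g, phi)`` so that
``Var(x_i/n_i) = pi_g (1 - pi_g) (1 + (n_i - 1) phi) / n_i``.  Group-level
methylation ``pi_g`` is estimated from coverage-weighted smoothed fractions
(moving window, default 500 bp); the per-site dispersion ``phi`` is a
method-of-moments estimate from the raw per-sample fractions, shrunk toward
the chromosome-wide median with ``m = 20`` pseudo-observations
(``phi_shrunk = (m * phi_median + n_samples * phi_hat) / (m + n_samples)``).
The Wald statistic is ``delta / se(delta)`` with a pooled-pi standard error,
so in the single-sample, zero-dispersion limit the test reduces exactly to
the classical pooled two-proportion z test.  P-values are two-sided normal.

Calling thresholds follow the study protocol: DMPs need p < 0.01 and
|delta| > 0.2; DMRs are maximal runs of consecutive same-direction DMPs with
inter-DMP gaps <= 1 kb, at least 6 member DMPs ("more than five"), and a
Stouffer-combined region p < 0.05.  Chromosomes are processed independently.

Subsample augmentation replays the study's bookkeeping — controls resampled
7x, cases 20x (3 + 3 parents -> 21 + 60 sub-samples) — as per-site binomial
thinning of the parent counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import CASE, CONTROL, CpGCountTable

log = logging.getLogger(__name__)

HYPO = "hypo"   # case below control
HYPER = "hyper"  # case above control

#: pseudo-observation weight pulling per-site dispersions to the chromosome median
DISPERSION_SHRINKAGE_M = 20.0

DMP_COLUMNS = ["chrom", "pos", "pi_case", "pi_control", "delta", "wald_stat", "p_value"]


@dataclass
class DMRRecord:
    """A differentially methylated region (1-based inclusive bounds)."""

    chrom: str
    start: int
    end: int
    n_dmps: int
    mean_delta: float
    direction: str
    region_p: float

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def smooth_methylation(table: CpGCountTable, window_bp: float = 500) -> np.ndarray:
    """Per-site smoothed methylation fraction.

    The smoothed value at a CpG is the coverage-weighted mean of raw
    fractions over CpGs of the same chromosome within +/- window_bp/2,
    i.e. the pooled ratio ``sum(n_meth) / sum(n_total)`` over the window.
    ``window_bp=0`` returns raw fractions; an isolated CpG keeps its raw
    fraction.
    """
    rec = table.records
    out = np.empty(len(rec))
    half = window_bp / 2.0
    for chrom, idx in rec.groupby("chrom", sort=False).groups.items():
        pos = rec.loc[idx, "pos"].to_numpy()
        meth = rec.loc[idx, "n_meth"].to_numpy(dtype=float)
        tot = rec.loc[idx, "n_total"].to_numpy(dtype=float)
        cm = np.r_[0.0, np.cumsum(meth)]
        ct = np.r_[0.0, np.cumsum(tot)]
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        wm = cm[hi] - cm[lo]
        wt = ct[hi] - ct[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(wt > 0, wm / wt, np.nan)
        # zero window coverage can only happen at zero-depth sites
        raw = np.where(tot > 0, meth / np.maximum(tot, 1), np.nan)
        out[np.asarray(idx)] = np.where(np.isnan(sm), raw, sm)
    return out


# ---------------------------------------------------------------------------
# site alignment
# ---------------------------------------------------------------------------

def _align(tables):
    """Union of sites across tables -> (site frame, n_meth, n_total arrays).

    Arrays are sites x samples with 0 where a sample lacks coverage.
    """
    keys = pd.concat(
        [t.records[["chrom", "pos"]] for t in tables], ignore_index=True
    ).drop_duplicates().sort_values(["chrom", "pos"], kind="mergesort")
    keys = keys.reset_index(drop=True)
    index = pd.MultiIndex.from_frame(keys)
    n_meth = np.zeros((len(keys), len(tables)))
    n_total = np.zeros_like(n_meth)
    for j, t in enumerate(tables):
        loc = index.get_indexer(pd.MultiIndex.from_frame(t.records[["chrom", "pos"]]))
        n_meth[loc, j] = t.records["n_meth"].to_numpy()
        n_total[loc, j] = t.records["n_total"].to_numpy()
    return keys, n_meth, n_total


def _smoothed_matrix(tables, keys, window_bp):
    """Sites x samples smoothed fractions on the union site set (NaN = no cover)."""
    index = pd.MultiIndex.from_frame(keys)
    out = np.full((len(keys), len(tables)), np.nan)
    for j, t in enumerate(tables):
        sm = smooth_methylation(t, window_bp=window_bp)
        loc = index.get_indexer(pd.MultiIndex.from_frame(t.records[["chrom", "pos"]]))
        out[loc, j] = sm
    return out


def _mom_dispersion(frac, n_total, pooled):
    """Per-site MoM dispersion from raw per-group residuals.

    For each group, residuals of per-sample raw fractions around the group's
    raw pooled ratio estimate ``phi`` via
    ``E[(x/n - pi)^2] = pi(1-pi)(1/n + phi (n-1)/n)``.  Estimates from both
    groups are averaged (covered samples only); clipped to [0, 0.99].
    """
    num = np.zeros(frac.shape[0])
    den = np.zeros(frac.shape[0])
    covered = n_total > 0
    var_unit = pooled * (1.0 - pooled)
    with np.errstate(invalid="ignore", divide="ignore"):
        resid2 = (frac - pooled[:, None]) ** 2
        contrib = resid2 / var_unit[:, None] - 1.0 / n_total
        weight = (n_total - 1.0) / n_total
        good = covered & (n_total > 1) & (var_unit[:, None] > 0)
        num += np.where(good, contrib, 0.0).sum(axis=1)
        den += np.where(good, weight, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    return np.clip(phi, 0.0, 0.99)


def bb_wald_test(
    cases, controls, window_bp: float = 500, shrinkage_m: float = DISPERSION_SHRINKAGE_M
) -> pd.DataFrame:
    """Beta-binomial Wald test per CpG site between case and control WGBS samples.

    Sites are tested only where at least one case and one control sample
    have coverage.  Returns a DataFrame with columns ``chrom, pos, pi_case,
    pi_control, delta, wald_stat, p_value`` sorted by (chrom, pos); empty
    (with a warning) when no common covered sites exist.
    """
    if not cases or not controls:
        raise ValueError("need >= 1 table per group")
    tables = list(controls) + list(cases)
    is_case = np.array([False] * len(controls) + [True] * len(cases))
    keys, n_meth, n_total = _align(tables)
    cov_case = (n_total[:, is_case] > 0).any(axis=1)
    cov_ctrl = (n_total[:, ~is_case] > 0).any(axis=1)
    testable = cov_case & cov_ctrl
    if not testable.any():
        log.warning("no sites covered in both groups")
        return pd.DataFrame(columns=DMP_COLUMNS)

    keys = keys.loc[testable].reset_index(drop=True)
    n_meth, n_total = n_meth[testable], n_total[testable]
    sm = _smoothed_matrix(tables, keys, window_bp)

    with np.errstate(invalid="ignore", divide="ignore"):
        raw_frac = np.where(n_total > 0, n_meth / np.maximum(n_total, 1), np.nan)

    def group_quantities(mask):
        nm, nt, smg = n_meth[:, mask], n_total[:, mask], sm[:, mask]
        # coverage-weighted mean of smoothed fractions
        w = nt.copy()
        w[np.isnan(smg)] = 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = np.nansum(np.where(w > 0, smg * w, 0.0), axis=1) / w.sum(axis=1)
        pooled_raw = nm.sum(axis=1) / np.maximum(nt.sum(axis=1), 1)
        return pi, pooled_raw, nm, nt

    pi_case, pooled_case, nm_case, nt_case = group_quantities(is_case)
    pi_ctrl, pooled_ctrl, nm_ctrl, nt_ctrl = group_quantities(~is_case)

    pooled_all = (nm_case.sum(axis=1) + nm_ctrl.sum(axis=1)) / np.maximum(
        nt_case.sum(axis=1) + nt_ctrl.sum(axis=1), 1
    )
    phi_case = _mom_dispersion(raw_frac[:, is_case], n_total[:, is_case], pooled_case)
    phi_ctrl = _mom_dispersion(raw_frac[:, ~is_case], n_total[:, ~is_case], pooled_ctrl)
    n_case_cov = (n_total[:, is_case] > 0).sum(axis=1)
    n_ctrl_cov = (n_total[:, ~is_case] > 0).sum(axis=1)
    phi_hat = (phi_case * n_case_cov + phi_ctrl * n_ctrl_cov) / (n_case_cov + n_ctrl_cov)

    # shrink per-site dispersion toward the chromosome-wide median
    phi = np.empty_like(phi_hat)
    n_samp = n_case_cov + n_ctrl_cov
    for chrom in keys["chrom"].unique():
        sel = (keys["chrom"] == chrom).to_numpy()
        med = float(np.median(phi_hat[sel]))
        phi[sel] = (shrinkage_m * med + n_samp[sel] * phi_hat[sel]) / (
            shrinkage_m + n_samp[sel]
        )

    def eff_weight(nt):
        with np.errstate(invalid="ignore", divide="ignore"):
            w = nt / (1.0 + (nt - 1.0) * phi[:, None])
        return np.where(nt > 0, w, 0.0).sum(axis=1)

    w_case = eff_weight(nt_case)
    w_ctrl = eff_weight(nt_ctrl)
    var_unit = pooled_all * (1.0 - pooled_all)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(var_unit * (1.0 / w_case + 1.0 / w_ctrl))
    delta = pi_case - pi_ctrl
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(se > 0, delta / se, 0.0)
    p = np.where(se > 0, 2.0 * sps.norm.sf(np.abs(wald)), 1.0)

    return pd.DataFrame(
        {
            "chrom": keys["chrom"],
            "pos": keys["pos"],
            "pi_case": pi_case,
            "pi_control": pi_ctrl,
            "delta": delta,
            "wald_stat": wald,
            "p_value": np.clip(p, 0.0, 1.0),
        }
    )


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_dmps(records: pd.DataFrame, p_max: float = 0.01, delta_min: float = 0.2) -> pd.DataFrame:
    """Significant DMPs: p < p_max and |delta| > delta_min."""
    keep = records[(records["p_value"] < p_max) & (records["delta"].abs() > delta_min)]
    return keep.reset_index(drop=True)


def call_dmrs(
    dmps: pd.DataFrame,
    min_dmps: int = 6,
    max_gap_bp: int = 1000,
    region_p_max: float = 0.05,
) -> list:
    """Merge runs of same-direction DMPs into regions; filter by size and p.

    Consecutive DMPs (per chromosome, position order) join the same
    candidate region while the gap to the previous member is <= max_gap_bp
    and the delta sign matches.  Regions need >= min_dmps members and a
    Stouffer-combined p < region_p_max.  Bounds are the first/last member
    CpG positions (1-based inclusive).
    """
    out = []
    if dmps.empty:
        return out
    for chrom, sub in dmps.groupby("chrom", sort=True):
        sub = sub.sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy()
        delta = sub["delta"].to_numpy()
        pval = sub["p_value"].to_numpy()
        sign = np.sign(delta)
        run_start = 0
        for i in range(1, len(sub) + 1):
            new_run = (
                i == len(sub)
                or pos[i] - pos[i - 1] > max_gap_bp
                or sign[i] != sign[i - 1]
            )
            if not new_run:
                continue
            members = slice(run_start, i)
            run_start = i
            k = members.stop - members.start
            if k < min_dmps:
                continue
            z = sps.norm.isf(np.clip(pval[members], 1e-300, 1.0) / 2.0)
            region_p = float(min(1.0, 2.0 * sps.norm.sf(z.sum() / np.sqrt(k))))
            if region_p >= region_p_max:
                continue
            out.append(
                DMRRecord(
                    chrom=str(chrom),
                    start=int(pos[members][0]),
                    end=int(pos[members][-1]),
                    n_dmps=int(k),
                    mean_delta=float(delta[members].mean()),
                    direction=HYPO if sign[members.start] < 0 else HYPER,
                    region_p=region_p,
                )
            )
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


# ---------------------------------------------------------------------------
# subsample augmentation
# ---------------------------------------------------------------------------

def augment_subsamples(
    tables,
    reps_control: int = 7,
    reps_case: int = 20,
    thin_fraction: float = 0.5,
    seed: int = 0,
) -> list:
    """Binomial-thinning augmentation of WGBS samples.

    Every input sample is replayed ``reps_control`` (controls) or
    ``reps_case`` (cases) times; in each replicate the methylated and
    unmethylated read counts are independently thinned per site with
    ``Binomial(count, thin_fraction)``.  With the study's 3 + 3 parents and
    7/20 replicates this yields the canonical 21 control and 60 case
    sub-samples.  ``thin_fraction=1`` reproduces each parent exactly;
    deterministic under ``seed``.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no input tables")
    if not 0.0 < thin_fraction <= 1.0:
        raise ValueError("thin_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for t in tables:
        reps = reps_control if t.group == CONTROL else reps_case
        meth = t.records["n_meth"].to_numpy()
        unmeth = t.records["n_total"].to_numpy() - meth
        for r in range(reps):
            if thin_fraction >= 1.0:
                m2, u2 = meth, unmeth
            else:
                m2 = rng.binomial(meth, thin_fraction)
                u2 = rng.binomial(unmeth, thin_fraction)
            rec = pd.DataFrame(
                {
                    "chrom": t.records["chrom"],
                    "pos": t.records["pos"],
                    "n_total": m2 + u2,
                    "n_meth": m2,
                }
            )
            out.append(
                CpGCountTable(
                    records=rec,
                    sample_id=f"{t.sample_id}_rep{r:02d}",
                    group=t.group,
                    activity=t.activity,
                )
            )
    return out
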