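"""Core data containers and readers/writers for the external formats the pipeline touches.

Containers
----------
:class:`BetaMatrix`
    Probes x samples methylation fractions (HM450-style beta values) with
    per-sample group labels and an optional disease-activity score.
:class:`ExprMatrix`
    Genes x samples log-scale expression with group labels.
:class:`CpGCountTable`
    Per-CpG methylated/total read counts for one bisulfite-sequencing sample.
:class:`ProbeAnnotation`
    Probe id -> (chrom, pos, gene symbol, region class) lookup.
:class:`GeneSetCollection`
    Named gene sets (GMT-style).
:class:`SignatureMatrix`
    Marker x cell-type reference methylation fractions for deconvolution.

Coordinate conventions
----------------------
CpG positions are 1-based internally, matching the Bismark coverage dialect.
Conversion to 0-based half-open happens only at the BED boundary
(:func:`write_dmr_bed`, :func:`read_bed`).  Strand is ignored throughout:
CpG-level aggregation never depends on it here.

Missing beta values stay missing (NaN) on read; they are resolved only by the
explicit imputation step, never silently zero-filled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CONTROL = "control"
CASE = "case"

_NA_TOKENS = ["NA", "NaN", "nan", ""]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class BetaMatrix:
    """Methylation-fraction matrix (probes x samples) in [0, 1].

    ``values`` is a DataFrame indexed by probe id with sample-id columns;
    NaN marks a missing beta value.  ``groups`` maps sample id to its label
    (typically ``"control"``/``"case"``); ``activity`` optionally carries a
    non-negative SLEDAI-like disease-activity score per sample.
    """

    values: pd.DataFrame
    groups: Optional[pd.Series] = None
    activity: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe id")
        _check_unique(self.values.columns, "sample id")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValueError(
                f"beta value outside [0,1]: probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r} = {vals[i, j]}"
            )
        if self.groups is not None:
            self.groups = pd.Series(self.groups).reindex(self.values.columns)
            if self.groups.isna().any():
                missing = self.values.columns[self.groups.isna()].tolist()
                raise ValueError(f"samples without group label: {missing[:5]}")
        if self.activity is not None:
            self.activity = pd.Series(self.activity, dtype=float).reindex(
                self.values.columns
            )

    @property
    def probe_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list:
        if self.groups is None:
            raise ValueError("BetaMatrix has no group labels")
        return list(self.groups.index[self.groups == group])


@dataclass
class ExprMatrix:
    """Log-scale expression matrix (genes x samples) with group labels."""

    values: pd.DataFrame
    groups: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene id")
        _check_unique(self.values.columns, "sample id")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.groups is not None:
            self.groups = pd.Series(self.groups).reindex(self.values.columns)
            if self.groups.isna().any():
                missing = self.values.columns[self.groups.isna()].tolist()
                raise ValueError(f"samples without group label: {missing[:5]}")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list:
        if self.groups is None:
            raise ValueError("ExprMatrix has no group labels")
        return list(self.groups.index[self.groups == group])


@dataclass
class CpGCountTable:
    """Per-CpG counts for one WGBS sample.

    ``records`` holds columns ``chrom`` (str), ``pos`` (1-based int),
    ``n_total`` and ``n_meth`` (ints, 0 <= n_meth <= n_total), sorted by
    (chrom, pos) with no duplicate site.  The per-site methylation ratio is
    ``n_meth / n_total``.
    """

    records: pd.DataFrame
    sample_id: str = "sample"
    group: str = CASE
    activity: Optional[float] = None

    def __post_init__(self) -> None:
        req = ["chrom", "pos", "n_total", "n_meth"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValueError(f"CpGCountTable missing columns {missing}")
        rec = self.records.loc[:, req].reset_index(drop=True)
        rec["chrom"] = rec["chrom"].astype(str)
        rec["pos"] = rec["pos"].astype(np.int64)
        rec["n_total"] = rec["n_total"].astype(np.int64)
        rec["n_meth"] = rec["n_meth"].astype(np.int64)
        if (rec["n_total"] < 0).any() or (rec["n_meth"] < 0).any():
            raise ValueError(f"negative counts in table for {self.sample_id!r}")
        if (rec["n_meth"] > rec["n_total"]).any():
            raise ValueError(f"n_meth > n_total in table for {self.sample_id!r}")
        if rec.duplicated(["chrom", "pos"]).any():
            dup = rec.loc[rec.duplicated(["chrom", "pos"]), ["chrom", "pos"]]
            raise ValueError(
                f"duplicate CpG site(s) in {self.sample_id!r}: "
                f"{dup.head(3).to_records(index=False).tolist()}"
            )
        ordered = rec.sort_values(["chrom", "pos"], kind="mergesort")
        if not ordered.index.equals(rec.index):
            log.info("CpG table %r was unsorted; sorted on load", self.sample_id)
            rec = ordered.reset_index(drop=True)
        self.records = rec

    def __len__(self) -> int:
        return len(self.records)

    @property
    def fractions(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.records["n_meth"].to_numpy() / self.records[
                "n_total"
            ].to_numpy(dtype=float)


@dataclass
class ProbeAnnotation:
    """HM450-style probe annotation: probe -> genomic position and gene.

    ``entries`` is indexed by probe id with columns ``chrom``, ``pos``
    (1-based), ``gene`` (symbol or empty string) and ``region_class``
    (promoter / TSS200 / TSS1500 / body / intergenic / ...).
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["chrom", "pos", "gene", "region_class"]
        missing = [c for c in req if c not in self.entries.columns]
        if missing:
            raise ValueError(f"ProbeAnnotation missing columns {missing}")
        _check_unique(self.entries.index, "probe id")
        self.entries = self.entries.copy()
        self.entries["pos"] = self.entries["pos"].astype(np.int64)
        if (self.entries["pos"] < 1).any():
            raise ValueError("probe positions must be >= 1 (1-based)")
        self.entries["gene"] = self.entries["gene"].fillna("").astype(str)

    def genes_of(self, probe_ids) -> set:
        present = self.entries.index.intersection(pd.Index(list(probe_ids)))
        genes = self.entries.loc[present, "gene"]
        return set(genes[genes != ""])


class GenomicInterval(NamedTuple):
    """BED-convention interval: 0-based inclusive start, exclusive end."""

    chrom: str
    start: int
    end: int
    payload: object = None

    def validate(self) -> "GenomicInterval":
        if not self.start < self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        return self


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets."""

    sets: dict

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(g) for name, g in self.sets.items()}
        empty = [name for name, g in self.sets.items() if not g]
        if empty:
            raise ValueError(f"empty gene set(s): {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    def names(self) -> list:
        return list(self.sets)


@dataclass
class SignatureMatrix:
    """Reference methylation signature: markers x cell types, values in [0,1].

    Deconvolution requires full column rank; rank is checked at solve time
    (the constructor only enforces the value range).
    """

    values: pd.DataFrame  # index: marker ids, columns: cell types

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "marker id")
        _check_unique(self.values.columns, "cell type")
        vals = self.values.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("signature values must lie in [0,1]")

    @property
    def marker_ids(self) -> list:
        return list(self.values.index)

    @property
    def cell_types(self) -> list:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_sample_sheet(path):
    sheet = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in sheet.columns or "group" not in sheet.columns:
        raise ValueError(f"sample sheet {path} needs 'sample_id' and 'group' columns")
    sheet = sheet.set_index("sample_id")
    groups = sheet["group"].astype(str)
    activity = sheet["activity"].astype(float) if "activity" in sheet.columns else None
    return groups, activity


def read_beta_matrix(path, sample_sheet_path=None) -> BetaMatrix:
    """Read a probes x samples beta-value TSV (first column = probe ids).

    ``NA`` cells are kept as missing values.  If ``sample_sheet_path`` is
    given it must be a CSV with columns ``sample_id,group[,activity]``.
    Out-of-range values and duplicate probe ids raise.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_TOKENS, keep_default_na=False
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    groups = activity = None
    if sample_sheet_path is not None:
        groups, activity = _read_sample_sheet(sample_sheet_path)
        unknown = [s for s in df.columns if s not in groups.index]
        if unknown:
            raise ValueError(f"samples missing from sample sheet: {unknown[:5]}")
        groups = groups.reindex(df.columns)
        if activity is not None:
            activity = activity.reindex(df.columns)
    return BetaMatrix(values=df.astype(float), groups=groups, activity=activity)


def write_beta_matrix(m: BetaMatrix, path, sample_sheet_path=None) -> None:
    """Write beta values as TSV (6 significant digits; NaN as ``NA``)."""
    m.values.to_csv(
        path, sep="\t", na_rep="NA", float_format="%.6g", index_label="probe_id"
    )
    if sample_sheet_path is not None:
        sheet = pd.DataFrame({"sample_id": m.sample_ids})
        sheet["group"] = m.groups.to_numpy() if m.groups is not None else ""
        if m.activity is not None:
            sheet["activity"] = m.activity.to_numpy()
        sheet.to_csv(sample_sheet_path, index=False)


def read_expr_matrix(path, sample_sheet_path=None) -> ExprMatrix:
    """Read a genes x samples log-expression TSV (same layout as beta TSV)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    groups = None
    if sample_sheet_path is not None:
        groups, _ = _read_sample_sheet(sample_sheet_path)
        groups = groups.reindex(df.columns)
    return ExprMatrix(values=df.astype(float), groups=groups)


def write_expr_matrix(m: ExprMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", float_format="%.6g", index_label="gene_id")


def read_bismark_cov(path, sample_id: str, group: str = CASE) -> CpGCountTable:
    """Parse a Bismark coverage file into a :class:`CpGCountTable`.

    Expected dialect: 6 whitespace/tab-separated columns —
    chrom, start (1-based), end, %methylation, count-methylated,
    count-unmethylated.  ``n_total`` is reconstructed as the sum of the two
    counts; the percentage column is ignored (redundant).
    """
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(
            columns=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"]
        )
    if df.empty:
        log.warning("Bismark coverage file %s is empty", path)
        rec = pd.DataFrame({"chrom": [], "pos": [], "n_total": [], "n_meth": []})
        return CpGCountTable(records=rec, sample_id=sample_id, group=group)
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        raise ValueError(f"negative counts in {path}")
    rec = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(np.int64),
            "n_total": (df["n_meth"] + df["n_unmeth"]).astype(np.int64),
            "n_meth": df["n_meth"].astype(np.int64),
        }
    )
    return CpGCountTable(records=rec, sample_id=sample_id, group=group)


def write_bismark_cov(table: CpGCountTable, path) -> None:
    """Write a table back to the 6-column Bismark coverage dialect."""
    rec = table.records
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(rec["n_total"] > 0, 100.0 * rec["n_meth"] / rec["n_total"], 0.0)
    out = pd.DataFrame(
        {
            "chrom": rec["chrom"],
            "start": rec["pos"],
            "end": rec["pos"],
            "pct": [f"{p:.6g}" for p in pct],
            "n_meth": rec["n_meth"],
            "n_unmeth": rec["n_total"] - rec["n_meth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


BED_SCORE_CAP = 300.0


def write_dmr_bed(dmrs, path) -> None:
    """Write DMR records as BED6: score = -log10(region p), capped at 300.

    Internal 1-based inclusive [start, end] becomes 0-based half-open
    [start-1, end).  ``dmrs`` is any iterable with ``chrom``, ``start``,
    ``end`` and ``region_p`` attributes.  An empty list produces an empty,
    header-less file.
    """
    lines = []
    for d in dmrs:
        p = float(d.region_p)
        score = BED_SCORE_CAP if p <= 0 else min(BED_SCORE_CAP, -math.log10(p))
        name = f"{d.chrom}:{d.start}-{d.end}"
        lines.append(f"{d.chrom}\t{d.start - 1}\t{d.end}\t{name}\t{score:.6g}\t.\n")
    Path(path).write_text("".join(lines))


def read_bed(path) -> list:
    """Read a BED3+ file into 0-based half-open :class:`GenomicInterval`s."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
        iv = GenomicInterval(
            chrom=parts[0],
            start=int(parts[1]),
            end=int(parts[2]),
            payload=tuple(parts[3:]) or None,
        ).validate()
        out.append(iv)
    return out


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from GMT (name, description, genes...).

    Duplicate genes within a set are collapsed; a line with a name and
    description but no genes is skipped with a warning; fewer than two
    columns or a repeated set name is an error.
    """
    sets = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: GMT line lacks a description column")
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}:{ln}: duplicate gene set name {name!r}")
        genes = frozenset(g for g in parts[2:] if g)
        if not genes:
            log.warning("%s:%d: gene set %r has no genes; skipped", path, ln, name)
            continue
        sets[name] = genes
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_probe_annotation(path) -> ProbeAnnotation:
    """Read probe annotation CSV: probe_id, chrom, pos, gene, region_class."""
    df = pd.read_csv(path, dtype={"probe_id": str, "chrom": str, "gene": str})
    req = ["probe_id", "chrom", "pos", "gene", "region_class"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ValueError(f"probe annotation {path} missing columns {missing}")
    df["gene"] = df["gene"].fillna("")
    return ProbeAnnotation(entries=df.set_index("probe_id"))


def write_probe_annotation(ann: ProbeAnnotation, path) -> None:
    ann.entries.to_csv(path, index_label="probe_id")
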