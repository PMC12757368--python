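"""Shared configuration and file-backed study loading for the drivers.

Driver 01 simulates the study and serializes every dataset through the
package's standard formats; later drivers reload what they need from disk,
so each numbered script can be re-run on its own.
"""

from pathlib import Path

import pandas as pd

from cflmd.io_formats import (
    read_beta_matrix,
    read_bismark_cov,
    read_expr_matrix,
    read_probe_annotation,
)
from cflmd.synthetic_data import StudyConfig

STUDY_SEED = 7
STUDY_CONFIG = StudyConfig(seed=STUDY_SEED, effect_size=0.3)

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "data"
OUT_DIR = ROOT / "results"


def array_paths(i: int):
    return DATA_DIR / f"array_ds{i}.tsv", DATA_DIR / f"array_ds{i}_samples.csv"


def expr_paths(i: int):
    return DATA_DIR / f"expr_ds{i}.tsv", DATA_DIR / f"expr_ds{i}_samples.csv"


def validation_paths():
    return DATA_DIR / "validation_array.tsv", DATA_DIR / "validation_array_samples.csv"


def load_array_datasets(n: int) -> list:
    return [read_beta_matrix(*array_paths(i)) for i in range(1, n + 1)]


def load_expr_datasets(n: int) -> list:
    return [read_expr_matrix(*expr_paths(i)) for i in range(1, n + 1)]


def load_wgbs_tables() -> list:
    sheet = pd.read_csv(DATA_DIR / "wgbs_samples.csv")
    tables = []
    for _, row in sheet.iterrows():
        t = read_bismark_cov(
            DATA_DIR / f"wgbs_{row['sample_id']}.cov",
            sample_id=row["sample_id"],
            group=row["group"],
        )
        t.activity = float(row["activity"])
        tables.append(t)
    return tables


def load_annotation():
    return read_probe_annotation(DATA_DIR / "probe_annotation.csv")


def load_tss() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "tss.csv")


def load_truth_genes() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "truth_genes.csv")
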