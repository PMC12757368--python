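#!/usr/bin/env python
"""Simulate the multi-platform study and serialize every dataset.

Produces, under results/data/: three HM450-style discovery beta matrices,
three log-expression matrices, an independent validation beta matrix with
per-sample activity scores, six Bismark coverage files (3 control + 3 case
plasma WGBS samples), the shared probe annotation, the TSS table and the
gene-level ground truth used only for evaluation.
"""

import pandas as pd

from cflmd.io_formats import write_beta_matrix, write_bismark_cov, write_expr_matrix, write_probe_annotation
from cflmd.synthetic_data import simulate_multiomics_study

from common import DATA_DIR, STUDY_CONFIG, array_paths, expr_paths, validation_paths


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    study = simulate_multiomics_study(STUDY_CONFIG)

    for i, beta in enumerate(study.beta_datasets, start=1):
        write_beta_matrix(beta, *array_paths(i))
    for i, expr in enumerate(study.expr_datasets, start=1):
        path, sheet = expr_paths(i)
        write_expr_matrix(expr, path)
        pd.DataFrame(
            {"sample_id": expr.values.columns, "group": expr.groups.to_numpy()}
        ).to_csv(sheet, index=False)

    write_beta_matrix(study.validation_beta, *validation_paths())

    rows = []
    for t in study.wgbs_tables:
        write_bismark_cov(t, DATA_DIR / f"wgbs_{t.sample_id}.cov")
        rows.append({"sample_id": t.sample_id, "group": t.group, "activity": t.activity})
    pd.DataFrame(rows).to_csv(DATA_DIR / "wgbs_samples.csv", index=False)

    write_probe_annotation(study.annotation, DATA_DIR / "probe_annotation.csv")
    study.tss_table.to_csv(DATA_DIR / "tss.csv", index=False)

    truth = pd.DataFrame(
        [{"gene": g, "direction": "hypo"} for g in sorted(study.truth.true_hypo_genes)]
        + [{"gene": g, "direction": "hyper"} for g in sorted(study.truth.true_hyper_genes)]
    )
    truth.to_csv(DATA_DIR / "truth_genes.csv", index=False)

    print(f"wrote {len(study.beta_datasets)} array + {len(study.expr_datasets)} "
          f"expression datasets, {len(study.wgbs_tables)} WGBS samples, "
          f"{len(study.annotation.entries)} probes, {len(truth)} planted genes "
          f"-> {DATA_DIR}")


if __name__ == "__main__":
    main()
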