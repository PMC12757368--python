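#!/usr/bin/env python
"""Consensus differential screen across the discovery cohorts.

Runs the moderated t-test per dataset, applies the DEG and DMP selection
rules, requires agreement (same direction, >= 3 datasets) and maps
consensus probes to genes.  Writes results/consensus_degs.csv and
results/consensus_dmgs.csv.
"""

import pandas as pd

from cflmd.diff_consensus import (
    consensus_features,
    map_probes_to_genes,
    moderated_t_test,
    select_degs,
    select_dmps,
)

from common import OUT_DIR, STUDY_CONFIG, load_annotation, load_array_datasets, load_expr_datasets


def main() -> None:
    ann = load_annotation()

    deg_sel = [select_degs(moderated_t_test(e))
               for e in load_expr_datasets(STUDY_CONFIG.n_expr_datasets)]
    deg = consensus_features(deg_sel, min_datasets=3)
    pd.DataFrame(
        [{"gene": g, "direction": "up"} for g in sorted(deg.selected_up)]
        + [{"gene": g, "direction": "down"} for g in sorted(deg.selected_down)]
    ).to_csv(OUT_DIR / "consensus_degs.csv", index=False)

    dmp_sel = [select_dmps(moderated_t_test(b))
               for b in load_array_datasets(STUDY_CONFIG.n_array_datasets)]
    dmp = consensus_features(dmp_sel, min_datasets=3)
    dmg_up = sorted(map_probes_to_genes(dmp.selected_up, ann))
    dmg_down = sorted(map_probes_to_genes(dmp.selected_down, ann))
    pd.DataFrame(
        [{"gene": g, "direction": "hyper"} for g in dmg_up]
        + [{"gene": g, "direction": "hypo"} for g in dmg_down]
    ).to_csv(OUT_DIR / "consensus_dmgs.csv", index=False)

    print(f"consensus DEGs: {len(deg.selected)} "
          f"({len(deg.selected_up)} up / {len(deg.selected_down)} down, "
          f"{len(deg.conflicting)} conflicting)")
    print(f"consensus DMPs: {len(dmp.selected)} -> "
          f"{len(dmg_up) + len(dmg_down)} DMGs "
          f"({len(dmg_up)} hyper / {len(dmg_down)} hypo)")


if __name__ == "__main__":
    main()
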