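#!/usr/bin/env python
"""Cross-platform screen for model regions and DMR context annotation.

Keeps DMRs falling in the padded loci of genes that are both consensus
DEGs and consensus DMGs, drops regions no array probe covers (so the WGBS
and array feature spaces stay aligned) and annotates each retained region
with its nearest-TSS distance and probe region class.  Also reports the
overlap with the planted truth genes (evaluation only).
"""

import pandas as pd

from cflmd.feature_integration import annotate_dmr_context, project_features_array, screen_model_regions
from cflmd.io_formats import read_beta_matrix
from cflmd.wgbs_dmr import DMRRecord

from common import OUT_DIR, load_annotation, load_truth_genes, load_tss, validation_paths


def load_dmrs() -> list:
    df = pd.read_csv(OUT_DIR / "wgbs_dmrs.csv")
    return [
        DMRRecord(chrom=r["chrom"], start=int(r["start"]), end=int(r["end"]),
                  n_dmps=int(r["n_dmps"]), mean_delta=float(r["mean_delta"]),
                  direction=r["direction"], region_p=float(r["region_p"]))
        for _, r in df.iterrows()
    ]


def main() -> None:
    ann = load_annotation()
    deg = set(pd.read_csv(OUT_DIR / "consensus_degs.csv")["gene"])
    dmg = set(pd.read_csv(OUT_DIR / "consensus_dmgs.csv")["gene"])
    dmrs = load_dmrs()

    regions = screen_model_regions(deg, dmg, dmrs, ann)

    # regions without a covering probe cannot be projected onto arrays;
    # drop them from the model so both platforms share one feature space
    val_beta = read_beta_matrix(*validation_paths())
    covered = set(project_features_array(regions, val_beta, ann).region_ids)
    regions = [r for r in regions if r.region_id in covered]

    genes_hit = set()
    for r in regions:
        ent = ann.entries
        sel = (ent["chrom"] == r.chrom) & (ent["pos"] >= r.start) & (ent["pos"] <= r.end)
        genes_hit |= set(ent.loc[sel, "gene"]) - {""}

    pd.DataFrame(
        [
            {"region_id": r.region_id, "chrom": r.chrom, "start": r.start,
             "end": r.end, "direction": r.direction, "mean_delta": r.mean_delta}
            for r in regions
        ]
    ).to_csv(OUT_DIR / "model_regions.csv", index=False)

    annotate_dmr_context(regions, ann, load_tss()).to_csv(
        OUT_DIR / "model_region_context.csv", index=False
    )

    truth = set(load_truth_genes()["gene"])
    print(f"{len(regions)} model regions over {len(genes_hit)} genes; "
          f"{len(genes_hit & truth)}/{len(truth)} planted genes recovered")


if __name__ == "__main__":
    main()
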