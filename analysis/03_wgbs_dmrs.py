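#!/usr/bin/env python
"""Differential methylation on the plasma WGBS samples.

Beta-binomial Wald test per CpG (500 bp smoothing, dispersion shrinkage),
DMP calling (p < 0.01, |delta| > 0.2) and DMR merging (same direction,
gap <= 1 kb, >= 6 DMPs, Stouffer region p < 0.05).  Writes the per-site
statistics, the DMR table and a BED track.
"""

import pandas as pd

from cflmd.io_formats import CASE, write_dmr_bed
from cflmd.wgbs_dmr import bb_wald_test, call_dmps, call_dmrs

from common import OUT_DIR, load_wgbs_tables


def main() -> None:
    tables = load_wgbs_tables()
    cases = [t for t in tables if t.group == CASE]
    ctrls = [t for t in tables if t.group != CASE]

    records = bb_wald_test(cases, ctrls)
    records.to_csv(OUT_DIR / "wgbs_site_stats.csv", index=False)

    dmps = call_dmps(records)
    dmps.to_csv(OUT_DIR / "wgbs_dmps.csv", index=False)

    dmrs = call_dmrs(dmps)
    pd.DataFrame(
        [
            {
                "region_id": d.region_id, "chrom": d.chrom, "start": d.start,
                "end": d.end, "n_dmps": d.n_dmps, "mean_delta": d.mean_delta,
                "direction": d.direction, "region_p": d.region_p,
            }
            for d in dmrs
        ]
    ).to_csv(OUT_DIR / "wgbs_dmrs.csv", index=False)
    write_dmr_bed(dmrs, OUT_DIR / "wgbs_dmrs.bed")

    n_hypo = sum(d.direction == "hypo" for d in dmrs)
    print(f"{len(records)} sites tested, {len(dmps)} DMPs, {len(dmrs)} DMRs "
          f"({n_hypo} hypo / {len(dmrs) - n_hypo} hyper)")


if __name__ == "__main__":
    main()
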