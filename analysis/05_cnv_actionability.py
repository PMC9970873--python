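"""Copy-number actionability: artifact removal by reciprocal overlap, log2
classification, the focality/threshold decision tree, second hits and LOH
review on the planted segment profile."""

from pathlib import Path

import pandas as pd

from somapipe.cnv import (
    actionable_cnv,
    artifact_overlap_filter,
    classify_segment,
    copies_from_log2,
    loh_actionable,
    second_hit,
)
from somapipe.simulate import CohortConfig, make_cnv_profile

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    prof = make_cnv_profile(CohortConfig(seed=seed))
    kept = artifact_overlap_filter(prof["segments"], prof["known_artifacts"])
    n_removed = len(prof["segments"]) - len(kept)
    rows = []
    for s in kept:
        act = actionable_cnv(s)
        rows.append({
            "chrom": s.interval.chrom, "start": s.interval.start, "end": s.interval.end,
            "length_mb": round(s.interval.length / 1e6, 2), "log2": s.log2_ratio,
            "class": classify_segment(s), "category": act["category"],
            "focal": act["focal"], "copies": round(copies_from_log2(s.log2_ratio), 1),
            "genes": ";".join(s.genes),
        })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "cnv_actionability.tsv", sep="\t", index=False)
    print(df[df["category"] != "none"].to_string(index=False))
    print(f"\n{n_removed} segment(s) removed as known artifacts (>=95% reciprocal overlap)")
    loh = loh_actionable(prof["loh_regions"], prof["actionable_genes"])
    for region, genes in loh:
        print(f"actionable LOH: {region.chrom}:{region.start}-{region.end} "
              f"({region.length / 1e6:.0f} Mb) over {', '.join(genes)}")
    hits = second_hit("SMARCB1", prof["second_hit_variants"], prof["segments"])
    for v, s in hits:
        print(f"second hit: {v.gene} {v.consequence} at {v.chrom}:{v.pos} + "
              f"deletion log2={s.log2_ratio} ({s.interval.length / 1e6:.0f} Mb)")


if __name__ == "__main__":
    main()
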