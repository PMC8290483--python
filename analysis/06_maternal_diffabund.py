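#!/usr/bin/env python
"""Genus-level differential abundance: maternal stool, week 1 vs week 4.

Aggregates OTU counts to the genus level (or the deepest resolved rank),
converts to relative abundance, and tests each genus between the two
postpartum windows with rank-sum tests under Benjamini-Hochberg FDR
control.  Also reports the most abundant genera overall.

Writes results/diffabund/.
"""

import argparse
from pathlib import Path

from otukit import diffabund
from otukit.core_io import (
    AnalysisConfig,
    read_count_table,
    read_metadata,
    read_taxonomy,
    write_report,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--qc-dir", type=Path, default=Path("results/qc"))
    ap.add_argument("--sim-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/diffabund"))
    ap.add_argument("--top-k", type=int, default=25)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    meta = read_metadata(args.sim_dir / "metadata.tsv")
    tax = read_taxonomy(args.sim_dir / "taxonomy.tsv")
    cfg = AnalysisConfig(rng_seed=args.seed)
    table = read_count_table(args.qc_dir / "cleaned_bacteria_16S.tsv")
    in_table = set(table.sample_ids)
    g1 = [s for s in meta.ids_where(sample_type="mother_stool", age_bin="Mother-wk1")
          if s in in_table]
    g2 = [s for s in meta.ids_where(sample_type="mother_stool", age_bin="Mother-wk4")
          if s in in_table]
    genus_table = diffabund.aggregate_by_genus(table.subset_samples(g1 + g2), tax)
    relab = diffabund.relative_abundance(genus_table)
    res = diffabund.group_difference_test(relab, g1, g2, cfg)
    write_report(res, args.out_dir / "genus_tests.tsv", params=cfg.to_dict())
    write_report(diffabund.top_genera(relab, args.top_k),
                 args.out_dir / "top_genera.tsv", params=cfg.to_dict())
    sig = res[res["significant"]]
    up_wk1 = sig[sig["direction"] > 0]["taxon"].tolist()
    up_wk4 = sig[sig["direction"] < 0]["taxon"].tolist()
    print(f"{len(sig)} of {len(res)} genera differ between maternal windows "
          f"(BH-adjusted p < {cfg.alpha_level})")
    print(f"  higher week 1: {', '.join(up_wk1) or 'none'}")
    print(f"  higher week 4: {', '.join(up_wk4) or 'none'}")


if __name__ == "__main__":
    main()
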