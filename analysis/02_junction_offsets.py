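"""Measure recovery of configured junction offsets.

For each configured 5' offset (0, 15, 110, 130 bp — canonical plus the
documented shifted geometries) and decay level (0 and 5%), simulate an
insertion, rediscover the copy, and call its junctions against the target.
The shifted geometries reproduce upstream 28S replacement: the 5' junction
moves while the 3' junction stays fixed at the canonical site.

Writes results/junction_offsets.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from r2scan.junctions import call_junctions, find_copies
from r2scan.syngenome import (InsertionSpec, build_target_reference,
                              insert_copies, simulate_element_family)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/junction_offsets.tsv")
    args = ap.parse_args()

    target = build_target_reference(flank_len=200, seed=args.seed)
    fam = simulate_element_family("R2A", seed=args.seed + 1, family_id="fam",
                                  target=target)
    rows = []
    for offset5 in (0, 15, 110, 130):
        for div in (0.0, 0.05):
            b = insert_copies(target, [fam],
                              [InsertionSpec("fam", offset5=offset5,
                                             divergence=div)],
                              n_units=1, spacer_len=400, seed=args.seed + 2)
            (copy,) = find_copies(b.genome, fam.consensus, family_id="fam",
                                  min_len=500)
            jc = call_junctions(copy, b.genome, target)
            rows.append(dict(configured_offset5=offset5, divergence=div,
                             called_offset5=jc.offset5, called_offset3=jc.offset3,
                             specificity=jc.specificity))
    df = pd.DataFrame(rows)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, sep="\t", index=False)
    print(df.to_string(index=False))
    exact = (df.configured_offset5 == df.called_offset5).mean()
    print(f"\nexact 5' offset recovery: {100 * exact:.0f}% of "
          f"{len(df)} configurations; 3' junction canonical throughout: "
          f"{bool((df.called_offset3 == 0).all())}")


if __name__ == "__main__":
    main()
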