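#!/usr/bin/env python
"""Temporal ordering of mutations within each clone-tree branch.

For every branch of the selected clone tree with at least two
mutations, builds the per-sample VAF wins matrix, fits Bradley-Terry
MAP abilities (prior shape a = 1.1), and writes the ranked timeline to
results/ordering/timeline.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from clonaltrace import branch_ordering as bo
from clonaltrace import subclone_inference as si
from clonaltrace import variant_matrix as vm

COHORT = Path("results/cohort")
SUBCLONES = Path("results/subclones")
OUT = Path("results/ordering")


def main() -> None:
    matrix = vm.read_cohort(COHORT / "cohort.vcf", COHORT / "manifest.tsv")
    tree = si.CloneTree.from_json((SUBCLONES / "clone_tree.json").read_text())

    ids = [matrix.variant_label(i) for i in range(len(matrix.variants))]
    vaf = pd.DataFrame(matrix.vaf, index=ids,
                       columns=matrix.samples)[matrix.tumor_samples]
    timelines = []
    for edge, muts in sorted(tree.edge_mutations().items()):
        if len(muts) < 2:
            print(f"branch {edge}: single mutation, no ordering")
            continue
        tl = bo.order_branch(vaf.loc[muts], branch=edge)
        timelines.append(tl)
        first = tl.sort_values("rank").iloc[0]
        print(f"branch {edge}: {len(muts)} mutations; earliest "
              f"{first['mutation']} (ability {first['ability']:.2f}, "
              f"max pair probability {first['max_pair_probability']:.2f})")
    timeline = pd.concat(timelines, ignore_index=True)
    OUT.mkdir(parents=True, exist_ok=True)
    bo.write_timeline(timeline, OUT / "timeline.tsv")
    print(f"timeline -> {OUT / 'timeline.tsv'}")


if __name__ == "__main__":
    main()
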