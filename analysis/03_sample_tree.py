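#!/usr/bin/env python
"""Sample-level phylogeny over somatic SNV sets.

Builds the symmetric-difference distance matrix (normal = empty set, so
its column equals each tumor's SNV count), runs neighbor joining, roots
the tree at the normal sample, and writes the Newick plus distance
matrix under results/tree/.
"""

from pathlib import Path

from clonaltrace import sample_phylogeny as sp
from clonaltrace import variant_matrix as vm

COHORT = Path("results/cohort")
OUT = Path("results/tree")


def main() -> None:
    matrix = vm.read_cohort(COHORT / "cohort.vcf", COHORT / "manifest.tsv")
    sets = matrix.presence_sets(snv_only=True)
    dm = sp.symmetric_difference_distance(sets)
    tree = sp.clamp_negative_lengths(sp.neighbor_joining(dm))
    rooted = sp.root_at_normal(tree)
    OUT.mkdir(parents=True, exist_ok=True)
    dm.write_tsv(OUT / "distances.tsv")
    sp.write_newick(rooted, OUT / "sample_tree.nwk")

    dist = sp.path_lengths_from(rooted, "normal")
    nearest = sorted((d, s) for s, d in dist.items()
                     if s in matrix.tumor_samples)
    print("path distance from normal, closest first:")
    for d, s in nearest:
        print(f"  {s}: {d:.1f}")
    print(f"tree -> {OUT / 'sample_tree.nwk'}")


if __name__ == "__main__":
    main()
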