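#!/usr/bin/env python
"""Subclonal deconvolution with BIC model selection.

Fits clone trees for K = 1..5 to the cohort (low-depth mutations held
out), selects K by the BIC elbow rule, assigns the held-out mutations
post hoc, and writes the clone tree, per-sample composition, and
assignments under results/subclones/.
"""

import json
from pathlib import Path

import pandas as pd

from clonaltrace import cnv_segments as cs
from clonaltrace import subclone_inference as si
from clonaltrace import variant_matrix as vm

COHORT = Path("results/cohort")
CNV = Path("results/cnv")
OUT = Path("results/subclones")
SEED = (20190801 + 5) % (2**31)
RESIDUAL_MIN_DEPTH = 30


def main() -> None:
    matrix = vm.read_cohort(COHORT / "cohort.vcf", COHORT / "manifest.tsv")
    bundle = cs.diploid_bundle(matrix)

    depth = matrix.depth[:, [matrix.sample_index(s) for s in matrix.tumor_samples]]
    low = (depth < RESIDUAL_MIN_DEPTH).any(axis=1)
    ids = [matrix.variant_label(i) for i in range(len(matrix.variants))]
    core = [m for m, lo in zip(ids, low) if not lo]
    residual = [m for m, lo in zip(ids, low) if lo]

    cfg = si.FitConfig(K_range=(1, 5), restarts=10, seed=SEED)
    selected, fits = si.fit_and_select(matrix, bundle, cfg, core)
    posthoc = si.posthoc_assign(selected, matrix, residual, bundle) if residual \
        else pd.DataFrame()

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "clone_tree.json").write_text(selected.to_json() + "\n")
    si.write_prevalence(selected, OUT / "composition")
    if not posthoc.empty:
        posthoc.to_csv(OUT / "posthoc.tsv", sep="\t", index=False)
    (OUT / "bic.json").write_text(json.dumps(
        {str(k): round(f.bic, 2) for k, f in fits.items()}, indent=1) + "\n")

    print("BIC by K: " + ", ".join(f"K={k}: {f.bic:.1f}"
                                   for k, f in sorted(fits.items())))
    print(f"selected K = {selected.K} "
          f"({len(core)} modeled + {len(residual)} post-hoc mutations)")
    comp = si.prevalence_report(selected).drop(index="total")
    dominant = comp.drop(index="normal").idxmax()
    print("dominant clone per sample:")
    for s, c in dominant.items():
        print(f"  {s}: {c} ({comp.loc[c, s]:.0f}%)")


if __name__ == "__main__":
    main()
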