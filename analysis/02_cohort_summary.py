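#!/usr/bin/env python
"""Per-sample mutation burden and cross-sample sharing of the cohort.

Reads results/cohort/ (written by 01_simulate_cohort.py), applies the
presence rule (alt >= 4 reads and VAF >= 0.05), and reports per-sample
TMB (mutations / 38.9 Mb capture) plus the sharing summary.  Writes
results/tables/.
"""

from pathlib import Path

import pandas as pd

from clonaltrace import variant_matrix as vm

COHORT = Path("results/cohort")
OUT = Path("results/tables")


def main() -> None:
    matrix = vm.read_cohort(COHORT / "cohort.vcf", COHORT / "manifest.tsv")
    OUT.mkdir(parents=True, exist_ok=True)
    summary = vm.sharing_summary(matrix)
    tmb = {s: vm.compute_tmb(matrix, s) for s in matrix.tumor_samples}
    pd.Series(tmb, name="tmb_per_mb").rename_axis("sample") \
        .to_frame().to_csv(OUT / "tmb.tsv", sep="\t", float_format="%.4f")
    vm.write_summary(summary, OUT / "sharing")

    print(f"{summary['unique_variants']} unique variants, "
          f"{summary['total_calls']} total per-sample calls")
    lo, hi = min(tmb, key=tmb.get), max(tmb, key=tmb.get)
    print(f"TMB range: {tmb[lo]:.2f} ({lo}) to {tmb[hi]:.2f} ({hi}) mutations/Mb")
    print(f"tables -> {OUT}")


if __name__ == "__main__":
    main()
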