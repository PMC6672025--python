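#!/usr/bin/env python
"""Simulate the emulated rapid-autopsy cohort and write it to disk.

Produces a multi-sample VCF (1 normal + 11 tumor samples, 292 unique
somatic mutations of which 7 are truncal, a truncal 21.9-Mb chr8q gain,
231x mean depth), the ground-truth JSON, and the sample manifest under
results/cohort/.
"""

from pathlib import Path

from clonaltrace import synthetic_tumor as st

SEED = 20190801 % (2**31)
OUT = Path("results/cohort")


def main() -> None:
    truth, matrix = st.simulate_figure3c_cohort(seed=SEED, depth_mean=231.0)
    paths = st.write_fixture(truth, matrix, OUT)
    n_truncal = len(truth.branch_mutations["clone3"])
    print(f"cohort: {len(matrix.variants)} unique mutations across "
          f"{len(matrix.tumor_samples)} tumor samples "
          f"({n_truncal} truncal, clone-1 branch carries "
          f"{len(truth.branch_mutations['clone1'])}); "
          f"truncal CNV: chr{truth.cnv_truth[0][0]}:"
          f"{truth.cnv_truth[0][1]}-{truth.cnv_truth[0][2]}")
    for name, p in paths.items():
        print(f"  {name}: {p}")


if __name__ == "__main__":
    main()
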