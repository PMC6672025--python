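#!/usr/bin/env python
"""One-shot pipeline run with the cohort report.

Runs simulate -> matrix -> tree -> CNV -> subclones -> ordering through
the pipeline orchestrator (same seed policy as the numbered scripts)
and renders results/pipeline/report.md plus the validated JSON summary.
"""

import json
import warnings
from pathlib import Path

from clonaltrace.pipeline import PipelineConfig, run_pipeline

OUT = Path("results/pipeline")


def main() -> None:
    cfg = PipelineConfig(out_dir=str(OUT), seed=20190801 % (2**31))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        run_pipeline(cfg)
    doc = json.loads((OUT / "report.json").read_text())
    print(f"selected K = {doc['selected_k']}; "
          f"{doc['n_unique_variants']} unique variants; "
          f"{doc['n_curated_cnv_regions']} curated CNV region(s)")
    print(f"report -> {OUT / 'report.md'}")


if __name__ == "__main__":
    main()
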