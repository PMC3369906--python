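#!/usr/bin/env python
"""Rank diseases by their disease-pain ratio to form the pain index.

Reads results/run/citations.tsv, drops diseases without a single pain
co-citation, and writes the ranked index (ratio + midrank) to
results/run/index.tsv.
"""

from pathlib import Path

from painscreen.pipeline import RunConfig, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    manifest = run_pipeline(RunConfig(out_dir=str(OUT), seed=7, stages=("dspi",)))
    c = manifest["counts"]["dspi"]
    print(f"pain index: {c['retained']} diseases retained, "
          f"{c['excluded']} excluded for lacking a pain co-citation")


if __name__ == "__main__":
    main()
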