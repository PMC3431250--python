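#!/usr/bin/env python
"""Gabriel-rule haplotype blocks on the independent haplotypes.

Classifies SNP pairs within a marker window by their |D'| confidence bounds
(strong LD: CU > 0.98 and CL > 0.70; recombination: CU < 0.90), calls blocks
greedily longest-first, and summarizes per chromosome.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

import importlib.util

from flockld.blocks import block_summary, blocks_to_frame
from flockld.pipeline import PipelineConfig, call_blocks_stage

_spec = importlib.util.spec_from_file_location(
    "ld_step", os.path.join(os.path.dirname(__file__), "03_ld_decay.py")
)
_ld_step = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_ld_step)

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
OUT = os.path.join(BASE, "blocks")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    h = _ld_step.load_haplotypes()
    blocks = call_blocks_stage(h, PipelineConfig())
    blocks_to_frame(blocks, h.markers).to_csv(
        os.path.join(OUT, "blocks.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    chrom_lengths = {
        int(c): int(h.markers.bp[h.markers.chrom_indices(int(c))].max())
        for c in h.markers.chromosomes()
    }
    summary = block_summary(blocks, h.markers, chrom_lengths)
    summary.to_csv(os.path.join(OUT, "block_summary.tsv"), sep="\t", index=False,
                   float_format="%.6g")
    total = summary[summary["chrom"] == "all"].iloc[0]
    print(
        f"{int(total['n_blocks'])} blocks, total {total['total_kb']:.1f} kb, "
        f"{total['pct_snps_in_blocks']:.2f}% of SNPs in blocks, "
        f"{total['pct_length_in_blocks']:.2f}% of genome length"
    )


if __name__ == "__main__":
    main()
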