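#!/usr/bin/env python
"""Simulate the half-sib study dataset.

Runs the Wright-Fisher simulator under the default declining-Ne trajectory,
draws the half-sib daughter design (8 sires x 40 daughters, dams not
genotyped), degrades genotypes with array-like missingness and error, and
writes the PLINK-style files plus the truth directory that the later steps
consume.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from flockld import io as fio
from flockld.simulate import SimConfig, degrade, sample_halfsib, simulate_population

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "simulated")
SEED = 20240901 % (2**31)


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    truth = simulate_population(cfg)
    sample = sample_halfsib(truth)
    g = degrade(sample.genotypes, cfg.missing_rate, cfg.genotype_error_rate, SEED + 2)

    fio.write_genotypes(g, os.path.join(OUT, "sample.ped"), os.path.join(OUT, "sample.map"))
    fio.write_pedigree(sample.pedigree, os.path.join(OUT, "pedigree.tsv"))
    fio.write_haplotypes(sample.true_phase, os.path.join(OUT, "true_phase.tsv"))
    truth.true_ne.to_csv(os.path.join(OUT, "true_ne.tsv"), sep="\t", index=False)
    with open(os.path.join(OUT, "sim_config.json"), "w") as fh:
        json.dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()},
            fh, indent=2, default=str,
        )
    print(
        f"simulated {g.n_individuals} genotyped individuals "
        f"({cfg.n_sires} sires + {cfg.n_sires * cfg.daughters_per_sire} daughters), "
        f"{g.n_markers} SNPs after {cfg.ascertainment_maf:.0%}-MAF ascertainment "
        f"(of {len(truth.markers)} candidate loci); outputs in {os.path.relpath(OUT)}"
    )


if __name__ == "__main__":
    main()
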