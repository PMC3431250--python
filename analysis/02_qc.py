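#!/usr/bin/env python
"""Quality control of the simulated genotypes.

Applies the two-stage protocol (per-individual missingness, then sequential
call-rate / MAF / HWE marker filters), Mendelian cleaning against sires, and
the iterative sire + frequency imputation; writes the cleaned panel, the QC
ledger and the conflict report.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from flockld import io as fio
from flockld.pipeline import PipelineConfig, run_qc_stage

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
IN = os.path.join(BASE, "simulated")
OUT = os.path.join(BASE, "qc")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    g = fio.read_genotypes(
        os.path.join(IN, "sample.ped"), os.path.join(IN, "sample.map"), ref_allele="A"
    )
    ped = fio.read_pedigree(os.path.join(IN, "pedigree.tsv"))
    cfg = PipelineConfig()
    g_clean, ledgers, conflicts = run_qc_stage(g, ped, cfg)

    fio.write_genotypes(
        g_clean, os.path.join(OUT, "clean.ped"), os.path.join(OUT, "clean.map")
    )
    conflicts.to_csv(os.path.join(OUT, "mendelian_conflicts.tsv"), sep="\t", index=False)
    with open(os.path.join(OUT, "qc_ledger.json"), "w") as fh:
        json.dump(ledgers, fh, indent=2)

    mk = ledgers["markers"]
    removed = {s["step"]: s["removed"] for s in mk["steps"]}
    print(
        f"individuals: {ledgers['individuals']['initial']} -> "
        f"{ledgers['individuals']['steps'][-1]['remaining']}; "
        f"markers: {mk['initial']} -> {mk['steps'][-1]['remaining']} "
        f"(call rate {removed.get('call_rate', 0)}, MAF {removed.get('maf', 0)}, "
        f"HWE {removed.get('hwe', 0)}); "
        f"{ledgers['mendelian_conflicts']} Mendelian conflicts blanked"
    )


if __name__ == "__main__":
    main()
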