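"""Rule-based haplotype deduction for a half-sib daughter design.

Only unambiguous transmission logic is applied (the analogue of the first two
steps of pedigree-based phasing programs); every allele written is *forced* by
the genotypes, so deduction is sound by construction.  Sites that would need
linkage information or statistical inference are left missing, and pipelines
that require complete haplotypes take true phase from the simulator instead.
"""

from __future__ import annotations

import numpy as np

from .datamodel import (
    MATERNAL,
    MISSING,
    PATERNAL,
    GenotypeMatrix,
    HaplotypeSet,
    Pedigree,
)


def deduce_haplotypes(g: GenotypeMatrix, ped: Pedigree) -> HaplotypeSet:
    """Deduce paternal/maternal alleles per daughter from her sire's genotype.

    Per daughter and SNP:

    * daughter homozygous -> both origins carry that allele;
    * daughter heterozygous, sire homozygous -> paternal allele is the sire
      allele, maternal the other;
    * daughter heterozygous, sire heterozygous or missing -> both missing.

    Sires contribute their own two haplotypes only where homozygous (no
    within-sire linkage completion).  Individuals without a recorded or
    genotyped sire are phased from their homozygous sites only.
    """
    row_of = {ind: i for i, ind in enumerate(g.individuals)}
    sire_of = ped.sire_of()
    sires_genotyped = {
        s for s in set(sire_of.values()) if s is not None and s in row_of
    }

    H_rows: list[np.ndarray] = []
    carriers: list[tuple[str, str]] = []
    for ind in g.individuals:
        x = g.X[row_of[ind]]
        pat = np.full(g.n_markers, MISSING, dtype=np.int8)
        mat = np.full(g.n_markers, MISSING, dtype=np.int8)
        # homozygous sites phase themselves
        pat[x == 0] = 0
        mat[x == 0] = 0
        pat[x == 2] = 1
        mat[x == 2] = 1
        if ind not in sires_genotyped:
            s = sire_of.get(ind)
            if s is not None and s in row_of:
                sx = g.X[row_of[s]]
                het = x == 1
                forced_ref = het & (sx == 2)
                pat[forced_ref] = 1
                mat[forced_ref] = 0
                forced_alt = het & (sx == 0)
                pat[forced_alt] = 0
                mat[forced_alt] = 1
        H_rows.append(pat)
        carriers.append((ind, PATERNAL))
        H_rows.append(mat)
        carriers.append((ind, MATERNAL))
    return HaplotypeSet(np.vstack(H_rows), carriers, g.markers)


def select_independent_haplotypes(h: HaplotypeSet, ped: Pedigree) -> HaplotypeSet:
    """Keep each sire's two haplotypes plus each daughter's maternal haplotype.

    Dropping the daughters' paternal haplotypes avoids over-representing the
    few sires' chromosomes in LD estimation; the retained set approximates a
    sample of independent chromosomes from the population.
    """
    sires = {s for s in ped.sire_of().values() if s is not None}
    keep = [
        k
        for k, (ind, origin) in enumerate(h.carriers)
        if ind in sires or origin == MATERNAL
    ]
    return HaplotypeSet(h.H[keep], [h.carriers[k] for k in keep], h.markers)
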