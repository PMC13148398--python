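"""VCF 4.2 snapshots of segregating mutations.

One record per segregating mutation on contig ``chr1`` (positions
exported 1-based from the 0-based internal coordinates), with INFO fields
``S`` (selection coefficient), ``H`` (dominance coefficient) and ``OG``
(origin generation), and one unphased genotype column per individual with
ploidy-many alleles (``0/0/1/1`` for a duplex tetraploid). Because every
mutation is a distinct allele, records are biallelic REF/ALT placeholders
(A -> T) even when two records share a position. The simulation
parameters are echoed as ``##podsim_<key>=<value>`` header lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .engine import Population, allele_counts

__all__ = ["write_vcf"]


def write_vcf(pop: Population, path, param_items=()) -> None:
    path = Path(path)
    params = pop.params
    uniq, _ = allele_counts(pop)
    reg = pop.registry
    order = np.argsort(reg.position[uniq], kind="stable") if uniq.size else []
    uniq = uniq[order] if len(order) else uniq

    # genotype dosage matrix: individuals x mutations
    id_to_col = {int(m): j for j, m in enumerate(uniq)}
    dosage = np.zeros((params.N, len(uniq)), dtype=np.int8)
    for i, ind in enumerate(pop.individuals):
        for hap in ind.haplotypes:
            for mid in hap:
                dosage[i, id_to_col[int(mid)]] += 1

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chr1,length={params.L}>\n")
        fh.write('##INFO=<ID=S,Number=1,Type=Float,Description="Selection coefficient">\n')
        fh.write('##INFO=<ID=H,Number=1,Type=Float,Description="Dominance coefficient">\n')
        fh.write('##INFO=<ID=OG,Number=1,Type=Integer,Description="Origin generation">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for key, val in param_items:
            fh.write(f"##podsim_{key}={val}\n")
        samples = "\t".join(f"ind{i}" for i in range(params.N))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, mid in enumerate(uniq):
            mid = int(mid)
            pos1 = int(reg.position[mid]) + 1
            info = (f"S={reg.s[mid]:.6g};H={reg.h[mid]:.6g};"
                    f"OG={int(reg.origin_generation[mid])}")
            gts = "\t".join(
                "/".join(["0"] * (params.ploidy - d) + ["1"] * d)
                for d in dosage[:, j]
            )
            fh.write(f"chr1\t{pos1}\tmut{mid}\tA\tT\t.\t.\t{info}\tGT\t{gts}\n")
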