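"""Shared fixtures: small synthetic genome bundles built at test time."""

import numpy as np
import pandas as pd
import pytest

import mutspectra as ms
from mutspectra import simulate as sim


@pytest.fixture(scope="session")
def tree13() -> str:
    return sim.DEFAULT_TREE


@pytest.fixture(scope="session")
def sqrt_cophenetic(tree13):
    return ms.cophenetic_matrix(tree13, sqrt=True)


@pytest.fixture(scope="session")
def genome_bundle(tmp_path_factory):
    """A 30 kb reference/ancestral pair with masks, regions and 3-mer targets."""
    out = tmp_path_factory.mktemp("bundle")
    ref, anc, masks = sim.simulate_reference_and_ancestral(30_000, seed=101)
    sim.write_fasta(out / "ref.fa", {"chr1": ref})
    sim.write_fasta(out / "anc.fa", {"chr1": anc})
    sim.write_bed(out / "mask.bed", "chr1", masks)
    regions = ms.load_masks_and_subtract(str(out / "ref.fa"),
                                         [str(out / "mask.bed")])
    targets3 = ms.count_targets(str(out / "anc.fa"), regions, 3, label="toy")
    return {"dir": out, "ref": ref, "anc": anc, "masks": masks,
            "regions": regions, "targets3": targets3}


@pytest.fixture(scope="session")
def uniform_targets3():
    """Flat shared ancestral 3-mer target counts for statistics tests."""
    schema = ms.SpectrumSchema(3)
    kmers = sorted({ms.MutationType.from_label(l).ancestral_kmer
                    for l in schema.labels})
    return ms.TargetCounts("shared", 3,
                           pd.Series(10_000, index=kmers, dtype=np.int64))


def write_vcf(path, records, samples, chrom="chr1", length=1000):
    """Hand-rolled fixture VCF: records are (pos1, ref, alt, gts)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FILTER=<ID=PASS,Description="ok">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for pos, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return path
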