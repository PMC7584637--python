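import numpy as np
import pytest

from gnselect import SnpMatrix


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n##contig=<ID=2>\n"
)


def make_vcf(path, records, samples=("s1", "s2")):
    """Write a minimal VCF; records are (chrom, pos, ref, alt, [gt...])."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return path


@pytest.fixture
def vcf_factory(tmp_path):
    def _make(records, samples=("s1", "s2"), name="test.vcf"):
        return make_vcf(tmp_path / name, records, samples)
    return _make


def random_panel(rng, n_sites=50, n_samples=20, chrom="1",
                 missing_rate=0.0) -> SnpMatrix:
    """A random (not population-genetic) panel for filter/IO tests."""
    pos = np.sort(rng.choice(np.arange(1, 10 * n_sites + 1), size=n_sites,
                             replace=False))
    geno = rng.integers(0, 2, size=(n_sites, n_samples)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = -1
    return SnpMatrix(
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=pos,
        ref_allele=np.full(n_sites, "A", dtype=object),
        alt_allele=np.full(n_sites, "G", dtype=object),
        genotypes=geno,
        sample_ids=[f"s{i}" for i in range(n_samples)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
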