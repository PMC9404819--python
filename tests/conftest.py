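import pytest

from locuskit.locus_model import GeneModel, LocusWindow, build_window
from locuskit.synthetic_data import ScenarioConfig, generate
from locuskit.variant_catalog import Variant


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic scenario (183 samples, minus-strand 3-exon gene)."""
    return generate(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def scenario_files(tmp_path_factory):
    from locuskit.synthetic_data import make_locus

    out = tmp_path_factory.mktemp("scenario")
    return make_locus(ScenarioConfig(seed=1), out)


@pytest.fixture
def toy_plus_gene():
    """Plus-strand 2-exon gene on a 400-base toy chromosome.

    exon1 41..100 (CDS from 61), intron 101..160, exon2 161..260
    (CDS to 200, then 3' UTR).  CDS length 40 + 40 + ... = 81? laid out so
    the CDS is 61..100 + 161..201 = 40 + 41 = 81 bases (27 codons).
    """
    return GeneModel(
        gene_id="toy+",
        chrom="t",
        strand="+",
        exons=((41, 100), (161, 260)),
        cds_start=61,
        cds_end=201,
    )


def make_snp(chrom, pos, ref, alt, genotypes):
    samples = tuple(f"S{i}" for i in range(len(genotypes)))
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt,
                   genotypes=tuple(genotypes), samples=samples)


@pytest.fixture
def make_variant():
    return make_snp
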