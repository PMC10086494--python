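import numpy as np
import pytest

from foundertrace.haplotype_io import HaplotypeMatrix, Site
from foundertrace.simulate import FounderSimConfig, simulate_founder_cohort
from foundertrace.variants import ReferenceWindow


@pytest.fixture
def toy_window():
    return ReferenceWindow("1", 1, "ACGTACGT")


@pytest.fixture
def vcf_writer(tmp_path):
    """Write a minimal phased VCF from (chrom, pos, ref, alt, genotypes) rows."""

    def _write(rows, samples, name="toy.vcf"):
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            )
            chroms = dict.fromkeys(r[0] for r in rows)
            for c in chroms:
                fh.write(f"##contig=<ID={c},length=1000000>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(samples)
                + "\n"
            )
            for chrom, pos, ref, alt, gts in rows:
                fh.write(
                    f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )
        return str(path)

    return _write


def tiny_matrix(hap_rows, positions, samples=None):
    """HaplotypeMatrix from a list of haplotype rows (2 per sample)."""
    alleles = np.asarray(hap_rows, dtype=np.int8)
    n = alleles.shape[0] // 2
    samples = samples or [f"s{i + 1}" for i in range(n)]
    sites = []
    for j, pos in enumerate(positions):
        col = alleles[:, j]
        obs = col != -1
        freq = float(col[obs].mean()) if obs.any() else 0.0
        sites.append(Site("1", int(pos), "A", "C", freq, 1 - obs.mean()))
    return HaplotypeMatrix(samples=samples, alleles=alleles, sites=sites)


@pytest.fixture(scope="session")
def small_cohort():
    """A small founder cohort shared across tests: 5 carriers, 200
    background samples, 120 common sites, 4 planted tags, g=10."""
    config = FounderSimConfig(
        n_carriers=5,
        n_background=200,
        n_common_sites=120,
        n_rare_tags=4,
        rare_tag_freq=0.01,
    )
    matrix, truth = simulate_founder_cohort(config, seed=7)
    return config, matrix, truth
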