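import warnings

import pytest

from varprior import SimConfig, run_benchmark, simulate_all

#: compact study system for module-level tests
SMALL_CONFIG = SimConfig(seed=7, n_individuals=40, n_genes=6, gene_length=1500,
                         intergenic_length=600, n_pathogenic=40, n_benign=40,
                         n_disease_train=60, n_population_train=200)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Synthetic input files for a compact study system."""
    out = tmp_path_factory.mktemp("smallsim")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        paths = simulate_all(SMALL_CONFIG, out)
    return paths


@pytest.fixture(scope="session")
def bench():
    """The default-configuration end-to-end benchmark (seed 1), run once."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_benchmark(SimConfig(seed=1))


def write_vcf(path, body_rows, samples=(), csq_format="Allele|Consequence|Gene|Feature|Amino_acids"):
    """Write a small hand-built VCF for I/O tests."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=100000>",
        "##contig=<ID=chr2,length=100000>",
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">',
        f'##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: {csq_format}">',
    ]
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        cols += ["FORMAT"] + list(samples)
    lines.append("\t".join(cols))
    lines.extend(body_rows)
    path.write_text("\n".join(lines) + "\n")
    return path
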