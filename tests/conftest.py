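import numpy as np
import pytest

from uvmut.genome import GeneAnnotation, GenomeAssembly
from uvmut.lesions import HINDIII_LAMBDA_BANDS, calibrate_ladder
from uvmut.simulate import SimulationConfig, generate_genome, simulate_cohort


@pytest.fixture
def toy_genome():
    """Two-contig genome with a handcrafted sequence and a mitochondrion."""
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=600)])
    return GenomeAssembly(
        {"chrI": seq, "chrM": "ACGT" * 25}, excluded_contigs={"chrM"}, ploidy=2
    )


@pytest.fixture
def toy_genes():
    return [
        GeneAnnotation("gA", "chrI", 50, 200, "+"),
        GeneAnnotation("gB", "chrI", 250, 400, "-"),
    ]


@pytest.fixture(scope="session")
def ladder_calibration():
    """Log-linear gel: migration grows linearly in -log10(size)."""
    bands = [(s, 10.0 + 40.0 * (np.log10(23130) - np.log10(s))) for s in HINDIII_LAMBDA_BANDS]
    return calibrate_ladder(bands)


@pytest.fixture(scope="session")
def sim_bundle():
    """One medium synthetic cohort shared across tests (read-only)."""
    config = SimulationConfig(genome_length_bp=120_000, n_genes=80, n_isolates=4, seed=11)
    genome, genes = generate_genome(config)
    sim = simulate_cohort(config, genome, genes)
    return config, genome, genes, sim


def write_vcf(path, rows, sample="iso1", contigs=(("chrI", 1000), ("chrM", 100))):
    """Minimal VCF writer for fixtures: rows of (contig, pos1, ref, alt, dp, af)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">\n')
        fh.write('##FORMAT=<ID=AF,Number=1,Type=Float,Description="fraction">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for contig, pos1, ref, alt, dp, af in rows:
            fh.write(f"{contig}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:DP:AF\t0/1:{dp}:{af}\n")
    return path
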