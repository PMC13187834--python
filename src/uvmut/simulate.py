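"""Synthetic mutation-accumulation cohorts with known ground truth.

The generator emulates the UV passaging experiment end to end: a random
diploid genome with genes on both strands; photoproduct channels (CPD, 6-4PP,
TA photoproduct, AC photoproduct) that deposit lesions Poisson-distributed
over their target dinucleotide occurrences on both strands; photolyase
repair as per-strain channel thinning; transcription-coupled repair as
suppression of template-strand lesions inside genes; channel-specific
substitution outcomes (including AC>TT doublets); per-variant depth and
allele-fraction noise; shared pre-existing contaminant variants to exercise
the recurrence filter; and mass-weighted gel lane profiles from Poisson
strand breakage. Every emitted mutation is recorded in a ground-truth table
with its causal channel and lesion strand.

Default rates are scaled to a 200 kb genome so a no-photolyase isolate
accumulates several hundred mutations over 15 passages, matching the shape
(not the genome size) of the real cohorts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from uvmut.genome import (
    COMPLEMENT,
    GeneAnnotation,
    GeneIndex,
    GenomeAssembly,
    revcomp,
)
from uvmut.lesions import LadderCalibration, LaneProfile
from uvmut.variants import DbsRecord, VariantRecord


@dataclass(frozen=True)
class Outcome:
    """One way a lesion at a target dinucleotide resolves into a mutation.

    ``kind`` is ``sbs`` (mutate the base at ``offset`` within the dinucleotide,
    read on the lesion strand, to ``alt``) or ``dbs`` (replace the whole
    dinucleotide with the 2-mer ``alt``). ``prob`` weights within a context.
    """

    kind: str
    alt: str
    prob: float
    offset: int = 0


@dataclass
class ChannelSpec:
    """A photoproduct channel: targets, rates, outcomes and strand bias.

    ``rates`` map target dinucleotides to the expected number of mutagenic
    lesions per occurrence per passage (before repair). ``ts_suppression_factor``
    divides the survival of template-strand lesions inside genes (TC-NER).
    """

    photoproduct: str  # CPD | PP64 | TA_PP | AC_PP | ...
    rates: dict[str, float]
    outcomes: dict[str, list[Outcome]]
    ts_suppression_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.ts_suppression_factor < 1.0:
            raise ValueError("ts_suppression_factor must be >= 1")
        for ctx, rate in self.rates.items():
            if rate < 0:
                raise ValueError(f"negative rate for {ctx}")
            outs = self.outcomes.get(ctx, [])
            if not outs:
                raise ValueError(f"no outcomes for target context {ctx}")
            total = sum(o.prob for o in outs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"outcome probabilities for {ctx} sum to {total}, not 1")


@dataclass
class StrainSpec:
    """Photolyase genotype: fraction of each channel's lesions removed."""

    strain_id: str
    repair_efficiency: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.repair_efficiency.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"repair efficiency for {k} must be in [0, 1]")


def default_channels(
    cpd_rate: float = 2.0e-4,
    pp64_rate: float = 1.6e-4,
    ta_pp_rate: float = 5.0e-5,
    ac_pp_rate: float = 3.0e-5,
    ts_suppression_factor: float = 4.0,
) -> list[ChannelSpec]:
    """Preset channels mirroring the qualitative UV photoproduct biology.

    CPDs target all four pyrimidine dinucleotides and drive mostly C>T (plus
    T>C at CT and T>A/T>G at TT); 6-4PPs favor T>C at the 3' T of TT and C>A
    at TC; the TA photoproduct mutates the A of TA (seen as T>A in NTA on the
    opposite strand); the AC photoproduct yields AC>TT doublets. These are
    presets shaped to the observed spectra, not fitted parameters; the rate
    split makes CPDs responsible for roughly 60% of the no-photolyase burden,
    so the CPD-photolyase strain retains about 40% of it, as in the real
    cohorts.
    """
    return [
        ChannelSpec(
            "CPD",
            {"TT": cpd_rate, "TC": cpd_rate, "CT": cpd_rate, "CC": cpd_rate},
            {
                "TC": [Outcome("sbs", "T", 1.0, offset=1)],  # C>T
                "CC": [Outcome("sbs", "T", 1.0, offset=1)],
                "CT": [Outcome("sbs", "T", 0.4, offset=0), Outcome("sbs", "C", 0.6, offset=1)],
                "TT": [
                    Outcome("sbs", "A", 0.5, offset=1),
                    Outcome("sbs", "G", 0.2, offset=1),
                    Outcome("sbs", "C", 0.3, offset=1),
                ],
            },
            ts_suppression_factor=ts_suppression_factor,
        ),
        ChannelSpec(
            "PP64",
            {"TT": pp64_rate, "TC": pp64_rate, "CC": pp64_rate},
            {
                "TT": [Outcome("sbs", "C", 1.0, offset=1)],  # 3' T>C
                "TC": [Outcome("sbs", "A", 0.5, offset=1), Outcome("sbs", "T", 0.5, offset=1)],
                "CC": [Outcome("sbs", "T", 1.0, offset=1)],
            },
            ts_suppression_factor=ts_suppression_factor,
        ),
        ChannelSpec(
            "TA_PP",
            {"TA": ta_pp_rate},
            {"TA": [Outcome("sbs", "T", 1.0, offset=1)]},  # A>T on the lesion strand
            ts_suppression_factor=ts_suppression_factor,
        ),
        ChannelSpec(
            "AC_PP",
            {"AC": ac_pp_rate},
            {"AC": [Outcome("dbs", "TT", 1.0)]},
            ts_suppression_factor=ts_suppression_factor,
        ),
    ]


def default_strains() -> list[StrainSpec]:
    """The four photolyase genotypes of the passaging design."""
    return [
        StrainSpec("NoPL", {}),
        StrainSpec("CPDPL", {"CPD": 1.0}),
        StrainSpec("64PPPL", {"PP64": 1.0}),
        StrainSpec("BothPL", {"CPD": 1.0, "PP64": 1.0}),
    ]


@dataclass
class SimulationConfig:
    """Study-condition parameters for a synthetic cohort."""

    genome_length_bp: int = 200_000
    gc_fraction: float = 0.38  # yeast-like
    n_genes: int = 120
    gene_length_range: tuple[int, int] = (500, 1500)
    channels: list[ChannelSpec] = field(default_factory=default_channels)
    strains: list[StrainSpec] = field(default_factory=default_strains)
    n_isolates: int = 6  # per strain per replicate
    n_replicates: int = 2
    n_passages: int = 15
    depth_mean: float = 50.0
    af_mean: float = 0.5
    af_sd: float = 0.02
    n_shared_contaminants: int = 2  # recurrent pre-existing variants per replicate
    contig_name: str = "chrS1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length_bp <= 0 or self.n_isolates <= 0 or self.n_replicates <= 0:
            raise ValueError("sizes must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(
    config: SimulationConfig, seed: int | None = None
) -> tuple[GenomeAssembly, list[GeneAnnotation]]:
    """Random genome at the configured GC with non-overlapping genes on both
    strands (~50/50). Deterministic under the seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = np.array(
        [(1 - config.gc_fraction) / 2, config.gc_fraction / 2,
         config.gc_fraction / 2, (1 - config.gc_fraction) / 2]
    )
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=config.genome_length_bp, p=p)])
    genome = GenomeAssembly({config.contig_name: seq}, set(), ploidy=2)

    genes: list[GeneAnnotation] = []
    if config.n_genes > 0:
        lo, hi = config.gene_length_range
        cursor = 0
        gap = max(
            (config.genome_length_bp - config.n_genes * hi) // max(config.n_genes + 1, 1), 10
        )
        for i in range(config.n_genes):
            length = int(rng.integers(lo, hi + 1))
            start = cursor + int(rng.integers(5, gap + 5))
            end = start + length
            if end >= config.genome_length_bp:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneAnnotation(f"gene{i:04d}", config.contig_name, start, end, strand))
            cursor = end
    return genome, genes


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSim:
    """In-memory result of a cohort simulation."""

    variants: list[VariantRecord]
    doublets: list[DbsRecord]
    metadata: pd.DataFrame  # isolate_id, strain_id, replicate_id
    ground_truth: pd.DataFrame
    config: SimulationConfig


def _dinuc_occurrences(genome: GenomeAssembly) -> dict[str, list[tuple[str, int, str]]]:
    """All occurrences of each dinucleotide reading on both strands.

    An entry (contig, i, strand) means the dinucleotide is read at forward
    positions (i, i+1): as-is for '+', reverse complemented for '-'.
    """
    occ: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
    for contig in genome.counted_contigs:
        seq = genome.contigs[contig]
        for i in range(len(seq) - 1):
            d = seq[i : i + 2]
            if "N" in d:
                continue
            occ[d].append((contig, i, "+"))
            occ[revcomp(d)].append((contig, i, "-"))
    return dict(occ)


def _template_suppressed(code: int, lesion_strand: str) -> bool:
    """Is a lesion on ``lesion_strand`` on the template strand of a covering gene?"""
    if code == GeneIndex.PLUS:
        return lesion_strand == "-"
    if code == GeneIndex.MINUS:
        return lesion_strand == "+"
    if code == GeneIndex.AMBIGUOUS:
        return True  # transcribed on both strands
    return False


def simulate_cohort(
    config: SimulationConfig,
    genome: GenomeAssembly,
    genes: list[GeneAnnotation],
    seed: int | None = None,
) -> CohortSim:
    """Simulate per-isolate mutation cohorts for every strain and replicate.

    Per isolate and channel, lesions are drawn Poisson(rate x occurrences x
    passages) over both-strand target-dinucleotide occurrences, thinned by
    the strain's repair efficiency, thinned again by the channel's
    transcription-coupled suppression when the lesion strand is a gene's
    template strand, and converted to substitutions through the channel's
    outcome distribution. Shared contaminant variants are injected into three
    isolates per replicate to exercise the recurrence filter.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    occurrences = _dinuc_occurrences(genome)
    index = GeneIndex(genome, genes)

    variants: list[VariantRecord] = []
    doublets: list[DbsRecord] = []
    truth_rows: list[dict] = []
    meta_rows: list[dict] = []

    for rep in range(1, config.n_replicates + 1):
        rep_id = f"rep{rep}"
        rep_isolates: list[tuple[str, str]] = []
        for strain in config.strains:
            for k in range(1, config.n_isolates + 1):
                iso_id = f"{strain.strain_id}_{rep_id}_iso{k:02d}"
                rep_isolates.append((iso_id, strain.strain_id))
                meta_rows.append(
                    dict(isolate_id=iso_id, strain_id=strain.strain_id, replicate_id=rep_id)
                )
                v, d, t = _simulate_isolate(
                    config, genome, index, occurrences, strain, iso_id, rep_id, rng
                )
                variants.extend(v)
                doublets.extend(d)
                truth_rows.extend(t)

        # shared pre-existing variants: same SNV in 3 isolates of this replicate
        for c in range(config.n_shared_contaminants):
            contig = genome.counted_contigs[int(rng.integers(len(genome.counted_contigs)))]
            seq = genome.contigs[contig]
            while True:
                pos = int(rng.integers(1, len(seq) - 1))
                if seq[pos] in "ACGT":
                    break
            ref = seq[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            chosen = rng.choice(len(rep_isolates), size=min(3, len(rep_isolates)), replace=False)
            for j in chosen:
                iso_id, strain_id = rep_isolates[int(j)]
                depth, af = _qc_noise(config, rng)
                variants.append(
                    VariantRecord(contig, pos, ref, str(alt), depth, af, iso_id, strain_id, rep_id)
                )
                truth_rows.append(
                    dict(
                        contig=contig, position=pos, ref=ref, alt=str(alt), kind="SBS",
                        channel="contaminant", lesion_strand=".", isolate_id=iso_id,
                        strain_id=strain_id, replicate_id=rep_id,
                    )
                )

    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "contig", "position", "ref", "alt", "kind", "channel",
            "lesion_strand", "isolate_id", "strain_id", "replicate_id",
        ],
    )
    return CohortSim(variants, doublets, metadata, truth, config)


def _qc_noise(config: SimulationConfig, rng: np.random.Generator) -> tuple[int, float]:
    depth = int(rng.poisson(config.depth_mean))
    af = float(np.clip(rng.normal(config.af_mean, config.af_sd), 0.0, 1.0))
    return depth, af


def _simulate_isolate(
    config: SimulationConfig,
    genome: GenomeAssembly,
    index: GeneIndex,
    occurrences: dict[str, list[tuple[str, int, str]]],
    strain: StrainSpec,
    iso_id: str,
    rep_id: str,
    rng: np.random.Generator,
) -> tuple[list[VariantRecord], list[DbsRecord], list[dict]]:
    variants: list[VariantRecord] = []
    doublets: list[DbsRecord] = []
    truth: list[dict] = []
    taken: set[tuple[str, int]] = set()  # avoid stacking mutations on one base

    for channel in config.channels:
        survival = 1.0 - strain.repair_efficiency.get(channel.photoproduct, 0.0)
        if survival == 0.0:
            continue
        for ctx, rate in channel.rates.items():
            sites = occurrences.get(ctx, [])
            if not sites:
                continue
            mean = rate * len(sites) * config.n_passages * survival
            n_lesions = rng.poisson(mean)
            if n_lesions == 0:
                continue
            picks = rng.integers(0, len(sites), size=n_lesions)
            for pick in picks:
                contig, i, lesion_strand = sites[int(pick)]
                code = index.strand_code(contig, i)
                if (
                    channel.ts_suppression_factor > 1.0
                    and _template_suppressed(code, lesion_strand)
                    and rng.random() > 1.0 / channel.ts_suppression_factor
                ):
                    continue
                outcome = _draw_outcome(channel.outcomes[ctx], rng)
                if outcome.kind == "sbs":
                    if lesion_strand == "+":
                        pos = i + outcome.offset
                        alt = outcome.alt
                    else:
                        pos = i + (1 - outcome.offset)
                        alt = COMPLEMENT[outcome.alt]
                    ref = genome.base(contig, pos)
                    if ref == alt or (contig, pos) in taken:
                        continue
                    taken.add((contig, pos))
                    depth, af = _qc_noise(config, rng)
                    variants.append(
                        VariantRecord(
                            contig, pos, ref, alt, depth, af, iso_id,
                            strain.strain_id, rep_id,
                        )
                    )
                    truth.append(
                        dict(
                            contig=contig, position=pos, ref=ref, alt=alt, kind="SBS",
                            channel=channel.photoproduct, lesion_strand=lesion_strand,
                            isolate_id=iso_id, strain_id=strain.strain_id, replicate_id=rep_id,
                        )
                    )
                else:  # doublet
                    if lesion_strand == "+":
                        ref_d = genome.contigs[contig][i : i + 2]
                        alt_d = outcome.alt
                    else:
                        ref_d = genome.contigs[contig][i : i + 2]
                        alt_d = revcomp(outcome.alt)
                    if (contig, i) in taken or (contig, i + 1) in taken:
                        continue
                    if ref_d[0] == alt_d[0] or ref_d[1] == alt_d[1]:
                        continue
                    taken.add((contig, i))
                    taken.add((contig, i + 1))
                    depth, af = _qc_noise(config, rng)
                    doublets.append(
                        DbsRecord(
                            contig, i, ref_d, alt_d, iso_id, strain.strain_id,
                            rep_id, depth, af,
                        )
                    )
                    truth.append(
                        dict(
                            contig=contig, position=i, ref=ref_d, alt=alt_d, kind="DBS",
                            channel=channel.photoproduct, lesion_strand=lesion_strand,
                            isolate_id=iso_id, strain_id=strain.strain_id, replicate_id=rep_id,
                        )
                    )
    return variants, doublets, truth


def _draw_outcome(outcomes: list[Outcome], rng: np.random.Generator) -> Outcome:
    if len(outcomes) == 1:
        return outcomes[0]
    probs = np.array([o.prob for o in outcomes])
    return outcomes[int(rng.choice(len(outcomes), p=probs))]


# ---------------------------------------------------------------------------
# Gel lane simulation
# ---------------------------------------------------------------------------

def simulate_lane_profile(
    true_lesions_per_kb: float,
    background_per_kb: float,
    strand_length_kb: float,
    n_strands: int,
    calibration: LadderCalibration,
    seed: int = 0,
    n_bins: int = 400,
) -> tuple[LaneProfile, LaneProfile]:
    """Simulate an (enzyme, no-enzyme) lane pair by Poisson strand breakage.

    Breaks are placed uniformly at the summed rate (lesions + background) on
    each strand for the enzyme lane and at the background rate alone for the
    control lane; fragment masses (intensity proportional to length) are
    binned onto the migration axis given by the ladder calibration.
    """
    if true_lesions_per_kb < 0 or background_per_kb < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    enzyme = _break_and_bin(
        true_lesions_per_kb + background_per_kb, strand_length_kb, n_strands,
        calibration, rng, n_bins, "t4_endoV",
    )
    control = _break_and_bin(
        background_per_kb, strand_length_kb, n_strands, calibration,
        rng, n_bins, "no_enzyme",
    )
    return enzyme, control


def _break_and_bin(
    rate_per_kb: float,
    strand_length_kb: float,
    n_strands: int,
    calibration: LadderCalibration,
    rng: np.random.Generator,
    n_bins: int,
    role: str,
) -> LaneProfile:
    n_breaks = rng.poisson(rate_per_kb * strand_length_kb, size=n_strands)
    fragments: list[np.ndarray] = []
    for k in np.unique(n_breaks):
        strands = int((n_breaks == k).sum())
        if k == 0:
            fragments.append(np.full(strands, strand_length_kb))
            continue
        cuts = np.sort(rng.uniform(0, strand_length_kb, size=(strands, k)), axis=1)
        bounded = np.hstack(
            [np.zeros((strands, 1)), cuts, np.full((strands, 1), strand_length_kb)]
        )
        fragments.append(np.diff(bounded, axis=1).ravel())
    sizes_kb = np.concatenate(fragments)
    sizes_bp = np.maximum(sizes_kb * 1000.0, 1.0)

    migrations = calibration.migration_at(sizes_bp)
    lo, hi = migrations.min(), migrations.max()
    if hi <= lo:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo - 1e-9, hi + 1e-9, n_bins + 1)
    intensity, _ = np.histogram(migrations, bins=edges, weights=sizes_kb)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return LaneProfile(centers, intensity, role)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_cohort(sim: CohortSim, genome: GenomeAssembly, genes: list[GeneAnnotation], outdir: str | Path) -> pd.DataFrame:
    """Write FASTA, BED, per-isolate VCFs, metadata and ground-truth TSVs.

    Returns the metadata table augmented with the written ``vcf_path`` column
    (the sample sheet the pipeline consumes).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "genome.fa", "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(outdir / "genes.bed", "w") as fh:
        for g in genes:
            fh.write(f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")

    by_isolate: dict[str, list] = defaultdict(list)
    for r in sim.variants:
        by_isolate[r.isolate_id].append((r.contig, r.position, r.ref_allele, r.alt_allele, r.depth, r.allele_fraction))
    for d in sim.doublets:
        by_isolate[d.isolate_id].append((d.contig, d.position, d.ref_dinuc, d.alt_dinuc, d.depth, d.allele_fraction))

    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    meta = sim.metadata.copy()
    paths = []
    for iso_id in meta["isolate_id"]:
        path = vcf_dir / f"{iso_id}.vcf"
        _write_vcf(path, genome, iso_id, sorted(by_isolate.get(iso_id, [])))
        paths.append(str(path))
    meta["vcf_path"] = paths

    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    sim.ground_truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    return meta


def _write_vcf(path: Path, genome: GenomeAssembly, sample: str, rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=uvmut-simulate\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for contig, pos, ref, alt, depth, af in rows:
            fh.write(
                f"{contig}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:DP:AF\t0/1:{depth}:{af:.4f}\n"
            )
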