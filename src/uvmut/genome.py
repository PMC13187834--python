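"""Genome and annotation handling, strand conventions and mutation-class encoding.

Single-base substitutions are encoded pyrimidine-centrically (SBS-96): a change
whose reference base is a purine is reported as the reverse complement of the
observed change, so every SNV maps to one of 6 substitution types x 16 flanking
trinucleotide contexts. Doublet substitutions collapse analogously onto a fixed
set of ten canonical reference dinucleotides (78 classes).

Coordinates are 0-based half-open throughout; conversions from 1-based formats
(VCF, GFF3) happen at the I/O edge.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")

#: The six pyrimidine-centric substitution types.
SBS_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical reference dinucleotides for doublet substitutions. Exactly one of
#: {d, revcomp(d)} is in this set for every non-palindromic dinucleotide.
DBS_CANONICAL_REFS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")

_PALINDROMIC_REFS = frozenset(("AT", "CG", "GC", "TA"))


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A, C, G, T, N)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class UncountableContextError(ValueError):
    """Raised when a variant's trinucleotide context contains an ambiguous base."""


# ---------------------------------------------------------------------------
# Class labels
# ---------------------------------------------------------------------------

def _sbs96_labels() -> tuple[str, ...]:
    labels = []
    for sub in SBS_SUBSTITUTIONS:
        ref = sub[0]
        for up in "ACGT":
            for down in "ACGT":
                labels.append(f"{up}[{sub}]{down}")
    return tuple(labels)


def _dbs78_labels() -> tuple[str, ...]:
    labels = []
    for ref in DBS_CANONICAL_REFS:
        alts = sorted(
            a + b
            for a, b in itertools.product("ACGT", repeat=2)
            if a != ref[0] and b != ref[1]
        )
        if ref in _PALINDROMIC_REFS:
            # palindromic refs: alt and revcomp(alt) describe the same doublet
            alts = sorted({min(alt, revcomp(alt)) for alt in alts})
        labels.extend(f"{ref}>{alt}" for alt in alts)
    return tuple(labels)


SBS96_LABELS: tuple[str, ...] = _sbs96_labels()
DBS78_LABELS: tuple[str, ...] = _dbs78_labels()

#: The 32 pyrimidine-central trinucleotides used as census keys.
PYRIMIDINE_TRINUCS: tuple[str, ...] = tuple(
    up + c + down for c in "CT" for up in "ACGT" for down in "ACGT"
)

#: Trinucleotide orderings re-sorted to match SBS96 label order within a type.
assert len(SBS96_LABELS) == 96 and len(DBS78_LABELS) == 78


@dataclass(frozen=True)
class SbsClass:
    """One of the 96 pyrimidine-centric single-base substitution classes."""

    substitution: str  # e.g. "C>T"
    context: str  # pyrimidine-central trinucleotide, e.g. "ACG"

    def __post_init__(self) -> None:
        if self.substitution not in SBS_SUBSTITUTIONS:
            raise ValueError(f"unknown substitution {self.substitution!r}")
        if len(self.context) != 3 or self.context[1] != self.substitution[0]:
            raise ValueError(
                f"context {self.context!r} does not center on {self.substitution[0]!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.context[0]}[{self.substitution}]{self.context[2]}"

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class DbsClass:
    """One of the 78 canonical doublet base substitution classes."""

    ref_dinucleotide: str
    alt_dinucleotide: str

    def __post_init__(self) -> None:
        if self.ref_dinucleotide not in DBS_CANONICAL_REFS:
            raise ValueError(f"{self.ref_dinucleotide!r} is not a canonical ref dinucleotide")

    @property
    def label(self) -> str:
        return f"{self.ref_dinucleotide}>{self.alt_dinucleotide}"

    def __str__(self) -> str:
        return self.label


# ---------------------------------------------------------------------------
# Canonicalization
# ---------------------------------------------------------------------------

def canonicalize_sbs(
    ref_base: str, alt_base: str, upstream_base: str, downstream_base: str
) -> tuple[SbsClass, bool]:
    """Collapse an observed SNV onto its pyrimidine-centric SBS-96 class.

    Returns the class and a flag that is True when the pyrimidine sits on the
    reported (forward) strand, i.e. the change was reported as-is. A purine
    reference forces reverse complementation of both the change and the
    flanking context, and the flag is False.

    Raises :class:`UncountableContextError` if any base in the trinucleotide
    window is N (such variants are excluded from spectra but audited).
    """
    for b in (ref_base, alt_base, upstream_base, downstream_base):
        if b not in "ACGTN" or len(b) != 1:
            raise ValueError(f"invalid base {b!r}")
    if ref_base == alt_base:
        raise ValueError("ref and alt must differ")
    if "N" in (ref_base, alt_base, upstream_base, downstream_base):
        raise UncountableContextError(
            f"ambiguous base in context {upstream_base}[{ref_base}>{alt_base}]{downstream_base}"
        )
    if ref_base in PYRIMIDINES:
        sub = f"{ref_base}>{alt_base}"
        context = upstream_base + ref_base + downstream_base
        return SbsClass(sub, context), True
    sub = f"{COMPLEMENT[ref_base]}>{COMPLEMENT[alt_base]}"
    context = revcomp(upstream_base + ref_base + downstream_base)
    return SbsClass(sub, context), False


def canonicalize_dbs(ref_dinuc: str, alt_dinuc: str) -> DbsClass:
    """Collapse a doublet substitution onto its canonical DBS class.

    The representation (as given, or reverse complemented) whose reference
    dinucleotide lies in :data:`DBS_CANONICAL_REFS` is returned; when the
    reference is its own reverse complement the lexicographically smaller alt
    breaks the tie. Deterministic for all 78 distinct doublet changes.
    """
    for d in (ref_dinuc, alt_dinuc):
        if len(d) != 2 or any(b not in "ACGT" for b in d):
            raise ValueError(f"invalid dinucleotide {d!r}")
    if ref_dinuc[0] == alt_dinuc[0] or ref_dinuc[1] == alt_dinuc[1]:
        raise ValueError(
            f"{ref_dinuc}>{alt_dinuc} does not differ at both positions; not a doublet"
        )
    rc_ref, rc_alt = revcomp(ref_dinuc), revcomp(alt_dinuc)
    if ref_dinuc in _PALINDROMIC_REFS:
        return DbsClass(ref_dinuc, min(alt_dinuc, rc_alt))
    if ref_dinuc in DBS_CANONICAL_REFS:
        return DbsClass(ref_dinuc, alt_dinuc)
    return DbsClass(rc_ref, rc_alt)


# ---------------------------------------------------------------------------
# Genome assembly and gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GenomeAssembly:
    """Contig sequences with an excluded-contig set and ploidy.

    ``haploid_size_kb`` is the total length of non-excluded contigs in kb and
    is the genome-size factor used for lesion-total arithmetic.
    """

    contigs: dict[str, str]
    excluded_contigs: set[str] = field(default_factory=set)
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValueError("ploidy must be a positive integer")
        self.contigs = {name: seq.upper() for name, seq in self.contigs.items()}
        self.excluded_contigs = set(self.excluded_contigs)
        if self.haploid_size_kb <= 0:
            raise ValueError("genome has no non-excluded sequence")
        self._codes: dict[str, np.ndarray] = {}

    @property
    def haploid_size_kb(self) -> float:
        return (
            sum(len(s) for n, s in self.contigs.items() if n not in self.excluded_contigs)
            / 1000.0
        )

    @property
    def counted_contigs(self) -> list[str]:
        return [n for n in self.contigs if n not in self.excluded_contigs]

    def base(self, contig: str, pos: int) -> str:
        return self.contigs[contig][pos]

    def context(self, contig: str, pos: int) -> tuple[str, str]:
        """Flanking (upstream, downstream) bases of ``pos``; 'N' beyond contig ends."""
        seq = self.contigs[contig]
        up = seq[pos - 1] if pos >= 1 else "N"
        down = seq[pos + 1] if pos + 1 < len(seq) else "N"
        return up, down

    def codes(self, contig: str) -> np.ndarray:
        """Sequence as uint8 codes (A=0, C=1, G=2, T=3, other=4), cached."""
        if contig not in self._codes:
            raw = np.frombuffer(self.contigs[contig].encode("ascii"), dtype=np.uint8)
            lut = np.full(256, 4, dtype=np.uint8)
            for i, b in enumerate(b"ACGT"):
                lut[b] = i
            self._codes[contig] = lut[raw]
        return self._codes[contig]


@dataclass(frozen=True)
class GeneAnnotation:
    """A transcribed gene: 0-based half-open interval with a coding strand."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end}) for {self.gene_id}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def load_genome(
    fasta_path: str | Path,
    excluded_contig_names: set[str] | None = None,
    ploidy: int = 2,
) -> GenomeAssembly:
    """Load a FASTA genome; excluded contigs (e.g. the mitochondrion) are kept
    out of size and census calculations and their variants are filtered out."""
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path), rebuild=True, build_index=True)
    contigs = {name: str(fasta[name][:]).upper() for name in fasta.keys()}
    if not contigs:
        raise ValueError(f"no sequences in {fasta_path}")
    return GenomeAssembly(contigs, set(excluded_contig_names or ()), ploidy)


def load_genes(path: str | Path) -> list[GeneAnnotation]:
    """Load gene annotation from 6-column BED or GFF3 (by extension).

    BED is 0-based half-open as stored; GFF3 coordinates are converted from
    1-based inclusive. GFF3 features of type ``gene`` are used.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _load_gff3(path)
    return _load_bed(path)


def _load_bed(path: Path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"BED line has <6 columns (strand required): {line!r}")
            genes.append(
                GeneAnnotation(parts[3], parts[0], int(parts[1]), int(parts[2]), parts[5])
            )
    return genes


def _load_gff3(path: Path) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneAnnotation(gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand))
    return genes


# ---------------------------------------------------------------------------
# Gene strand index
# ---------------------------------------------------------------------------

class GeneIndex:
    """Per-contig strand coverage for fast NTS/TS assignment.

    Coverage codes: 0 intergenic, 1 covered by +-strand gene(s) only,
    2 by −-strand gene(s) only, 3 by genes on both strands (ambiguous —
    excluded from strand censuses and strand assignment).
    """

    INTERGENIC, PLUS, MINUS, AMBIGUOUS = 0, 1, 2, 3

    def __init__(self, genome: GenomeAssembly, genes: list[GeneAnnotation]):
        self.genome = genome
        self.genes = list(genes)
        self._coverage: dict[str, np.ndarray] = {}
        for name in genome.counted_contigs:
            self._coverage[name] = np.zeros(len(genome.contigs[name]), dtype=np.uint8)
        for g in self.genes:
            if g.contig not in self._coverage:
                continue
            cov = self._coverage[g.contig]
            if g.end > len(cov):
                raise ValueError(f"gene {g.gene_id} extends beyond contig {g.contig}")
            bit = self.PLUS if g.strand == "+" else self.MINUS
            cov[g.start : g.end] |= bit

    def coverage(self, contig: str) -> np.ndarray:
        return self._coverage[contig]

    def strand_code(self, contig: str, pos: int) -> int:
        cov = self._coverage.get(contig)
        if cov is None:
            return self.INTERGENIC
        return int(cov[pos])


# ---------------------------------------------------------------------------
# Context censuses
# ---------------------------------------------------------------------------

@dataclass
class ContextCensus:
    """Occurrence counts of the 32 pyrimidine-central trinucleotides on a
    designated strand set."""

    counts: dict[str, int]
    strand_mode: str

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, key: str) -> int:
        return self.counts.get(key, 0)


# lookup tables: trinuc code (64) -> collapsed pyrimidine-central trinuc string
_TRINUCS64 = ["".join(t) for t in itertools.product("ACGT", repeat=3)]
_COLLAPSED64 = [t if t[1] in PYRIMIDINES else revcomp(t) for t in _TRINUCS64]
_CENTER_IS_PYR64 = np.array([t[1] in PYRIMIDINES for t in _TRINUCS64])


def _window_keys(codes: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trinucleotide codes (0..63) for windows centered at ``centers``.

    Returns (keys, valid_mask); windows touching a non-ACGT base or a contig
    end are invalid.
    """
    n = len(codes)
    inside = (centers >= 1) & (centers <= n - 2)
    centers = centers[inside]
    up, mid, down = codes[centers - 1], codes[centers], codes[centers + 1]
    valid = (up < 4) & (mid < 4) & (down < 4)
    keys = up.astype(np.int64) * 16 + mid * 4 + down
    return keys[valid], centers[valid]


def context_census(
    genome: GenomeAssembly,
    regions: list[GeneAnnotation] | None = None,
    strand_mode: str = "genome_both_strands",
) -> ContextCensus:
    """Census of pyrimidine-central trinucleotides on the requested strand(s).

    ``genome_both_strands`` counts every valid window on both strands of every
    non-excluded contig (restricted to ``regions`` if given). ``gene_NTS``
    counts windows centered in gene bodies as read on the gene's coding
    strand; ``gene_TS`` on its complement. Positions covered by genes on both
    strands are ambiguous and excluded from the gene-strand modes. Windows
    containing N are excluded everywhere.
    """
    if strand_mode not in {"genome_both_strands", "gene_NTS", "gene_TS"}:
        raise ValueError(f"unknown strand_mode {strand_mode!r}")

    counts = dict.fromkeys(PYRIMIDINE_TRINUCS, 0)

    if strand_mode == "genome_both_strands":
        if regions is None:
            spans = [(c, 0, len(genome.contigs[c])) for c in genome.counted_contigs]
        else:
            spans = [(r.contig, r.start, r.end) for r in regions]
        for contig, start, end in spans:
            if contig not in genome.contigs:
                raise ValueError(f"region contig {contig!r} not in genome")
            if not 0 <= start <= end <= len(genome.contigs[contig]):
                raise ValueError(f"region [{start},{end}) outside contig {contig}")
            codes = genome.codes(contig)
            keys, _ = _window_keys(codes, np.arange(start, end))
            for k, n in zip(*np.unique(keys, return_counts=True)):
                counts[_COLLAPSED64[k]] += 2 * int(n)  # each window exists on both strands
        return ContextCensus(counts, strand_mode)

    if regions is None:
        raise ValueError("gene-strand censuses require gene regions")
    nts, ts = gene_strand_census(genome, regions)
    return nts if strand_mode == "gene_NTS" else ts


def gene_strand_census(
    genome: GenomeAssembly, genes: list[GeneAnnotation]
) -> tuple[ContextCensus, ContextCensus]:
    """NTS and TS trinucleotide censuses over gene bodies in one pass.

    The NTS is the gene's annotated (coding) strand. A pyrimidine-central
    window read on the forward strand lies on the NTS of a + gene and on the
    TS of a − gene; a purine-centered forward window contributes its reverse
    complement to the opposite strand set.
    """
    nts = dict.fromkeys(PYRIMIDINE_TRINUCS, 0)
    ts = dict.fromkeys(PYRIMIDINE_TRINUCS, 0)
    index = GeneIndex(genome, genes)
    for contig in genome.counted_contigs:
        codes = genome.codes(contig)
        cov = index.coverage(contig)
        for strand_bit, strand in ((GeneIndex.PLUS, "+"), (GeneIndex.MINUS, "-")):
            centers = np.nonzero(cov == strand_bit)[0]
            keys, _ = _window_keys(codes, centers)
            for k, n in zip(*np.unique(keys, return_counts=True)):
                trinuc = _COLLAPSED64[k]
                pyr_on_forward = bool(_CENTER_IS_PYR64[k])
                on_coding = pyr_on_forward == (strand == "+")
                (nts if on_coding else ts)[trinuc] += int(n)
    return ContextCensus(nts, "gene_NTS"), ContextCensus(ts, "gene_TS")


def dinuc_strand_census(
    genome: GenomeAssembly, genes: list[GeneAnnotation]
) -> tuple[dict[str, int], dict[str, int]]:
    """Canonical-dinucleotide abundances on the NTS and TS of gene bodies.

    Each genomic dinucleotide site is read once per strand: the coding-strand
    reading feeds the NTS census and the template-strand reading the TS
    census, keeping only readings whose dinucleotide is canonical. Palindromic
    dinucleotides (AT, CG, GC, TA) therefore count on both strands at each
    site. Sites whose first position is gene-ambiguous are excluded, as are
    dinucleotides straddling a gene/coverage boundary.
    """
    nts = dict.fromkeys(DBS_CANONICAL_REFS, 0)
    ts = dict.fromkeys(DBS_CANONICAL_REFS, 0)
    index = GeneIndex(genome, genes)
    for contig in genome.counted_contigs:
        codes = genome.codes(contig)
        cov = index.coverage(contig)
        n = len(codes)
        if n < 2:
            continue
        first, second = codes[:-1], codes[1:]
        valid = (first < 4) & (second < 4) & (cov[:-1] == cov[1:])
        for strand_bit, strand in ((GeneIndex.PLUS, "+"), (GeneIndex.MINUS, "-")):
            sel = valid & (cov[:-1] == strand_bit)
            keys = first[sel].astype(np.int64) * 4 + second[sel]
            for k, cnt in zip(*np.unique(keys, return_counts=True)):
                dinuc = "ACGT"[k // 4] + "ACGT"[k % 4]
                coding = dinuc if strand == "+" else revcomp(dinuc)
                template = revcomp(coding)
                if coding in nts:
                    nts[coding] += int(cnt)
                if template in ts:
                    ts[template] += int(cnt)
    return nts, ts
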