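"""Per-isolate variant input and the cohort filtering rules.

Filtering mirrors the mutation-accumulation QC used for photolyase passaging
cohorts: depth >= 10 reads, allele fraction >= 45% (inclusive thresholds),
mitochondrial exclusion, and removal of any identical mutation seen in more
than two isolates within a passaging replicate (pre-existing variants, not
UV-induced ones). Adjacent filtered SNVs merge into doublet substitutions;
runs of three or more adjacent SNVs are set aside as multi-nucleotide events.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class VariantRecord:
    """One called single-base substitution with provenance and QC fields."""

    contig: str
    position: int  # 0-based
    ref_allele: str
    alt_allele: str
    depth: int
    allele_fraction: float
    isolate_id: str
    strain_id: str
    replicate_id: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError("allele fraction must be in [0, 1]")

    @property
    def identity_key(self) -> tuple:
        return (self.contig, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class DbsRecord:
    """A doublet substitution: two adjacent substituted bases in one isolate."""

    contig: str
    position: int  # 0-based position of the first base
    ref_dinuc: str
    alt_dinuc: str
    isolate_id: str
    strain_id: str
    replicate_id: str
    depth: int = 0
    allele_fraction: float = 1.0

    @property
    def identity_key(self) -> tuple:
        return (self.contig, self.position, self.ref_dinuc, self.alt_dinuc)


@dataclass
class FilterConfig:
    """Cohort filtering thresholds (all inclusive)."""

    min_depth: int = 10
    min_allele_fraction: float = 0.45
    max_recurrence: int = 2
    excluded_contigs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0.0 <= self.min_allele_fraction <= 1.0:
            raise ValueError("min_allele_fraction must be in [0, 1]")
        if self.max_recurrence < 1:
            raise ValueError("max_recurrence must be >= 1")
        self.excluded_contigs = set(self.excluded_contigs)


class FilterAudit:
    """Counts of records removed per rule, plus retained; totals reconcile."""

    RULES = (
        "depth",
        "allele_fraction",
        "excluded_contig",
        "recurrence",
        "uncountable_context",
        "indel",
        "multi_allelic",
        "long_mnv",
        "multi_nucleotide_run",
        "merged_into_doublet",
    )

    def __init__(self) -> None:
        self.removed: Counter[str] = Counter()
        self.retained: int = 0

    @property
    def input_count(self) -> int:
        return self.retained + sum(self.removed.values())

    def merge(self, other: "FilterAudit") -> "FilterAudit":
        self.removed.update(other.removed)
        self.retained += other.retained
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "removed": self.removed.get(r, 0)} for r in self.RULES]
        rows.append({"rule": "retained", "removed": self.retained})
        return pd.DataFrame(rows)

    def __repr__(self) -> str:
        parts = ", ".join(f"{k}={v}" for k, v in sorted(self.removed.items()) if v)
        return f"FilterAudit(retained={self.retained}, removed=[{parts}])"


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV with columns isolate_id, strain_id, replicate_id, vcf_path."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"isolate_id", "strain_id", "replicate_id", "vcf_path"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def _resolve_qc(rec, sample, depth_field: str, af_field: str) -> tuple[int, float]:
    """Pull depth and allele fraction from FORMAT (preferred) or INFO."""

    def lookup(field_name):
        if sample is not None and field_name in sample and sample[field_name] is not None:
            return sample[field_name]
        if field_name in rec.info:
            return rec.info[field_name]
        return None

    depth = lookup(depth_field)
    af = lookup(af_field)
    if depth is None or af is None:
        raise ValueError(
            f"record {rec.chrom}:{rec.pos} missing {depth_field!r}/{af_field!r} "
            "in FORMAT and INFO"
        )
    if isinstance(depth, (tuple, list)):
        depth = depth[0]
    if isinstance(af, (tuple, list)):
        af = af[0]
    # VCF floats are single precision; round so 0.45 on disk is 0.45, not
    # 0.44999998, keeping the inclusive threshold exact at its boundary
    return int(depth), round(float(af), 6)


def read_variants(
    vcf_path: str | Path,
    metadata_row: Mapping[str, str],
    depth_field: str = "DP",
    af_field: str = "AF",
) -> tuple[list[VariantRecord], list[DbsRecord], FilterAudit]:
    """Read one isolate's VCF into SNV records and doublet candidates.

    SNVs become :class:`VariantRecord`; length-2 MNVs become direct
    :class:`DbsRecord` candidates (carrying the same QC fields); indels and
    longer MNVs are set aside in the audit. Multi-allelic records are audited
    rather than guessed at.
    """
    import pysam

    iso = metadata_row["isolate_id"]
    strain = metadata_row["strain_id"]
    rep = metadata_row["replicate_id"]

    snvs: list[VariantRecord] = []
    doublets: list[DbsRecord] = []
    audit = FilterAudit()

    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                audit.removed["multi_allelic"] += 1
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            sample = rec.samples[0] if len(rec.samples) else None
            if len(ref) == 1 and len(alt) == 1:
                depth, af = _resolve_qc(rec, sample, depth_field, af_field)
                snvs.append(
                    VariantRecord(rec.chrom, rec.pos - 1, ref, alt, depth, af, iso, strain, rep)
                )
                audit.retained += 1
            elif len(ref) == 2 and len(alt) == 2 and ref[0] != alt[0] and ref[1] != alt[1]:
                depth, af = _resolve_qc(rec, sample, depth_field, af_field)
                doublets.append(
                    DbsRecord(rec.chrom, rec.pos - 1, ref, alt, iso, strain, rep, depth, af)
                )
                audit.retained += 1
            elif len(ref) == len(alt):
                audit.removed["long_mnv"] += 1
            else:
                audit.removed["indel"] += 1
    return snvs, doublets, audit


def read_cohort(
    metadata: pd.DataFrame, depth_field: str = "DP", af_field: str = "AF"
) -> tuple[list[VariantRecord], list[DbsRecord], FilterAudit]:
    """Read every isolate VCF listed in a sample sheet."""
    all_snvs: list[VariantRecord] = []
    all_dbs: list[DbsRecord] = []
    audit = FilterAudit()
    for _, row in metadata.iterrows():
        snvs, dbs, a = read_variants(row["vcf_path"], row, depth_field, af_field)
        all_snvs.extend(snvs)
        all_dbs.extend(dbs)
        audit.merge(a)
    return all_snvs, all_dbs, audit


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def apply_site_filters(records: Sequence, config: FilterConfig) -> tuple[list, FilterAudit]:
    """Keep records with depth >= min_depth, AF >= min_allele_fraction and a
    non-excluded contig. Pure per-record predicate; order-independent."""
    kept = []
    audit = FilterAudit()
    for r in records:
        if r.contig in config.excluded_contigs:
            audit.removed["excluded_contig"] += 1
        elif r.depth < config.min_depth:
            audit.removed["depth"] += 1
        elif r.allele_fraction < config.min_allele_fraction:
            audit.removed["allele_fraction"] += 1
        else:
            kept.append(r)
            audit.retained += 1
    return kept, audit


def apply_recurrence_filter(
    records: Sequence, max_recurrence: int = 2
) -> tuple[list, FilterAudit]:
    """Remove mutations recurring in more than ``max_recurrence`` isolates
    within a passaging replicate.

    All strains passaged within a replicate experiment are pooled; the
    identity key is (contig, position, ref, alt) and distinct isolates are
    counted, so the same mutation in two isolates survives but in three or
    more is removed everywhere in that replicate. Cross-replicate recurrence
    is not filtered.
    """
    isolates_per_key: dict[tuple, set[str]] = defaultdict(set)
    for r in records:
        isolates_per_key[(r.replicate_id,) + r.identity_key].add(r.isolate_id)

    kept = []
    audit = FilterAudit()
    for r in records:
        if len(isolates_per_key[(r.replicate_id,) + r.identity_key]) > max_recurrence:
            audit.removed["recurrence"] += 1
        else:
            kept.append(r)
            audit.retained += 1
    return kept, audit


def call_doublets(
    snvs: Sequence[VariantRecord],
    direct_doublets: Sequence[DbsRecord] = (),
) -> tuple[list[DbsRecord], list[VariantRecord], FilterAudit]:
    """Merge adjacent filtered SNVs within an isolate into doublets.

    Exactly two adjacent SNVs become one :class:`DbsRecord`; runs of three or
    more adjacent SNVs are multi-nucleotide events, excluded from both SBS
    and DBS spectra but audited (one removal entry per constituent SNV).
    Direct length-2 MNV candidates pass through unchanged. The audit counts
    SNV dispositions: retained = SNVs left as singletons.
    """
    by_isolate: dict[tuple[str, str], list[VariantRecord]] = defaultdict(list)
    for r in snvs:
        by_isolate[(r.isolate_id, r.contig)].append(r)

    doublets: list[DbsRecord] = list(direct_doublets)
    singles: list[VariantRecord] = []
    audit = FilterAudit()

    for group in by_isolate.values():
        group.sort(key=lambda r: r.position)
        run: list[VariantRecord] = []
        for r in group + [None]:  # sentinel flushes the last run
            if run and (r is None or r.position != run[-1].position + 1):
                if len(run) == 1:
                    singles.append(run[0])
                    audit.retained += 1
                elif len(run) == 2:
                    a, b = run
                    audit.removed["merged_into_doublet"] += 2
                    doublets.append(
                        DbsRecord(
                            a.contig,
                            a.position,
                            a.ref_allele + b.ref_allele,
                            a.alt_allele + b.alt_allele,
                            a.isolate_id,
                            a.strain_id,
                            a.replicate_id,
                            min(a.depth, b.depth),
                            min(a.allele_fraction, b.allele_fraction),
                        )
                    )
                else:
                    audit.removed["multi_nucleotide_run"] += len(run)
                run = []
            if r is not None:
                run.append(r)
    return doublets, singles, audit


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Flat TSV-ready table of variant or doublet records."""
    rows = []
    for r in records:
        if isinstance(r, VariantRecord):
            rows.append(
                dict(
                    contig=r.contig, position=r.position, ref=r.ref_allele,
                    alt=r.alt_allele, kind="SBS", depth=r.depth,
                    allele_fraction=r.allele_fraction, isolate_id=r.isolate_id,
                    strain_id=r.strain_id, replicate_id=r.replicate_id,
                )
            )
        else:
            rows.append(
                dict(
                    contig=r.contig, position=r.position, ref=r.ref_dinuc,
                    alt=r.alt_dinuc, kind="DBS", depth=r.depth,
                    allele_fraction=r.allele_fraction, isolate_id=r.isolate_id,
                    strain_id=r.strain_id, replicate_id=r.replicate_id,
                )
            )
    return pd.DataFrame(rows)
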