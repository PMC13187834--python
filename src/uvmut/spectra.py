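"""Per-isolate SBS-96 and DBS mutation-spectrum matrices and summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from uvmut.genome import (
    DBS78_LABELS,
    SBS96_LABELS,
    GenomeAssembly,
    UncountableContextError,
    canonicalize_dbs,
    canonicalize_sbs,
)
from uvmut.variants import DbsRecord, FilterAudit, VariantRecord


class ReferenceMismatchError(ValueError):
    """Variant reference allele disagrees with the genome sequence.

    A hard error rather than a skip: it almost always means the VCF was
    called against a different genome build than the one supplied.
    """


@dataclass
class SpectrumMatrix:
    """Isolates x mutation-class count matrix with summary statistics.

    ``counts`` is indexed by isolate_id with one column per class label
    (96 SBS or 78 DBS classes); ``isolate_meta`` maps each isolate to its
    strain and replicate. SEM uses the n-1 sample standard deviation and is
    undefined (NaN) for fewer than two isolates.
    """

    counts: pd.DataFrame
    isolate_meta: pd.DataFrame  # index isolate_id; columns strain_id, replicate_id
    audit: FilterAudit = field(default_factory=FilterAudit)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.isolate_meta.index):
            raise ValueError("counts and isolate_meta must share the isolate index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def class_labels(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def isolate_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_isolates(self) -> int:
        return len(self.counts)

    @property
    def per_isolate_total(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def per_class_mean(self) -> pd.Series:
        return self.counts.mean(axis=0)

    @property
    def per_class_sem(self) -> pd.Series:
        if self.n_isolates < 2:
            return pd.Series(np.nan, index=self.counts.columns)
        return self.counts.std(axis=0, ddof=1) / np.sqrt(self.n_isolates)

    def subset(self, strain_id: str | None = None, replicate_id: str | None = None) -> "SpectrumMatrix":
        mask = pd.Series(True, index=self.counts.index)
        if strain_id is not None:
            mask &= self.isolate_meta["strain_id"] == strain_id
        if replicate_id is not None:
            mask &= self.isolate_meta["replicate_id"] == replicate_id
        return SpectrumMatrix(self.counts.loc[mask], self.isolate_meta.loc[mask], self.audit)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.T  # classes x isolates, as figures tabulate them
        out.index.name = "class"
        out.to_csv(path, sep="\t")


def _isolate_meta(
    records: Iterable, isolates: pd.DataFrame | Sequence[tuple[str, str, str]] | None
) -> pd.DataFrame:
    if isolates is None:
        seen: dict[str, tuple[str, str]] = {}
        for r in records:
            seen.setdefault(r.isolate_id, (r.strain_id, r.replicate_id))
        meta = pd.DataFrame(
            [(iso, s, rep) for iso, (s, rep) in seen.items()],
            columns=["isolate_id", "strain_id", "replicate_id"],
        )
    elif isinstance(isolates, pd.DataFrame):
        meta = isolates[["isolate_id", "strain_id", "replicate_id"]].copy()
    else:
        meta = pd.DataFrame(isolates, columns=["isolate_id", "strain_id", "replicate_id"])
    return meta.set_index("isolate_id")


def build_sbs_matrix(
    variants: Sequence[VariantRecord],
    genome: GenomeAssembly,
    isolates: pd.DataFrame | Sequence[tuple[str, str, str]] | None = None,
) -> SpectrumMatrix:
    """Count filtered SNVs into the 96 pyrimidine-centric classes per isolate.

    ``isolates`` (a sample sheet or (isolate, strain, replicate) triples)
    fixes the row set so isolates with zero surviving mutations keep all-zero
    rows; without it rows are derived from the variants present. Variants
    whose trinucleotide window contains N are excluded and audited. A variant
    whose reference allele disagrees with the genome raises
    :class:`ReferenceMismatchError`.
    """
    meta = _isolate_meta(variants, isolates)
    counts = pd.DataFrame(0, index=meta.index, columns=list(SBS96_LABELS), dtype=int)
    audit = FilterAudit()
    for v in variants:
        genome_base = genome.base(v.contig, v.position)
        if genome_base != v.ref_allele:
            raise ReferenceMismatchError(
                f"{v.contig}:{v.position}: VCF ref {v.ref_allele!r} but genome has "
                f"{genome_base!r} (genome/VCF build mismatch?)"
            )
        up, down = genome.context(v.contig, v.position)
        try:
            sbs, _ = canonicalize_sbs(v.ref_allele, v.alt_allele, up, down)
        except UncountableContextError:
            audit.removed["uncountable_context"] += 1
            continue
        counts.loc[v.isolate_id, sbs.label] += 1
        audit.retained += 1
    return SpectrumMatrix(counts, meta, audit)


def build_dbs_matrix(
    doublets: Sequence[DbsRecord],
    genome: GenomeAssembly,
    isolates: pd.DataFrame | Sequence[tuple[str, str, str]] | None = None,
) -> SpectrumMatrix:
    """Count doublet substitutions into the 78 canonical DBS classes."""
    meta = _isolate_meta(doublets, isolates)
    counts = pd.DataFrame(0, index=meta.index, columns=list(DBS78_LABELS), dtype=int)
    audit = FilterAudit()
    for d in doublets:
        genome_dinuc = genome.contigs[d.contig][d.position : d.position + 2]
        if genome_dinuc != d.ref_dinuc:
            raise ReferenceMismatchError(
                f"{d.contig}:{d.position}: doublet ref {d.ref_dinuc!r} but genome has "
                f"{genome_dinuc!r}"
            )
        dbs = canonicalize_dbs(d.ref_dinuc, d.alt_dinuc)
        counts.loc[d.isolate_id, dbs.label] += 1
        audit.retained += 1
    return SpectrumMatrix(counts, meta, audit)


def summarize(matrix: SpectrumMatrix, group_by: str = "strain") -> pd.DataFrame:
    """Per-group totals: median, mean and SEM of per-isolate mutation counts.

    ``group_by`` is ``strain`` or ``strain_replicate``. The median of an
    even-sized group is the mean of the two central values; statistics over
    empty or singleton groups are flagged as NaN where undefined.
    """
    if group_by not in {"strain", "strain_replicate"}:
        raise ValueError("group_by must be 'strain' or 'strain_replicate'")
    keys = ["strain_id"] if group_by == "strain" else ["strain_id", "replicate_id"]
    totals = matrix.per_isolate_total
    df = matrix.isolate_meta.copy()
    df["total"] = totals
    grouped = df.groupby(keys)["total"]
    out = grouped.agg(
        n_isolates="count",
        median_total="median",
        mean_total="mean",
        sem_total=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) >= 2 else np.nan,
    ).reset_index()
    return out


def class_summary(matrix: SpectrumMatrix) -> pd.DataFrame:
    """Per-class mean and SEM across the matrix's isolates (figure-bar table)."""
    return pd.DataFrame(
        {"mean": matrix.per_class_mean, "sem": matrix.per_class_sem}
    ).rename_axis("class")
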