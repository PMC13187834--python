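"""Transcriptional strand asymmetry of UV mutations within genes.

Because pyrimidine-centric classes collapse the two strands, a mutation whose
pyrimidine lies on the gene's coding strand is assigned to the non-transcribed
strand (NTS) and one whose pyrimidine lies on the template strand to the
transcribed strand (TS). TC-NER removes lesions from the TS, so lesions on
pyrimidines produce NTS-enriched mutation classes. Classes *depleted* on the
NTS (normalized ratio < 1) imply the causative photoproduct sits on the
complementary strand — the signature used to infer purine-containing atypical
photoproducts such as the thymine-adenine photoproduct (reported as A>T in
TAN read from the lesion strand, observed as T>A in NTA).

NTS/TS counts are normalized by the strand-specific abundance of each class's
context across gene bodies, and tested with a 1-df chi-squared against the
abundance-proportional expectation, Bonferroni-corrected over tested classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from uvmut.genome import (
    COMPLEMENT,
    PYRIMIDINES,
    GeneAnnotation,
    GeneIndex,
    GenomeAssembly,
    UncountableContextError,
    _PALINDROMIC_REFS,
    canonicalize_dbs,
    canonicalize_sbs,
    dinuc_strand_census,
    gene_strand_census,
    revcomp,
)
from uvmut.variants import DbsRecord, VariantRecord


@dataclass
class AsymmetryRow:
    """Strand-asymmetry measurements and test for one mutation class."""

    class_label: str
    n_nts: int
    n_ts: int
    a_nts: int  # context abundance on NTS across gene bodies
    a_ts: int
    normalized_ratio: float  # (n_nts/a_nts) / (n_ts/a_ts)
    chi2_stat: float
    chi2_p: float
    significant_after_bonferroni: bool
    reverse_asymmetric: bool  # ratio < 1 and significant
    undefined: bool = False  # zero abundance or zero TS count
    bonferroni_divisor: int = 1


def assign_transcriptional_strand(
    variant: VariantRecord | DbsRecord, gene_index: GeneIndex
) -> str:
    """Locate a mutation relative to gene strands: NTS, TS, intergenic or ambiguous.

    For an SNV the pyrimidine-bearing strand of the canonical class is
    compared with the gene's coding strand; for a doublet, the strand on
    which the canonical reference dinucleotide is read. Positions covered by
    genes on both strands are ambiguous, as are doublets whose reference
    dinucleotide is its own reverse complement.
    """
    code = gene_index.strand_code(variant.contig, variant.position)
    if code == GeneIndex.INTERGENIC:
        return "intergenic"
    if code == GeneIndex.AMBIGUOUS:
        return "ambiguous"
    coding = "+" if code == GeneIndex.PLUS else "-"

    if isinstance(variant, VariantRecord):
        canonical_on_forward = variant.ref_allele in PYRIMIDINES
    else:
        ref = variant.ref_dinuc
        if ref in _PALINDROMIC_REFS or revcomp(ref) == ref:
            return "ambiguous"
        canonical = canonicalize_dbs(variant.ref_dinuc, variant.alt_dinuc)
        canonical_on_forward = canonical.ref_dinucleotide == ref
    on_coding = canonical_on_forward == (coding == "+")
    return "NTS" if on_coding else "TS"


def _chi2_1df(n_nts: int, n_ts: int, a_nts: float, a_ts: float) -> tuple[float, float]:
    """Closed-form 1-df goodness-of-fit of the observed strand split against
    expected proportions a_nts : a_ts."""
    total = n_nts + n_ts
    p_nts = a_nts / (a_nts + a_ts)
    e_nts, e_ts = total * p_nts, total * (1 - p_nts)
    stat = (n_nts - e_nts) ** 2 / e_nts + (n_ts - e_ts) ** 2 / e_ts
    return stat, float(stats.chi2.sf(stat, 1))


def asymmetry_table(
    records: Sequence[VariantRecord] | Sequence[DbsRecord],
    genes: Sequence[GeneAnnotation],
    genome: GenomeAssembly,
    min_total_mutations: int = 50,
    expected_mode: str = "abundance",
    alpha: float = 0.05,
) -> list[AsymmetryRow]:
    """Per-class NTS/TS counts, normalized ratios and chi-squared tests.

    Only genic, strand-assignable mutations contribute. Classes with fewer
    than ``min_total_mutations`` genic mutations are not tested (and not
    reported); the Bonferroni divisor is the number of reported classes.
    ``expected_mode`` selects the chi-squared null: ``abundance`` (default;
    expected split proportional to strand context abundance) or ``equal``
    (50:50, for sensitivity analysis). Rows with a zero abundance or zero TS
    count are flagged ``undefined`` rather than dropped.
    """
    if expected_mode not in {"abundance", "equal"}:
        raise ValueError("expected_mode must be 'abundance' or 'equal'")
    if not records:
        return []

    gene_index = GeneIndex(genome, list(genes))
    is_sbs = isinstance(records[0], VariantRecord)
    if is_sbs:
        nts_census, ts_census = gene_strand_census(genome, list(genes))
    else:
        nts_abund, ts_abund = dinuc_strand_census(genome, list(genes))

    counts: dict[str, list[int]] = {}
    contexts: dict[str, str] = {}
    for r in records:
        strand = assign_transcriptional_strand(r, gene_index)
        if strand not in ("NTS", "TS"):
            continue
        if is_sbs:
            up, down = genome.context(r.contig, r.position)
            try:
                cls, _ = canonicalize_sbs(r.ref_allele, r.alt_allele, up, down)
            except UncountableContextError:
                continue
            label, context = cls.label, cls.context
        else:
            cls = canonicalize_dbs(r.ref_dinuc, r.alt_dinuc)
            label, context = cls.label, cls.ref_dinucleotide
        counts.setdefault(label, [0, 0])[0 if strand == "NTS" else 1] += 1
        contexts[label] = context

    tested = {
        label: c for label, c in counts.items() if c[0] + c[1] >= min_total_mutations
    }
    divisor = max(len(tested), 1)

    rows: list[AsymmetryRow] = []
    for label in sorted(tested):
        n_nts, n_ts = tested[label]
        context = contexts[label]
        if is_sbs:
            a_nts, a_ts = nts_census[context], ts_census[context]
        else:
            a_nts, a_ts = nts_abund[context], ts_abund[context]
        if expected_mode == "equal":
            e_nts, e_ts = 1.0, 1.0
        else:
            e_nts, e_ts = float(a_nts), float(a_ts)

        undefined = a_nts == 0 or a_ts == 0 or n_ts == 0
        if a_nts > 0 and a_ts > 0:
            ratio = (n_nts / a_nts) / (n_ts / a_ts) if n_ts > 0 else float("inf")
        else:
            ratio = float("nan")
        if e_nts > 0 and e_ts > 0:
            chi2_stat, chi2_p = _chi2_1df(n_nts, n_ts, e_nts, e_ts)
        else:
            chi2_stat, chi2_p = float("nan"), float("nan")
        significant = bool(chi2_p == chi2_p and chi2_p < alpha / divisor)
        reverse = bool(significant and ratio == ratio and ratio < 1.0)
        rows.append(
            AsymmetryRow(
                label, n_nts, n_ts, int(a_nts), int(a_ts), ratio,
                chi2_stat, chi2_p, significant, reverse, undefined, divisor,
            )
        )
    return rows


def complementary_reading(class_label: str) -> str:
    """Re-express a pyrimidine-centric SBS class as read from the other strand.

    ``T[T>A]A`` (T>A in TTA) becomes ``T[A>T]A`` (A>T in TAA): the context is
    reverse complemented and the substitution complemented. This is how a
    reverse-asymmetric class is reported as the putative lesion-strand change.
    Doublet labels are reverse complemented on both sides.
    """
    if "[" not in class_label:
        ref, alt = class_label.split(">")
        return f"{revcomp(ref)}>{revcomp(alt)}"
    up, rest = class_label.split("[")
    change, down = rest.split("]")
    ref, alt = change.split(">")
    rc = revcomp(up + ref + down)
    return f"{rc[0]}[{COMPLEMENT[ref]}>{COMPLEMENT[alt]}]{rc[2]}"


def reverse_asymmetry_report(rows: Sequence[AsymmetryRow]) -> pd.DataFrame:
    """Significantly NTS-depleted classes with their complementary-strand
    re-expression — the candidate atypical-photoproduct mutation classes."""
    out = []
    for r in rows:
        if not r.reverse_asymmetric:
            continue
        out.append(
            {
                "class_label": r.class_label,
                "lesion_strand_reading": complementary_reading(r.class_label),
                "normalized_ratio": r.normalized_ratio,
                "chi2_p": r.chi2_p,
                "n_nts": r.n_nts,
                "n_ts": r.n_ts,
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "class_label", "lesion_strand_reading", "normalized_ratio",
            "chi2_p", "n_nts", "n_ts",
        ],
    )


def asymmetry_to_frame(rows: Sequence[AsymmetryRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])
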