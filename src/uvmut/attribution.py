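"""Photoproduct attribution by photolyase-subtractive strain comparison.

The logic follows the experimental design: a strain expressing a photolyase
removes one photoproduct class (CPDs or 6-4PPs) before mutagenesis, so the
per-class drop in mutations relative to the no-photolyase control measures
that photoproduct's contribution. Fold reductions with Welch's unequal-
variance t-tests rank the affected classes; the two fold axes together
classify each class as CPD-dominant, 6-4PP-dominant, mixed, or atypical
(unaffected by either photolyase). Attributed mutation counts divided by
gel-quantified lesion totals give the mutagenic potential of a lesion class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from uvmut.genome import GenomeAssembly
from uvmut.spectra import SpectrumMatrix


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float, bool]:
    """Welch's unpaired two-sample t-test (unequal variances), two-sided.

    Returns (t, degrees of freedom via Welch–Satterthwaite, p, degenerate).
    When both groups have zero variance the statistic is undefined: equal
    constants give p = 1, unequal constants p = 0, with the degenerate flag
    set so callers can report it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("Welch's test needs at least two observations per group")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if mx == my:
            return 0.0, float("nan"), 1.0, True
        return math.copysign(float("inf"), mx - my), float("nan"), 0.0, True
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, min(p, 1.0), False


def _rank_sum_distribution(doubled_ranks: np.ndarray, n_x: int) -> dict[int, float]:
    """Exact permutation distribution of the rank sum of a size-``n_x`` subset.

    ``doubled_ranks`` are 2x the pooled mid-ranks (integers even under ties).
    Returns a map from doubled rank sum to probability, built by subset-count
    dynamic programming — equivalent to enumerating all C(n, n_x) subsets.
    """
    max_sum = int(doubled_ranks.sum())
    counts = np.zeros((n_x + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        for k in range(min(n_x, len(doubled_ranks)), 0, -1):
            counts[k, r:] += counts[k - 1, : max_sum + 1 - r]
    total = counts[n_x].sum()
    return {s: c / total for s, c in enumerate(counts[n_x]) if c > 0}


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 20
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test on two independent samples.

    The exact permutation distribution (tie-aware, via rank-sum dynamic
    programming) is used when the combined sample size is at most
    ``exact_limit``; larger samples use the normal approximation with tie
    correction and continuity correction. Returns (U of ``x``, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    rank_sum_x = ranks[:nx].sum()
    u = rank_sum_x - nx * (nx + 1) / 2.0

    if nx + ny <= exact_limit:
        doubled = np.round(2 * ranks).astype(int)
        dist = _rank_sum_distribution(doubled, nx)
        obs = int(round(2 * rank_sum_x))
        p_le = sum(p for s, p in dist.items() if s <= obs)
        p_ge = sum(p for s, p in dist.items() if s >= obs)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u, p

    mu = nx * ny / 2.0
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u, 1.0  # all observations tied
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return u, min(p, 1.0)


# ---------------------------------------------------------------------------
# Fold-reduction tables
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeRow:
    """Per-class comparison of a control (no-photolyase) vs a treated strain."""

    class_label: str
    mean_control: float
    mean_treated: float
    fold_reduction: float  # control / treated; inf when treated mean is 0
    welch_t: float
    welch_p: float
    significant: bool
    degenerate_variance: bool
    n_control: int
    n_treated: int
    total_control_mutations: int


def fold_reduction_table(
    control: SpectrumMatrix,
    treated: SpectrumMatrix,
    min_total_mutations: int = 70,
    alpha: float = 0.001,
) -> list[FoldChangeRow]:
    """Per-class fold reductions with Welch's t-tests between two strains.

    Only classes whose cumulative control count reaches ``min_total_mutations``
    are reported (the comparison figures use 50, 70 or 100 depending on the
    mutation class). No multiple-testing correction is applied here; the
    significance flag marks two-sided p < ``alpha``.
    """
    if list(control.class_labels) != list(treated.class_labels):
        raise ValueError("control and treated matrices use different class label sets")
    if min_total_mutations < 0:
        raise ValueError("min_total_mutations must be >= 0")
    rows: list[FoldChangeRow] = []
    for label in control.class_labels:
        c = control.counts[label].to_numpy(dtype=float)
        t = treated.counts[label].to_numpy(dtype=float)
        total_control = int(c.sum())
        if total_control < min_total_mutations:
            continue
        mean_c, mean_t = c.mean(), t.mean()
        if mean_t > 0:
            fold = mean_c / mean_t
        elif mean_c > 0:
            fold = float("inf")
        else:
            fold = float("nan")
        if len(c) >= 2 and len(t) >= 2:
            welch_t, _, welch_p, degenerate = welch_t_test(c, t)
            significant = welch_p < alpha
        else:
            welch_t, welch_p, degenerate, significant = float("nan"), float("nan"), False, False
        rows.append(
            FoldChangeRow(
                label, mean_c, mean_t, fold, welch_t, welch_p, significant,
                degenerate, len(c), len(t), total_control,
            )
        )
    return rows


def fold_table_to_frame(rows: Sequence[FoldChangeRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# Photoproduct classification (fold-plane quadrants)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhotoproductCall:
    class_label: str
    fold_cpd: float
    fold_64pp: float
    label: str  # CPD-dominant | 6-4PP-dominant | mixed | atypical
    cpd_threshold: float
    pp64_threshold: float


def classify_photoproduct(
    fold_cpd: float,
    fold_64pp: float,
    cpd_threshold: float = 2.0,
    pp64_threshold: float = 2.0,
    class_label: str = "",
) -> PhotoproductCall:
    """Assign a mutation class to a causal photoproduct from its two folds.

    ``fold_cpd`` is the reduction seen when CPD photolyase is expressed,
    ``fold_64pp`` when 6-4PP photolyase is; a class strongly reduced by one
    photolyase but not the other is attributed to that photoproduct, reduced
    by both is mixed, and reduced by neither is attributed to atypical
    (photolyase-resistant) photoproducts. The thresholds partition the fold
    plane, so every (fold_cpd, fold_64pp) pair receives exactly one label.
    """
    if fold_cpd < 0 or fold_64pp < 0:
        raise ValueError("folds must be >= 0")
    if cpd_threshold <= 1 or pp64_threshold <= 1:
        raise ValueError("thresholds must exceed 1")
    cpd_hit = fold_cpd >= cpd_threshold
    pp64_hit = fold_64pp >= pp64_threshold
    if cpd_hit and not pp64_hit:
        label = "CPD-dominant"
    elif pp64_hit and not cpd_hit:
        label = "6-4PP-dominant"
    elif cpd_hit and pp64_hit:
        label = "mixed"
    else:
        label = "atypical"
    return PhotoproductCall(class_label, fold_cpd, fold_64pp, label, cpd_threshold, pp64_threshold)


# ---------------------------------------------------------------------------
# Replicate concordance
# ---------------------------------------------------------------------------

def replicate_concordance(matrix: SpectrumMatrix, strain_id: str) -> tuple[float, float]:
    """Mann–Whitney U comparison of per-isolate totals between the two
    passaging replicates of one strain. Returns (U, two-sided p)."""
    sub = matrix.subset(strain_id=strain_id)
    reps = sorted(sub.isolate_meta["replicate_id"].unique())
    if len(reps) != 2:
        raise ValueError(f"strain {strain_id!r} has {len(reps)} replicates; need exactly 2")
    totals = sub.per_isolate_total
    a = totals[sub.isolate_meta["replicate_id"] == reps[0]].to_numpy()
    b = totals[sub.isolate_meta["replicate_id"] == reps[1]].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each replicate needs at least one isolate")
    return mann_whitney_u(a, b)


# ---------------------------------------------------------------------------
# Attribution arithmetic and mutagenic potential
# ---------------------------------------------------------------------------

def attribute_mutation_counts(
    control_replicate_medians: Sequence[float],
    treated_replicate_medians: Sequence[float] = (),
) -> float:
    """Mutations per isolate attributed to the photoproduct a treatment removes.

    Per-replicate median totals are averaged within each strain, and the
    treated average is subtracted from the control average. With no treated
    medians (comparison against a zero-mutation baseline) the attribution is
    simply the control average — the reading used for residual, photolyase-
    resistant mutagenesis.
    """
    control = np.asarray(list(control_replicate_medians), dtype=float)
    if control.size == 0:
        raise ValueError("control medians must be non-empty")
    treated = np.asarray(list(treated_replicate_medians), dtype=float)
    treated_mean = treated.mean() if treated.size else 0.0
    return float(control.mean() - treated_mean)


def attribute_from_summary(
    summary: pd.DataFrame, control_strain: str, treated_strain: str | None = None
) -> float:
    """Attribution from a ``summarize(..., group_by='strain_replicate')`` table."""
    if "replicate_id" not in summary.columns:
        raise ValueError("need a strain x replicate summary (group_by='strain_replicate')")
    control = summary.loc[summary["strain_id"] == control_strain, "median_total"]
    if control.empty:
        raise ValueError(f"strain {control_strain!r} not in summary")
    treated: Sequence[float] = ()
    if treated_strain is not None:
        t = summary.loc[summary["strain_id"] == treated_strain, "median_total"]
        if t.empty:
            raise ValueError(f"strain {treated_strain!r} not in summary")
        treated = t.to_list()
    return attribute_mutation_counts(control.to_list(), treated)


@dataclass(frozen=True)
class MutagenicPotential:
    """Fraction of induced lesions of a class that became fixed mutations."""

    attributed_mutations: float
    lesions_per_kb: float
    haploid_size_kb: float
    ploidy: int
    strands_per_bp: int = 2

    @property
    def total_lesions(self) -> float:
        return self.lesions_per_kb * self.haploid_size_kb * self.ploidy * self.strands_per_bp

    @property
    def percent_mutagenic(self) -> float:
        if self.attributed_mutations == 0:
            return 0.0
        return 100.0 * self.attributed_mutations / self.total_lesions


def mutagenic_potential(
    attributed_mutations: float,
    lesions_per_kb: float,
    genome: GenomeAssembly | float,
    ploidy: int | None = None,
) -> MutagenicPotential:
    """Combine attributed mutations with a gel-derived lesion density.

    Total lesions per cell = lesions/kb x haploid genome size (kb) x ploidy
    x 2 strands, since gel quantification measures lesion frequency per DNA
    strand. ``genome`` may be a loaded assembly (supplying size and ploidy)
    or a haploid size in kb with ``ploidy`` given explicitly.
    """
    if isinstance(genome, GenomeAssembly):
        size_kb, pl = genome.haploid_size_kb, genome.ploidy
    else:
        if ploidy is None:
            raise ValueError("ploidy required when genome is given as a size")
        size_kb, pl = float(genome), ploidy
    if attributed_mutations < 0 or lesions_per_kb <= 0 or size_kb <= 0:
        raise ValueError("inputs must be positive (attributed may be 0)")
    return MutagenicPotential(attributed_mutations, lesions_per_kb, size_kb, pl)
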