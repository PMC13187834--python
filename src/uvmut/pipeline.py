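"""End-to-end orchestration: filter -> spectra -> attribution -> asymmetry
-> lesion quantification -> consolidated report.

A single YAML run-config names the inputs and thresholds; every stage writes
its TSV so stages are independently inspectable, and the report echoes every
parameter that affects a number. The pipeline is deterministic: re-running an
unchanged config reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from uvmut import attribution, asymmetry, lesions, spectra, variants
from uvmut.genome import GenomeAssembly, load_genes, load_genome
from uvmut.variants import FilterConfig

logger = logging.getLogger("uvmut")


@dataclass
class RunConfig:
    """Paths, thresholds and comparisons for one pipeline run."""

    genome: str
    genes: str
    metadata: str
    outdir: str
    excluded_contigs: list[str] = field(default_factory=list)
    ploidy: int = 2
    min_depth: int = 10
    min_allele_fraction: float = 0.45
    max_recurrence: int = 2
    depth_field: str = "DP"
    af_field: str = "AF"
    fold_min_total: int = 70
    fold_alpha: float = 0.001
    asymmetry_min_total: int = 50
    asymmetry_alpha: float = 0.05
    asymmetry_expected_mode: str = "abundance"
    cpd_fold_threshold: float = 2.0
    pp64_fold_threshold: float = 2.0
    poisson_correction: float = lesions.POISSON_MASS_MEDIAN
    comparisons: list[dict] = field(default_factory=list)  # {control, treated}
    cpd_comparison: dict | None = None   # {control, treated} defining fold_cpd
    pp64_comparison: dict | None = None  # {control, treated} defining fold_64pp
    asymmetry_strains: list[str] | None = None
    ladder: str | None = None  # TSV: size_bp, migration
    lanes: list[dict] = field(default_factory=list)  # {enzyme, control, kind}
    mutagenic: list[dict] = field(default_factory=list)  # {control_strain, treated_strain?, lesion_kind}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            self.min_depth, self.min_allele_fraction, self.max_recurrence,
            set(self.excluded_contigs),
        )


def _echo_params(config: RunConfig) -> str:
    lines = ["# uvmut run parameters"]
    for name in config.__dataclass_fields__:
        lines.append(f"#   {name} = {getattr(config, name)!r}")
    return "\n".join(lines)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the in-memory stage outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(name)s: %(message)s")

    strains_in_comparisons = set()
    for cmp_def in list(config.comparisons) + [config.cpd_comparison, config.pp64_comparison]:
        if cmp_def:
            strains_in_comparisons |= {cmp_def["control"], cmp_def["treated"]}
    meta = variants.read_metadata(config.metadata)
    known_strains = set(meta["strain_id"])
    missing = strains_in_comparisons - known_strains
    if missing:
        raise ValueError(f"comparisons reference strains not in metadata: {sorted(missing)}")

    genome = load_genome(config.genome, set(config.excluded_contigs), config.ploidy)
    genes = load_genes(config.genes)
    logger.info(
        "genome: %d contigs, %.1f kb haploid; %d genes",
        len(genome.contigs), genome.haploid_size_kb, len(genes),
    )

    snvs, direct_dbs, read_audit = variants.read_cohort(meta, config.depth_field, config.af_field)
    fc = config.filter_config()
    snvs, site_audit_s = variants.apply_site_filters(snvs, fc)
    direct_dbs, site_audit_d = variants.apply_site_filters(direct_dbs, fc)
    snvs, rec_audit_s = variants.apply_recurrence_filter(snvs, fc.max_recurrence)
    direct_dbs, rec_audit_d = variants.apply_recurrence_filter(direct_dbs, fc.max_recurrence)
    doublets, snvs, merge_audit = variants.call_doublets(snvs, direct_dbs)
    logger.info(
        "filtering: read %s | site %s %s | recurrence %s %s | doublets %s",
        read_audit, site_audit_s, site_audit_d, rec_audit_s, rec_audit_d, merge_audit,
    )

    audit_frames = []
    for stage, audit in [
        ("read", read_audit), ("site_snv", site_audit_s), ("site_dbs", site_audit_d),
        ("recurrence_snv", rec_audit_s), ("recurrence_dbs", rec_audit_d),
        ("doublet_merge", merge_audit),
    ]:
        frame = audit.to_frame()
        frame.insert(0, "stage", stage)
        audit_frames.append(frame)
    pd.concat(audit_frames).to_csv(outdir / "audit.tsv", sep="\t", index=False)
    variants.records_to_frame(list(snvs) + list(doublets)).to_csv(
        outdir / "filtered_variants.tsv", sep="\t", index=False
    )

    sbs = spectra.build_sbs_matrix(snvs, genome, meta)
    dbs = spectra.build_dbs_matrix(doublets, genome, meta)
    sbs.to_tsv(outdir / "sbs_matrix.tsv")
    dbs.to_tsv(outdir / "dbs_matrix.tsv")
    summary_strain = spectra.summarize(sbs, "strain")
    summary_rep = spectra.summarize(sbs, "strain_replicate")
    summary_strain.to_csv(outdir / "summary_strain.tsv", sep="\t", index=False)
    summary_rep.to_csv(outdir / "summary_strain_replicate.tsv", sep="\t", index=False)

    fold_tables: dict[str, list] = {}
    for cmp_def in config.comparisons:
        control, treated = cmp_def["control"], cmp_def["treated"]
        rows = attribution.fold_reduction_table(
            sbs.subset(strain_id=control), sbs.subset(strain_id=treated),
            cmp_def.get("min_total", config.fold_min_total), config.fold_alpha,
        )
        key = f"{control}_vs_{treated}"
        fold_tables[key] = rows
        attribution.fold_table_to_frame(rows).to_csv(
            outdir / f"fold_{key}.tsv", sep="\t", index=False
        )

    calls = []
    if config.cpd_comparison and config.pp64_comparison:
        cpd_rows = attribution.fold_reduction_table(
            sbs.subset(strain_id=config.cpd_comparison["control"]),
            sbs.subset(strain_id=config.cpd_comparison["treated"]),
            config.fold_min_total, config.fold_alpha,
        )
        pp64_rows = attribution.fold_reduction_table(
            sbs.subset(strain_id=config.pp64_comparison["control"]),
            sbs.subset(strain_id=config.pp64_comparison["treated"]),
            config.fold_min_total, config.fold_alpha,
        )
        pp64_by_class = {r.class_label: r for r in pp64_rows}
        for r in cpd_rows:
            other = pp64_by_class.get(r.class_label)
            if other is None:
                continue
            calls.append(
                attribution.classify_photoproduct(
                    r.fold_reduction, other.fold_reduction,
                    config.cpd_fold_threshold, config.pp64_fold_threshold, r.class_label,
                )
            )
        pd.DataFrame([vars(c) for c in calls]).to_csv(
            outdir / "photoproduct_calls.tsv", sep="\t", index=False
        )

    asym_tables: dict[str, list] = {}
    strain_list = config.asymmetry_strains
    if strain_list is None:
        strain_list = sorted(known_strains)
    for strain in strain_list:
        strain_snvs = [v for v in snvs if v.strain_id == strain]
        rows = asymmetry.asymmetry_table(
            strain_snvs, genes, genome, config.asymmetry_min_total,
            config.asymmetry_expected_mode, config.asymmetry_alpha,
        )
        asym_tables[strain] = rows
        asymmetry.asymmetry_to_frame(rows).to_csv(
            outdir / f"asymmetry_{strain}.tsv", sep="\t", index=False
        )
        asymmetry.reverse_asymmetry_report(rows).to_csv(
            outdir / f"reverse_asymmetry_{strain}.tsv", sep="\t", index=False
        )

    estimates: list[lesions.LesionEstimate] = []
    lesion_means: dict[str, float] = {}
    if config.ladder and config.lanes:
        ladder_df = pd.read_csv(config.ladder, sep="\t", comment="#")
        calibration = lesions.calibrate_ladder(
            list(zip(ladder_df.iloc[:, 0], ladder_df.iloc[:, 1]))
        )
        for lane_def in config.lanes:
            est = lesions.lesion_frequency(
                lesions.LaneProfile.from_tsv(lane_def["enzyme"], "t4_endoV"),
                lesions.LaneProfile.from_tsv(lane_def["control"], "no_enzyme"),
                calibration, config.poisson_correction, lane_def.get("kind", "CPD"),
            )
            estimates.append(est)
        df = pd.DataFrame([vars(e) | {"lesion_kind": e.lesion_kind} for e in estimates])
        df.to_csv(outdir / "lesions.tsv", sep="\t", index=False)
        lesion_means = df.groupby("lesion_kind")["net_lesions_per_kb"].mean().to_dict()

    potentials: list[tuple[str, attribution.MutagenicPotential]] = []
    for mdef in config.mutagenic:
        kind = mdef.get("lesion_kind", "CPD")
        if kind not in lesion_means:
            logger.info("no lesion estimate of kind %s; skipping mutagenic entry", kind)
            continue
        attributed = attribution.attribute_from_summary(
            summary_rep, mdef["control_strain"], mdef.get("treated_strain")
        )
        mp = attribution.mutagenic_potential(attributed, lesion_means[kind], genome)
        potentials.append((kind, mp))
    if potentials:
        pd.DataFrame(
            [
                dict(
                    lesion_kind=k, attributed_mutations=mp.attributed_mutations,
                    lesions_per_kb=mp.lesions_per_kb, haploid_size_kb=mp.haploid_size_kb,
                    ploidy=mp.ploidy, total_lesions=mp.total_lesions,
                    percent_mutagenic=mp.percent_mutagenic,
                )
                for k, mp in potentials
            ]
        ).to_csv(outdir / "mutagenic.tsv", sep="\t", index=False)

    report_text = build_report(
        config, summary_strain, summary_rep, fold_tables, calls, asym_tables,
        estimates, potentials,
    )
    (outdir / "report.txt").write_text(report_text)

    return dict(
        genome=genome, genes=genes, sbs=sbs, dbs=dbs,
        summary_strain=summary_strain, summary_replicate=summary_rep,
        fold_tables=fold_tables, photoproduct_calls=calls,
        asymmetry=asym_tables, lesion_estimates=estimates, potentials=potentials,
        report=report_text,
    )


def format_mutagenic(mp: attribution.MutagenicPotential, label: str) -> str:
    """Human-readable lesion-total and mutagenic-percentage arithmetic."""
    return (
        f"{label}: {mp.lesions_per_kb:.2f} lesions/kb x {mp.haploid_size_kb:.0f} kb/haploid "
        f"x {mp.ploidy} haploids x {mp.strands_per_bp} strands = "
        f"{mp.total_lesions:.0f} lesions; attributed mutations/isolate = "
        f"{mp.attributed_mutations:.1f}; mutagenic = "
        f"{mp.percent_mutagenic:.2f}%"
    )


def build_report(
    config: RunConfig,
    summary_strain: pd.DataFrame,
    summary_rep: pd.DataFrame,
    fold_tables: dict,
    calls: list,
    asym_tables: dict,
    estimates: list,
    potentials: list,
) -> str:
    lines = [_echo_params(config), "", "== Per-strain mutation totals =="]
    for _, row in summary_strain.iterrows():
        lines.append(
            f"  {row['strain_id']}: n={row['n_isolates']}, median={row['median_total']:.1f}, "
            f"mean={row['mean_total']:.1f}"
        )
    lines.append("")
    lines.append("== Per-replicate medians ==")
    for _, row in summary_rep.iterrows():
        lines.append(
            f"  {row['strain_id']} {row['replicate_id']}: median={row['median_total']:.1f}"
        )
    for key, rows in fold_tables.items():
        lines.append("")
        lines.append(f"== Top fold reductions: {key} ==")
        for r in sorted(rows, key=lambda r: -r.fold_reduction)[:10]:
            star = " ***" if r.significant else ""
            lines.append(
                f"  {r.class_label}: {r.mean_control:.2f} -> {r.mean_treated:.2f} "
                f"({r.fold_reduction:.1f}-fold, p={r.welch_p:.2e}){star}"
            )
    if calls:
        lines.append("")
        lines.append("== Photoproduct calls ==")
        for c in calls:
            lines.append(
                f"  {c.class_label}: fold_cpd={c.fold_cpd:.1f}, fold_64pp={c.fold_64pp:.1f} "
                f"-> {c.label}"
            )
    for strain, rows in asym_tables.items():
        reverse = [r for r in rows if r.reverse_asymmetric]
        if reverse:
            lines.append("")
            lines.append(f"== Reverse-asymmetric classes ({strain}) ==")
            for r in reverse:
                lines.append(
                    f"  {r.class_label}: NTS/TS={r.normalized_ratio:.2f}, p={r.chi2_p:.2e} "
                    f"(lesion-strand reading {asymmetry.complementary_reading(r.class_label)})"
                )
    if estimates:
        lines.append("")
        lines.append("== Lesion quantification ==")
        for e in estimates:
            flag = " [negative net floored]" if e.negative_net_flagged else ""
            lines.append(
                f"  {e.lesion_kind}: median size {e.median_size_kb_enzyme:.2f} kb (enzyme) / "
                f"{e.median_size_kb_control:.2f} kb (control) -> net "
                f"{e.net_lesions_per_kb:.3f} lesions/kb{flag}"
            )
    if potentials:
        lines.append("")
        lines.append("== Mutagenic potential ==")
        for kind, mp in potentials:
            lines.append("  " + format_mutagenic(mp, kind))
    else:
        lines.append("")
        lines.append("== Mutagenic potential: lesion profiles not provided ==")
    lines.append("")
    return "\n".join(lines)
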