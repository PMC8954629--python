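"""End-to-end orchestration: summaries -> screens -> intersections -> DEG ->
enrichment -> CRE, from one declarative config.

The in-memory entry point is :func:`analyze`; :func:`run_pipeline` is the
file-facing wrapper driven by a YAML config and writes a TSV bundle plus one
flat machine-readable report.  Every percentage in the report is stored next
to its integer numerator and denominator and re-audited with
:func:`tissuespec.specificity.overlap_percentage` before the report is
returned.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
import yaml

from . import cre as cre_mod
from .diffexpr import DiffExprConfig, call_degs, cross_tabulate_degs, deg_sets
from .enrichment import hypergeom_enrich, read_annotation_tsv, validate_annotation
from .expression import (
    ExpressionMatrix,
    correlation_matrix,
    counts_to_tpm,
    read_expression_tsv,
    read_gene_lengths_tsv,
    read_sample_metadata,
    transcriptome_summary,
    validate_sample_metadata,
)
from .specificity import (
    GeneSet,
    ScreenConfig,
    abundant_genes,
    classify_abundance_series,
    intersect,
    make_roles,
    overlap_percentage,
    screen_specific,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    correlation: pd.DataFrame
    tiers: pd.Series  # target-tissue abundance tier per gene
    gene_sets: dict[str, GeneSet]
    screen_records: dict[str, pd.DataFrame]
    region_counts: dict[str, dict]
    degs: pd.DataFrame | None
    cross_tab: dict[str, pd.DataFrame] | None
    enrichment: dict[str, pd.DataFrame]
    cre_frequencies: dict[str, pd.Series]
    report: dict
    resolved_config: dict


def _audit_report(report: Mapping) -> None:
    """Every reported percentage must equal overlap_percentage(num, den)."""
    for key, value in report.items():
        if key.endswith("_pct"):
            num = report.get(key[:-4] + "_num")
            den = report.get(key[:-4] + "_den")
            if num is None or den is None:
                raise PipelineError(f"report audit: {key} lacks numerator/denominator")
            if overlap_percentage(num, den) != value:
                raise PipelineError(
                    f"report audit: {key}={value} != overlap_percentage({num}, {den})"
                )


def analyze(
    tpm: ExpressionMatrix,
    meta: pd.DataFrame,
    pollen_label: str,
    anther_labels: list[str],
    stage_samples: Mapping[str, str] | None = None,
    deg_counts: ExpressionMatrix | None = None,
    annotation: pd.DataFrame | None = None,
    promoters=None,
    motifs=None,
    screen_config: ScreenConfig = ScreenConfig(),
    deg_config: DiffExprConfig = DiffExprConfig(),
    enrich_kwargs: dict | None = None,
    cre_sets: Mapping[str, set] | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs.

    ``stage_samples`` maps developmental-stage names to the single anther
    sample that represents them; ``cre_sets`` optionally restricts the CRE
    frequency tables to named gene subsets (default: the anther-and-pollen
    intersection set plus, when DEGs are called, the DEG/PSG shared genes).
    """
    validate_sample_metadata(meta, tpm)
    if pollen_label not in set(meta["tissue_label"]):
        raise PipelineError(f"screen stage: pollen label {pollen_label!r} not in metadata")
    missing = set(anther_labels) - set(meta["tissue_label"])
    if missing:
        raise PipelineError(f"screen stage: anther label(s) {sorted(missing)} not in metadata")
    stage_samples = dict(stage_samples or {})

    summary = transcriptome_summary(tpm, eg_cutoff=screen_config.eg_cutoff)
    correlation = correlation_matrix(tpm)
    tiers = classify_abundance_series(tpm.data[pollen_label], screen_config)

    gene_sets: dict[str, GeneSet] = {}
    records: dict[str, pd.DataFrame] = {}

    psg_meta = make_roles(meta, [pollen_label], exclude_labels=anther_labels)
    gene_sets["PSG"], records["PSG"] = screen_specific(
        tpm, psg_meta, "single", screen_config, name="PSG"
    )
    gene_sets["PAG"] = abundant_genes(tpm, psg_meta, "single", screen_config, name="PAG")

    asg_meta = make_roles(meta, anther_labels, exclude_labels=[pollen_label])
    gene_sets["ASG"], records["ASG"] = screen_specific(
        tpm, asg_meta, "mean", screen_config, name="ASG"
    )
    gene_sets["AAG"] = abundant_genes(tpm, asg_meta, "mean", screen_config, name="AAG")

    for stage, sample in stage_samples.items():
        exclude = [pollen_label] + [a for a in anther_labels if a != sample]
        stage_meta = make_roles(meta, [sample], exclude_labels=exclude)
        gene_sets[f"{stage}SG"], records[f"{stage}SG"] = screen_specific(
            tpm, stage_meta, "single", screen_config, name=f"{stage}SG"
        )

    region_counts: dict[str, dict] = {}
    gene_sets["APSG"], region_counts["APSG"] = intersect(
        [gene_sets["PSG"], gene_sets["ASG"]], name="APSG"
    )
    for stage in stage_samples:
        name = f"{stage}PSG"
        gene_sets[name], region_counts[name] = intersect(
            [gene_sets["PSG"], gene_sets[f"{stage}SG"]], name=name
        )

    report: dict = {}
    n_genes = tpm.shape[0]
    pollen_eg = int(summary.loc[pollen_label, "n_EG"])
    report["n_genes"] = n_genes
    report["pollen_n_EG"] = pollen_eg
    report["pollen_pct_top300"] = float(summary.loc[pollen_label, "pct_top300"])
    report["pollen_EG_of_genome_num"] = pollen_eg
    report["pollen_EG_of_genome_den"] = n_genes
    report["pollen_EG_of_genome_pct"] = overlap_percentage(pollen_eg, n_genes)
    for name in ("PSG", "ASG", "APSG", "PAG", "AAG"):
        report[f"n_{name}"] = len(gene_sets[name])
    for stage in stage_samples:
        report[f"n_{stage}SG"] = len(gene_sets[f"{stage}SG"])
        report[f"n_{stage}PSG"] = len(gene_sets[f"{stage}PSG"])
    if pollen_eg > 0:
        report["PSG_of_pollen_EG_num"] = len(gene_sets["PSG"])
        report["PSG_of_pollen_EG_den"] = pollen_eg
        report["PSG_of_pollen_EG_pct"] = overlap_percentage(len(gene_sets["PSG"]), pollen_eg)
    if len(gene_sets["PAG"]):
        k = len(gene_sets["PAG"].genes & gene_sets["PSG"].genes)
        report["PAG_in_PSG_num"] = k
        report["PAG_in_PSG_den"] = len(gene_sets["PAG"])
        report["PAG_in_PSG_pct"] = overlap_percentage(k, len(gene_sets["PAG"]))
    if len(gene_sets["AAG"]):
        k = len(gene_sets["AAG"].genes & gene_sets["ASG"].genes)
        report["AAG_in_ASG_num"] = k
        report["AAG_in_ASG_den"] = len(gene_sets["AAG"])
        report["AAG_in_ASG_pct"] = overlap_percentage(k, len(gene_sets["AAG"]))

    degs = None
    cross = None
    if deg_counts is not None:
        degs = call_degs(deg_counts, deg_config)
        groups = deg_sets(degs, deg_config.p_cutoff)
        report["n_DEG"] = len(groups["all"])
        report["n_DEG_up"] = len(groups["up"])
        report["n_DEG_down"] = len(groups["down"])
        cross = cross_tabulate_degs(
            degs, tiers, {"PSG": gene_sets["PSG"], "PAG": gene_sets["PAG"]}
        )
        report["n_DEG_in_PSG"] = len(groups["all"] & gene_sets["PSG"].genes)
        report["n_DEG_in_PAG"] = len(groups["all"] & gene_sets["PAG"].genes)
        if report["n_DEG"]:
            leg = cross["by_tier"].loc["LEG"]
            report["DEG_in_LEG_num"] = int(leg["total"])
            report["DEG_in_LEG_den"] = report["n_DEG"]
            report["DEG_in_LEG_pct"] = overlap_percentage(int(leg["total"]), report["n_DEG"])

    enrichment: dict[str, pd.DataFrame] = {}
    if annotation is not None:
        annotation = validate_annotation(annotation)
        universe = set(annotation["gene_id"]) & set(tpm.gene_ids)
        kwargs = enrich_kwargs or {}
        for name in ("PSG", "ASG", "APSG"):
            if len(gene_sets[name]):
                enrichment[name] = hypergeom_enrich(
                    gene_sets[name].genes, annotation, universe, **kwargs
                )
        if degs is not None and report.get("n_DEG"):
            enrichment["DEG"] = hypergeom_enrich(
                deg_sets(degs, deg_config.p_cutoff)["all"], annotation, universe, **kwargs
            )

    cre_frequencies: dict[str, pd.Series] = {}
    if promoters:
        motifs = motifs if motifs is not None else cre_mod.DEFAULT_MOTIFS
        hits = cre_mod.scan_motifs(promoters, motifs)
        targets = dict(cre_sets or {})
        if not targets:
            targets["PSG"] = set(gene_sets["PSG"].genes)
            if len(gene_sets["APSG"]):
                targets["APSG"] = set(gene_sets["APSG"].genes)
            if degs is not None:
                targets["DEG_PSG_shared"] = (
                    deg_sets(degs, deg_config.p_cutoff)["all"] & gene_sets["PSG"].genes
                )
        for name, genes in targets.items():
            subset = [p for p in promoters if p.gene_id in genes]
            if subset:
                cre_frequencies[name] = cre_mod.group_frequencies(hits, subset)

    _audit_report(report)
    resolved = {
        "pollen_label": pollen_label,
        "anther_labels": list(anther_labels),
        "stage_samples": dict(stage_samples),
        "screen": vars(screen_config) | {"zero_floor": screen_config.floor},
        "deg": vars(deg_config),
    }
    return PipelineResult(
        summary=summary,
        correlation=correlation,
        tiers=tiers,
        gene_sets=gene_sets,
        screen_records=records,
        region_counts=region_counts,
        degs=degs,
        cross_tab=cross,
        enrichment=enrichment,
        cre_frequencies=cre_frequencies,
        report=report,
        resolved_config=resolved,
    )


def _write_result(result: PipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    result.summary.to_csv(os.path.join(outdir, "summary.tsv"), sep="\t")
    result.correlation.to_csv(os.path.join(outdir, "correlation.tsv"), sep="\t")
    for name, gs in result.gene_sets.items():
        gs.to_file(os.path.join(outdir, f"set_{name}.txt"))
    for name, rec in result.screen_records.items():
        rec.to_csv(os.path.join(outdir, f"screen_{name}.tsv"), sep="\t")
    if result.degs is not None:
        result.degs.to_csv(os.path.join(outdir, "deg.tsv"), sep="\t")
        for key, table in (result.cross_tab or {}).items():
            table.to_csv(os.path.join(outdir, f"deg_cross_{key}.tsv"), sep="\t")
    for name, table in result.enrichment.items():
        table.to_csv(os.path.join(outdir, f"enrichment_{name}.tsv"), sep="\t", index=False)
    for name, freq in result.cre_frequencies.items():
        freq.rename("frequency").to_csv(
            os.path.join(outdir, f"cre_frequency_{name}.tsv"), sep="\t", index_label="group"
        )
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(result.report, fh, indent=1, sort_keys=True)
    with open(os.path.join(outdir, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(result.resolved_config, fh, sort_keys=False)


def run_synthetic(sim_config=None, workdir: str | None = None, with_genome: bool = True):
    """Generate a synthetic atlas and run the full analysis on it.

    Returns ``(result, synthetic_expression, synthetic_genome)``; the genome
    leg (promoter extraction + CRE scan) needs a scratch directory for the
    FASTA/GFF3 pair and is skipped when ``with_genome`` is False.  The DEG
    enumeration cap is raised above its conservative default because the
    heavy-tailed pollen profile legitimately produces per-gene count totals
    beyond 1e5 at the emulated depth.
    """
    import tempfile

    from .simulate import (
        ANTHER_LABELS,
        POLLEN_LABEL,
        STAGE_SAMPLES,
        SyntheticConfig,
        generate_expression,
        generate_promoters_and_annotation,
    )

    sim_config = sim_config or SyntheticConfig()
    data = generate_expression(sim_config)
    tpm = counts_to_tpm(data.counts, data.lengths)
    genome = None
    promoters = None
    motifs = None
    if with_genome:
        rng_genes = sorted(
            set(data.truth.psg) | set(data.truth.asg) | set(data.truth.shared_deg_psg)
        )
        background = [g for g in data.counts.gene_ids if g not in set(rng_genes)][:100]
        genome = generate_promoters_and_annotation(
            sim_config,
            rng_genes + background,
            motif_target_genes=sorted(data.truth.psg),
            term_target_genes=sorted(data.truth.psg),
            all_gene_ids=list(data.counts.gene_ids),
        )
        ctx = tempfile.TemporaryDirectory() if workdir is None else None
        gdir = workdir if workdir is not None else ctx.name
        try:
            paths = genome.write(gdir)
            promoters = cre_mod.extract_promoters(
                paths["genome"], paths["gff3"], sim_config.promoter_length
            )
        finally:
            if ctx is not None:
                ctx.cleanup()
        motifs = genome.motifs
    result = analyze(
        tpm,
        data.metadata,
        pollen_label=POLLEN_LABEL,
        anther_labels=list(ANTHER_LABELS),
        stage_samples=STAGE_SAMPLES,
        deg_counts=data.deg_counts,
        annotation=genome.annotation if genome is not None else None,
        promoters=promoters,
        motifs=motifs,
        deg_config=DiffExprConfig(enumeration_cap=10_000_000),
    )
    return result, data, genome


def run_pipeline(config, outdir: str | None = None) -> PipelineResult:
    """Run the pipeline from a YAML config path (or an equivalent dict)."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    try:
        inputs = config["inputs"]
        design = config["design"]
    except KeyError as exc:
        raise PipelineError(f"config stage: missing section {exc.args[0]!r}") from None

    unit = inputs.get("unit", "TPM")
    matrix = read_expression_tsv(inputs["matrix"], unit)
    if unit == "counts":
        if "lengths" not in inputs:
            raise PipelineError("config stage: counts input requires 'lengths'")
        lengths = read_gene_lengths_tsv(inputs["lengths"])
        tpm = counts_to_tpm(matrix, lengths)
    else:
        tpm = matrix
    meta = read_sample_metadata(inputs["metadata"])
    validate_sample_metadata(meta, tpm)

    deg_counts = (
        read_expression_tsv(inputs["deg_counts"], "counts") if inputs.get("deg_counts") else None
    )
    annotation = read_annotation_tsv(inputs["annotation"]) if inputs.get("annotation") else None
    promoters = None
    motifs = None
    if inputs.get("genome") and inputs.get("gff3"):
        promoters = cre_mod.extract_promoters(
            inputs["genome"], inputs["gff3"], config.get("promoter_length", 2000)
        )
        if inputs.get("motifs"):
            motifs = cre_mod.load_motifs_yaml(inputs["motifs"])

    screen_config = ScreenConfig(**config.get("screen", {}))
    deg_config = DiffExprConfig(**config.get("deg", {}))
    result = analyze(
        tpm,
        meta,
        pollen_label=design["pollen_label"],
        anther_labels=list(design["anther_labels"]),
        stage_samples=design.get("stage_samples"),
        deg_counts=deg_counts,
        annotation=annotation,
        promoters=promoters,
        motifs=motifs,
        screen_config=screen_config,
        deg_config=deg_config,
        enrich_kwargs=config.get("enrichment"),
    )
    if outdir or config.get("out"):
        _write_result(result, outdir or config["out"])
    return result
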