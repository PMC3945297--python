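"""End-to-end orchestration: inputs -> filtered records -> report tables.

The stage order is fixed: transcript selection, site counting, substitution
classification, within-tumor deduplication, nonsense/frameshift exclusion,
germline frequency filtering, expression partitioning, group tallies, ratio
statistics, the per-gene screen and enrichment tests.  Every filter logs its
record counts and the report archives the counts each ratio was computed
from, so any reported number can be recomputed from the report itself.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ValidationError
from .expression_breadth import (
    breadth_histogram,
    compute_breadth,
    partition_genes,
    read_expression_tsv,
    read_gene_list,
)
from .selection_stats import (
    Metric,
    compare_groups,
    list_enrichment,
    per_gene_screen,
    test_ratio_vs_one,
)
from .site_counting import (
    Scheme,
    aggregate_site_counts,
    compute_site_counts,
    read_cds_fasta,
    read_functionality_table,
    write_site_counts_tsv,
)
from .variant_processing import (
    apply_nonsense_frameshift_filter,
    classify_records,
    deduplicate_within_tumor,
    filter_germline_by_frequency,
    patient_zero_hit_summary,
    read_germline_vcf,
    read_maf,
    select_longest_transcript,
    tally_group_counts,
    write_classified_tsv,
)

logger = logging.getLogger(__name__)

METRICS = (Metric.DN_DS, Metric.DMF_DLF_SIFT, Metric.DMF_DLF_PPH)


@dataclass
class PipelineInputs:
    fasta: Path
    maf: Path
    expression: Path
    sift: Path | None = None
    pph: Path | None = None
    vcf: Path | None = None
    census: Path | None = None
    essential: Path | None = None

    def validate(self) -> None:
        for name, path in dataclasses.asdict(self).items():
            if path is not None and not Path(path).exists():
                raise ValidationError(f"missing input file for {name}: {path}")


@dataclass
class PipelineOptions:
    focal_tissue: str = "tissue01"
    platform: str = "rpkm"
    globality: str = "strict"
    germline_min_freq: float = 0.1
    screen_alpha: float = 0.05
    screen_min_syn: int = 1
    seed: int | None = None


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def _counts_dict(counts) -> dict:
    return _jsonable(counts)


def _group_stats(counts, sites) -> dict:
    """Ratio + vs-1 test for every metric, with archived inputs."""
    out = {
        "counts": _counts_dict(counts),
        "sites": {
            "N": sites.N,
            "S": sites.S,
            "N_missense": sites.N_missense,
            "MF_sift": sites.MF_sift,
            "LF_sift": sites.LF_sift,
            "MF_pph": sites.MF_pph,
            "LF_pph": sites.LF_pph,
        },
    }
    for metric in METRICS:
        out[metric.value] = _jsonable(test_ratio_vs_one(counts, sites, metric))
    return out


def run_pipeline(
    inputs: PipelineInputs, options: PipelineOptions | None = None
) -> dict:
    """Run the whole analysis and return the report as a plain dict."""
    options = options or PipelineOptions()
    inputs.validate()

    filter_log: list[dict] = []

    def log_stage(stage: str, **counts):
        filter_log.append({"stage": stage, **counts})
        logger.info("%s: %s", stage, counts)

    # --- gene models and site counts -------------------------------------
    all_models = read_cds_fasta(inputs.fasta)
    models = select_longest_transcript(all_models)
    log_stage("transcript_selection", transcripts=len(all_models), genes=len(models))

    sift = read_functionality_table(inputs.sift, Scheme.SIFT) if inputs.sift else None
    pph = read_functionality_table(inputs.pph, Scheme.POLYPHEN) if inputs.pph else None
    site_counts = {
        gid: compute_site_counts(m, sift, pph) for gid, m in models.items()
    }

    # --- somatic records ---------------------------------------------------
    raw = read_maf(inputs.maf)
    classified, rejected = classify_records(raw, models, sift, pph)
    assert len(classified) + len(rejected) == len(raw)
    log_stage("classification", input=len(raw), kept=len(classified), rejected=len(rejected))

    deduped = deduplicate_within_tumor(classified)
    log_stage(
        "dedup_within_tumor",
        input=len(classified),
        kept=len(deduped),
        removed=len(classified) - len(deduped),
    )

    somatic, removed = apply_nonsense_frameshift_filter(deduped)
    assert len(somatic) + len(removed) == len(deduped)
    log_stage(
        "nonsense_frameshift_filter",
        input=len(deduped),
        kept=len(somatic),
        removed=len(removed),
    )

    # --- germline records --------------------------------------------------
    germline = []
    if inputs.vcf:
        raw_germ = read_germline_vcf(inputs.vcf)
        classified_germ, rejected_germ = classify_records(raw_germ, models, sift, pph)
        germline = filter_germline_by_frequency(
            classified_germ, options.germline_min_freq
        )
        log_stage(
            "germline_frequency_filter",
            input=len(raw_germ),
            classified=len(classified_germ),
            rejected=len(rejected_germ),
            kept=len(germline),
        )

    # --- expression partition ---------------------------------------------
    matrix = read_expression_tsv(inputs.expression)
    profiles = compute_breadth(
        matrix, platform=options.platform, globality=options.globality,
        n_tissues=matrix.shape[1],
    )
    unprofiled = sorted(set(models) - set(profiles))
    if unprofiled:
        logger.warning(
            "%d gene(s) missing from the expression matrix; excluded from partitions",
            len(unprofiled),
        )
    partition = partition_genes(profiles, options.focal_tissue)

    census = read_gene_list(inputs.census) if inputs.census else {
        g for g, m in models.items() if m.is_census
    }
    essential = read_gene_list(inputs.essential) if inputs.essential else {
        g for g, m in models.items() if m.is_essential
    }
    universe = set(models)

    groups = {
        "all": universe,
        "global": partition.global_set,
        "nonglobal": partition.nonglobal_set,
        "nonglobal_expressed_in_focal": partition.nonglobal_expressed_in_focal,
        "nonglobal_not_expressed_in_focal": partition.nonglobal_not_expressed_in_focal,
        "global_no_census": partition.global_set - census,
        "nonglobal_no_census": partition.nonglobal_set - census,
        "census": census & universe,
        "non_census": universe - census,
    }

    # --- group tallies and statistics --------------------------------------
    table1 = {}
    group_counts = {}
    group_sites = {}
    for name, gene_set in groups.items():
        counts = tally_group_counts(somatic, gene_set, name)
        sites = aggregate_site_counts(site_counts, gene_set)
        group_counts[name], group_sites[name] = counts, sites
        if sites.syn_changes == 0:
            logger.warning("group %s has no site counts; skipped", name)
            continue
        table1[name] = _group_stats(counts, sites)

    comparisons = {}
    comparison_pairs = [
        ("global", "nonglobal"),
        ("global", "nonglobal_expressed_in_focal"),
        ("global", "nonglobal_not_expressed_in_focal"),
        ("global_no_census", "nonglobal_no_census"),
        ("census", "non_census"),
    ]
    for a, b in comparison_pairs:
        if group_sites[a].syn_changes == 0 or group_sites[b].syn_changes == 0:
            continue
        comparisons[f"{a}_vs_{b}"] = {
            metric.value: _jsonable(
                compare_groups(
                    group_counts[a], group_sites[a],
                    group_counts[b], group_sites[b], metric,
                )
            )
            for metric in METRICS
        }

    # --- somatic vs germline (Fig-1-style) ---------------------------------
    somatic_vs_germline = {"somatic": table1.get("all")}
    if germline:
        germ_counts = tally_group_counts(germline, universe, "germline")
        germ_sites = group_sites["all"]
        somatic_vs_germline["germline"] = _group_stats(germ_counts, germ_sites)

    # --- per-gene screen and enrichments -----------------------------------
    screen = per_gene_screen(
        somatic,
        site_counts,
        alpha=options.screen_alpha,
        min_syn=options.screen_min_syn,
    )
    flagged = {r.gene_id for r in screen if r.significant_above_one}
    strict_flagged = {r.gene_id for r in screen if r.strict_above_one}
    screened_universe = {r.gene_id for r in screen}

    enrichments = {}
    if flagged:
        for name, annot in (
            ("census", census),
            ("essential", essential),
            ("global_expression", partition.global_set),
        ):
            enrichments[name] = _jsonable(
                list_enrichment(
                    flagged, annot & screened_universe, screened_universe
                )
            )

    coverage = None
    driver_set = census & universe
    patients = {r.patient_id for r in somatic if r.patient_id}
    if driver_set and patients:
        coverage = patient_zero_hit_summary(somatic, driver_set, patients)

    histogram = None
    if census & set(profiles):
        histogram = _jsonable(breadth_histogram(profiles, census & set(profiles)))

    # --- provenance ---------------------------------------------------------
    config_repr = json.dumps(
        {
            "inputs": _jsonable(dataclasses.asdict(inputs)),
            "options": _jsonable(dataclasses.asdict(options)),
        },
        sort_keys=True,
    )
    report = {
        "provenance": {
            "tool": "somasel",
            "version": __version__,
            "seed": options.seed,
            "config_sha256": hashlib.sha256(config_repr.encode()).hexdigest(),
            "options": _jsonable(dataclasses.asdict(options)),
        },
        "filter_log": filter_log,
        "n_genes": len(models),
        "group_sizes": {name: len(gs) for name, gs in groups.items()},
        "table1": table1,
        "group_comparisons": comparisons,
        "somatic_vs_germline": somatic_vs_germline,
        "screen": {
            "alpha": options.screen_alpha,
            "n_screened": len(screen),
            "n_tested": sum(1 for r in screen if r.p_value is not None),
            "n_flagged": len(flagged),
            "n_strict_flagged": len(strict_flagged),
            "flagged": sorted(flagged),
            "results": [_jsonable(r) for r in screen],
        },
        "enrichments": enrichments,
        "patient_coverage": coverage,
        "census_breadth_histogram": histogram,
    }
    report["_artifacts"] = {
        "somatic_records": somatic,
        "removed_records": removed,
        "germline_records": germline,
        "site_counts": site_counts,
    }
    return report


def write_report(report: dict, outdir: str | Path) -> Path:
    """Write report.json plus TSV side files; returns the JSON path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = report.pop("_artifacts", None)
    if artifacts:
        write_classified_tsv(artifacts["somatic_records"], outdir / "somatic_kept.tsv")
        write_classified_tsv(artifacts["removed_records"], outdir / "somatic_removed.tsv")
        if artifacts["germline_records"]:
            write_classified_tsv(
                artifacts["germline_records"], outdir / "germline_kept.tsv"
            )
        write_site_counts_tsv(
            artifacts["site_counts"].values(), outdir / "site_counts.tsv"
        )
    screen_rows = report["screen"]["results"]
    if screen_rows:
        pd.DataFrame(screen_rows).to_csv(outdir / "screen.tsv", sep="\t", index=False)
    path = outdir / "report.json"
    path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
    return path


def _fmt(value, digits=2) -> str:
    if value is None:
        return "NA"
    return f"{value:.{digits}f}"


def _fmt_p(p) -> str:
    if p is None:
        return "refused"
    if p < 1e-4:
        return "<0.0001"
    return f"{p:.4g}"


def render_report(report: dict) -> str:
    """Markdown rendering of the headline tables."""
    lines = ["# Somatic selection report", ""]
    prov = report["provenance"]
    lines += [
        f"- version: {prov['version']}; seed: {prov['seed']}; "
        f"config: {prov['config_sha256'][:12]}",
        "",
        "## Substitution ratios by gene group",
        "",
        "| group | n | s | dN/dS | P | mf(SIFT) | lf(SIFT) | dMF/dLF(SIFT) | P "
        "| mf(PPH) | lf(PPH) | dMF/dLF(PPH) | P |",
        "|---|---|---|---|---|---|---|---|---|---|---|---|---|",
    ]
    for name, stats in report["table1"].items():
        c = stats["counts"]
        m_sift, m_pph = stats["dmf_dlf_sift"], stats["dmf_dlf_pph"]
        row = [
            name,
            str(c["n"]),
            str(c["s"]),
            _fmt(stats["dn_ds"]["ratio"]),
            _fmt_p(stats["dn_ds"]["p_value"]),
            str(c["mf_sift"]),
            str(c["lf_sift"]),
            _fmt(m_sift["ratio"]),
            _fmt_p(m_sift["p_value"]),
            str(c["mf_pph"]),
            str(c["lf_pph"]),
            _fmt(m_pph["ratio"]),
            _fmt_p(m_pph["p_value"]),
        ]
        lines.append("| " + " | ".join(row) + " |")

    lines += ["", "## Group comparisons (site-composition corrected)", ""]
    lines += ["| comparison | metric | ratio A | ratio B | cf | P |", "|---|---|---|---|---|---|"]
    for name, metrics in report["group_comparisons"].items():
        for metric, comp in metrics.items():
            lines.append(
                "| "
                + " | ".join(
                    [
                        name,
                        metric,
                        _fmt(comp["ratio_a"]),
                        _fmt(comp["ratio_b"]),
                        _fmt(comp["cf"], 3),
                        _fmt_p(comp["p_value"]),
                    ]
                )
                + " |"
            )

    svg = report.get("somatic_vs_germline") or {}
    if svg.get("germline"):
        lines += ["", "## Somatic vs germline ratios", ""]
        lines += ["| dataset | dN/dS | dMF/dLF(SIFT) | dMF/dLF(PPH) |", "|---|---|---|---|"]
        for label in ("somatic", "germline"):
            stats = svg.get(label)
            if not stats:
                continue
            lines.append(
                "| "
                + " | ".join(
                    [
                        label,
                        _fmt(stats["dn_ds"]["ratio"]),
                        _fmt(stats["dmf_dlf_sift"]["ratio"]),
                        _fmt(stats["dmf_dlf_pph"]["ratio"]),
                    ]
                )
                + " |"
            )

    screen = report["screen"]
    lines += [
        "",
        "## Per-gene positive-selection screen",
        "",
        f"- genes screened: {screen['n_screened']} (tested: {screen['n_tested']})",
        f"- flagged at p < {screen['alpha']} with dN/dS > 1: {screen['n_flagged']}",
        f"- strict tier (p < 0.001): {screen['n_strict_flagged']}",
    ]
    if screen["n_flagged"] == 0:
        lines.append("- no genes flagged")

    if report["enrichments"]:
        lines += ["", "## Enrichment of flagged genes", ""]
        lines += [
            "| annotation | overlap | % of flagged | fold | P |",
            "|---|---|---|---|---|",
        ]
        for name, enr in report["enrichments"].items():
            lines.append(
                "| "
                + " | ".join(
                    [
                        name,
                        str(enr["overlap"]),
                        f"{enr['pct_flagged_annotated']:.1f}%",
                        _fmt(enr["fold_enrichment"]),
                        _fmt_p(enr["p_value"]),
                    ]
                )
                + " |"
            )

    cov = report.get("patient_coverage")
    if cov:
        lines += [
            "",
            "## Patient coverage of the designated driver set",
            "",
            f"- {cov['n_zero_hit']} of {cov['n_patients']} patients "
            f"({cov['pct_zero_hit']:.1f}%) carry no retained substitution in the "
            f"{cov['n_genes']} designated genes",
        ]
    return "\n".join(lines) + "\n"
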