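"""Simulation-calibration experiments: cohort -> pooled ratio statistics.

These helpers run the generator and the full record-processing chain
(classify, deduplicate, truncation-filter, tally) in memory and return the
pooled ratio statistics, so calibration and parameter-recovery runs share
one code path with the file-based pipeline.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .selection_stats import Metric, RatioResult, test_ratio_vs_one
from .site_counting import aggregate_site_counts, compute_site_counts
from .synthetic_data import (
    SimConfig,
    generate_functionality_tables,
    generate_gene_models,
    simulate_somatic_cohort,
)
from .variant_processing import (
    apply_nonsense_frameshift_filter,
    classify_records,
    deduplicate_within_tumor,
    select_longest_transcript,
    tally_group_counts,
)


def cohort_ratios(
    config: SimConfig, metrics: tuple[Metric, ...] = (Metric.DN_DS,)
) -> dict[Metric, RatioResult]:
    """Simulate one cohort and return pooled ratio statistics over all genes.

    Functionality tables are generated only when an MF/LF metric is
    requested or the configuration applies an MF boost.
    """
    rng = np.random.default_rng(config.seed)
    models = generate_gene_models(config, rng)
    need_tables = config.mf_boost != 1.0 or any(
        m is not Metric.DN_DS for m in metrics
    )
    sift = pph = None
    if need_tables:
        sift, pph = generate_functionality_tables(models, config, rng)
    records = simulate_somatic_cohort(models, sift, config, rng)

    model_map = select_longest_transcript(models)
    classified, rejected = classify_records(records, model_map, sift, pph)
    if rejected:
        raise AssertionError(f"synthetic cohort produced {len(rejected)} rejects")
    kept, _ = apply_nonsense_frameshift_filter(deduplicate_within_tumor(classified))

    gene_set = set(model_map)
    counts = tally_group_counts(kept, gene_set, "all")
    sites = aggregate_site_counts(
        [compute_site_counts(m, sift, pph) for m in model_map.values()]
    )
    return {metric: test_ratio_vs_one(counts, sites, metric) for metric in metrics}


def ratios_over_seeds(
    config: SimConfig,
    seeds: list[int],
    metrics: tuple[Metric, ...] = (Metric.DN_DS,),
) -> dict[Metric, list[float]]:
    """Pooled ratio per seed; the per-seed spread is the Monte-Carlo error."""
    out: dict[Metric, list[float]] = {m: [] for m in metrics}
    for seed in seeds:
        results = cohort_ratios(replace(config, seed=seed), metrics)
        for metric in metrics:
            ratio = results[metric].ratio
            if ratio is None:
                raise AssertionError(f"undefined {metric.value} at seed {seed}")
            out[metric].append(ratio)
    return out


def bootstrap_interval(
    values: list[float], n_boot: int = 10_000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of per-seed estimates."""
    rng = np.random.default_rng(seed)
    arr = np.asarray(values, dtype=float)
    means = rng.choice(arr, size=(n_boot, arr.size), replace=True).mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)
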