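"""Ratio statistics (dN/dS, dMF/dLF), chi-square tests and enrichment screens.

A ratio statistic divides the per-site rate of the numerator class by the
per-site rate of the denominator class, e.g. dN/dS = (n/N)/(s/S).  Departure
from 1 is tested with a 1-df chi-square comparing the observed class split
of substitutions against the split of sites.  Group comparisons use a 2x2
chi-square after dividing one group's numerator count by a site-composition
correction factor cf = (N_a/S_a)/(N_b/S_b), which is 1 when both groups have
the same site composition.

Because observed substitution counts for the non-synonymous class cover
missense changes only (stop gains are diverted to the truncation filter and
are never scored by the functionality schemes), dN/dS uses the missense-only
site total as its numerator denominator by default; pass
``stop_gain_in_sites=True`` to use the full non-synonymous site total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .site_counting import SiteCounts
from .variant_processing import GroupCounts, SubstitutionRecord, tally_group_counts

logger = logging.getLogger(__name__)

DEFAULT_MIN_EXPECTED = 5.0


class Metric(str, Enum):
    DN_DS = "dn_ds"
    DMF_DLF_SIFT = "dmf_dlf_sift"
    DMF_DLF_PPH = "dmf_dlf_pph"


@dataclass
class RatioResult:
    metric: Metric
    ratio: float | None
    numerator_count: int
    denominator_count: int
    numerator_sites: float
    denominator_sites: float
    chi2_stat: float | None = None
    p_value: float | None = None
    direction: str | None = None  # above_one / below_one / at_one
    undefined: bool = False
    refused: str | None = None


@dataclass
class GroupComparison:
    metric: Metric
    ratio_a: float | None
    ratio_b: float | None
    cf: float
    corrected_n_a: float
    chi2_stat: float | None
    p_value: float | None
    refused: str | None = None


@dataclass
class ScreenResult:
    gene_id: str
    dn_ds: float | None
    p_value: float | None
    q_value: float | None
    n: int
    s: int
    significant_above_one: bool
    strict_above_one: bool
    refused: str | None = None


@dataclass
class EnrichmentResult:
    n_flagged: int
    n_annotation: int
    n_universe: int
    overlap: int
    pct_flagged_annotated: float
    pct_annotation_unflagged: float
    fold_enrichment: float
    chi2_stat: float
    p_value: float


def _extract(
    counts: GroupCounts, sites: SiteCounts, metric: Metric, stop_gain_in_sites: bool
) -> tuple[int, int, float, float]:
    if metric is Metric.DN_DS:
        num_sites = sites.N if stop_gain_in_sites else sites.N_missense
        return counts.n, counts.s, num_sites, sites.S
    if metric is Metric.DMF_DLF_SIFT:
        return counts.mf_sift, counts.lf_sift, sites.MF_sift, sites.LF_sift
    if metric is Metric.DMF_DLF_PPH:
        return counts.mf_pph, counts.lf_pph, sites.MF_pph, sites.LF_pph
    raise ValidationError(f"unknown metric {metric!r}")


def ratio_statistic(
    counts: GroupCounts,
    sites: SiteCounts,
    metric: Metric = Metric.DN_DS,
    stop_gain_in_sites: bool = False,
) -> RatioResult:
    """Per-site rate ratio for one gene group.

    A zero denominator count yields an undefined (None) ratio, flagged
    rather than reported as infinity; zero site totals are an error.
    """
    num, den, num_sites, den_sites = _extract(counts, sites, metric, stop_gain_in_sites)
    if num_sites <= 0 or den_sites <= 0:
        raise ValidationError(
            f"{metric.value}: site totals must be positive "
            f"(got {num_sites}, {den_sites})"
        )
    if den == 0:
        return RatioResult(
            metric, None, num, den, num_sites, den_sites, undefined=True
        )
    ratio = (num / num_sites) / (den / den_sites)
    return RatioResult(metric, ratio, num, den, num_sites, den_sites)


def chi2_counts_vs_sites(
    num_count: int,
    den_count: int,
    num_sites: float,
    den_sites: float,
    min_expected: float = DEFAULT_MIN_EXPECTED,
) -> tuple[float | None, float | None, str | None]:
    """1-df chi-square of an observed count split against the site split.

    Expected counts are the total substitutions apportioned by site
    composition.  Returns (chi2, p, refusal-reason); the test is refused
    when either expected cell falls below ``min_expected``.
    """
    total = num_count + den_count
    site_total = num_sites + den_sites
    expected = np.array(
        [total * num_sites / site_total, total * den_sites / site_total]
    )
    if expected.min() < min_expected:
        return None, None, (
            f"expected count {expected.min():.3f} below {min_expected}"
        )
    observed = np.array([num_count, den_count], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p, None


def test_ratio_vs_one(
    counts: GroupCounts,
    sites: SiteCounts,
    metric: Metric = Metric.DN_DS,
    min_expected: float = DEFAULT_MIN_EXPECTED,
    stop_gain_in_sites: bool = False,
) -> RatioResult:
    """Ratio plus the two-sided chi-square test of departure from 1."""
    result = ratio_statistic(counts, sites, metric, stop_gain_in_sites)
    num, den = result.numerator_count, result.denominator_count
    chi2, p, reason = chi2_counts_vs_sites(
        num, den, result.numerator_sites, result.denominator_sites, min_expected
    )
    result.chi2_stat, result.p_value, result.refused = chi2, p, reason
    if result.ratio is not None:
        if result.ratio > 1:
            result.direction = "above_one"
        elif result.ratio < 1:
            result.direction = "below_one"
        else:
            result.direction = "at_one"
    return result


def compare_groups(
    counts_a: GroupCounts,
    sites_a: SiteCounts,
    counts_b: GroupCounts,
    sites_b: SiteCounts,
    metric: Metric = Metric.DN_DS,
    min_expected: float = DEFAULT_MIN_EXPECTED,
    stop_gain_in_sites: bool = False,
) -> GroupComparison:
    """Site-composition-corrected 2x2 chi-square comparison of two groups.

    Group A's numerator count is divided by cf = (sitesN_a/sitesS_a) /
    (sitesN_b/sitesS_b) before testing {corrected n_a, s_a; n_b, s_b}, so
    composition differences between the groups cannot masquerade as a
    substitution-rate difference.  cf = 1 reduces to the plain 2x2 test.
    """
    n_a, s_a, N_a, S_a = _extract(counts_a, sites_a, metric, stop_gain_in_sites)
    n_b, s_b, N_b, S_b = _extract(counts_b, sites_b, metric, stop_gain_in_sites)
    for label, v in (("A", (N_a, S_a)), ("B", (N_b, S_b))):
        if min(v) <= 0:
            raise ValidationError(f"group {label}: site totals must be positive")
    cf = (N_a / S_a) / (N_b / S_b)
    corrected_n_a = n_a / cf
    table = np.array([[corrected_n_a, s_a], [n_b, s_b]], dtype=float)
    ratio_a = ratio_statistic(counts_a, sites_a, metric, stop_gain_in_sites).ratio
    ratio_b = ratio_statistic(counts_b, sites_b, metric, stop_gain_in_sites).ratio
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return GroupComparison(
            metric, ratio_a, ratio_b, cf, corrected_n_a, None, None,
            refused="degenerate contingency table",
        )
    expected = stats.contingency.expected_freq(table)
    if expected.min() < min_expected:
        return GroupComparison(
            metric, ratio_a, ratio_b, cf, corrected_n_a, None, None,
            refused=f"expected count {expected.min():.3f} below {min_expected}",
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return GroupComparison(
        metric, ratio_a, ratio_b, cf, corrected_n_a, float(chi2), float(p)
    )


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def per_gene_screen(
    records: Iterable[SubstitutionRecord],
    site_counts: Mapping[str, SiteCounts],
    alpha: float = 0.05,
    min_syn: int = 1,
    strict_alpha: float = 0.001,
    min_expected: float = DEFAULT_MIN_EXPECTED,
    stop_gain_in_sites: bool = False,
) -> list[ScreenResult]:
    """Per-gene positive-selection screen on dN/dS.

    Genes with at least ``min_syn`` synonymous substitutions are tested for
    departure from 1; a gene is flagged when its raw p is below alpha with
    dN/dS above 1.  A stricter tier at ``strict_alpha`` and BH q-values are
    reported as auxiliary columns.  Results sort by p then gene id, with
    refused tests last.
    """
    per_gene: dict[str, GroupCounts] = {}
    for rec in records:
        counts = per_gene.setdefault(rec.gene_id, GroupCounts(gene_set_id=rec.gene_id))
        from .site_counting import Effect

        if rec.effect is Effect.MISSENSE:
            counts.n += 1
        elif rec.effect is Effect.SYNONYMOUS:
            counts.s += 1
    results: list[ScreenResult] = []
    for gene_id, counts in per_gene.items():
        if counts.s < min_syn:
            continue
        sites = site_counts.get(gene_id)
        if sites is None:
            logger.warning("screen: no site counts for %s; skipped", gene_id)
            continue
        rr = test_ratio_vs_one(
            counts, sites, Metric.DN_DS, min_expected, stop_gain_in_sites
        )
        results.append(
            ScreenResult(
                gene_id=gene_id,
                dn_ds=rr.ratio,
                p_value=rr.p_value,
                q_value=None,
                n=counts.n,
                s=counts.s,
                significant_above_one=(
                    rr.p_value is not None
                    and rr.p_value < alpha
                    and rr.ratio is not None
                    and rr.ratio > 1
                ),
                strict_above_one=(
                    rr.p_value is not None
                    and rr.p_value < strict_alpha
                    and rr.ratio is not None
                    and rr.ratio > 1
                ),
                refused=rr.refused,
            )
        )
    tested = [r for r in results if r.p_value is not None]
    qs = benjamini_hochberg([r.p_value for r in tested])
    for r, q in zip(tested, qs):
        r.q_value = q
    results.sort(
        key=lambda r: (r.p_value is None, r.p_value if r.p_value is not None else 1.0, r.gene_id)
    )
    return results


def list_enrichment(
    flagged_set: set[str], annotation_set: set[str], universe: set[str]
) -> EnrichmentResult:
    """2x2 enrichment of an annotation within a flagged gene set.

    Reports the overlap, the annotated percentage of flagged genes, the
    complementary unflagged percentage of the annotation set, the fold
    enrichment over the universe base rate, and a chi-square p-value.
    """
    if not flagged_set:
        raise ValidationError("empty flagged set")
    if not flagged_set <= universe or not annotation_set <= universe:
        raise ValidationError("flagged and annotation sets must lie in the universe")
    overlap = len(flagged_set & annotation_set)
    n_flag, n_annot, n_univ = len(flagged_set), len(annotation_set), len(universe)
    table = np.array(
        [
            [overlap, n_flag - overlap],
            [n_annot - overlap, n_univ - n_flag - n_annot + overlap],
        ],
        dtype=float,
    )
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    base_rate = n_annot / n_univ
    return EnrichmentResult(
        n_flagged=n_flag,
        n_annotation=n_annot,
        n_universe=n_univ,
        overlap=overlap,
        pct_flagged_annotated=100.0 * overlap / n_flag,
        pct_annotation_unflagged=(
            100.0 * (n_annot - overlap) / n_annot if n_annot else float("nan")
        ),
        fold_enrichment=(overlap / n_flag) / base_rate if base_rate else float("nan"),
        chi2_stat=float(chi2),
        p_value=float(p),
    )
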