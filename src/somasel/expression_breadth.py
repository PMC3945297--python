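"""Tissue-expression breadth classification and gene-group partitioning.

A gene is "expressed" in a tissue when its value clears the platform
threshold (intensity strictly above 100, or at least 1 RPKM); breadth is the
number of tissues cleared, and globally expressed genes are those expressed
in all examined tissues (relaxed mode: all but up to two).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

N_TISSUES = 16
RELAXED_MIN_BREADTH = 14

DEFAULT_BINS: tuple[tuple[int, int], ...] = (
    (0, 0),
    (1, 3),
    (4, 6),
    (7, 9),
    (10, 12),
    (13, 15),
    (16, 16),
)


@dataclass(frozen=True)
class ExpressionProfile:
    gene_id: str
    tissues: tuple[str, ...]
    expressed_in: tuple[bool, ...]
    is_global: bool

    @property
    def breadth(self) -> int:
        return sum(self.expressed_in)

    def expressed(self, tissue: str) -> bool:
        return self.expressed_in[self.tissues.index(tissue)]


@dataclass
class GenePartition:
    focal_tissue: str
    global_set: set[str]
    nonglobal_set: set[str]
    nonglobal_expressed_in_focal: set[str]
    nonglobal_not_expressed_in_focal: set[str]


def is_expressed(values: np.ndarray, platform: str) -> np.ndarray:
    if platform == "intensity":
        return values > 100.0
    if platform == "rpkm":
        return values >= 1.0
    raise ValidationError(f"unknown expression platform {platform!r}")


def compute_breadth(
    matrix: pd.DataFrame,
    platform: str = "rpkm",
    globality: str = "strict",
    n_tissues: int = N_TISSUES,
) -> dict[str, ExpressionProfile]:
    """Breadth profiles from a genes x tissues matrix.

    The matrix is indexed by gene id with one column per tissue.  ``strict``
    globality requires expression in every tissue; ``relaxed`` requires
    expression in at least 14 of 16 (scaled proportionally for other tissue
    counts).
    """
    if matrix.shape[1] != n_tissues:
        raise ValidationError(
            f"expected {n_tissues} tissue columns, got {matrix.shape[1]}"
        )
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("expression values must be non-negative")
    if globality == "strict":
        min_breadth = n_tissues
    elif globality == "relaxed":
        min_breadth = n_tissues - (N_TISSUES - RELAXED_MIN_BREADTH)
    else:
        raise ValidationError(f"unknown globality mode {globality!r}")
    expressed = is_expressed(values, platform)
    tissues = tuple(str(c) for c in matrix.columns)
    profiles = {}
    for gene_id, row in zip(matrix.index, expressed):
        breadth = int(row.sum())
        profiles[str(gene_id)] = ExpressionProfile(
            gene_id=str(gene_id),
            tissues=tissues,
            expressed_in=tuple(bool(v) for v in row),
            is_global=breadth >= min_breadth,
        )
    return profiles


def partition_genes(
    profiles: Mapping[str, ExpressionProfile], focal_tissue: str
) -> GenePartition:
    """Split profiled genes into the four groups compared in the analysis."""
    any_profile = next(iter(profiles.values()), None)
    if any_profile is not None and focal_tissue not in any_profile.tissues:
        raise ValidationError(f"unknown focal tissue {focal_tissue!r}")
    part = GenePartition(focal_tissue, set(), set(), set(), set())
    for gene_id, prof in profiles.items():
        if prof.is_global:
            part.global_set.add(gene_id)
        else:
            part.nonglobal_set.add(gene_id)
            if prof.expressed(focal_tissue):
                part.nonglobal_expressed_in_focal.add(gene_id)
            else:
                part.nonglobal_not_expressed_in_focal.add(gene_id)
    return part


def _bin_label(lo: int, hi: int) -> str:
    return str(lo) if lo == hi else f"{lo}-{hi}"


def _chi2_2x2(table: np.ndarray, min_expected: float = 5.0):
    """(chi2, p, reason) for a 2x2 with the expected-count guard."""
    table = np.asarray(table, dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 0.0, 1.0, None
    expected = stats.contingency.expected_freq(table)
    if expected.min() < min_expected:
        return None, None, f"expected count {expected.min():.2f} below {min_expected}"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), None


def breadth_histogram(
    profiles: Mapping[str, ExpressionProfile],
    flag_set: set[str],
    bins: Sequence[tuple[int, int]] = DEFAULT_BINS,
) -> dict:
    """Breadth distribution of flagged vs remaining genes, with tests.

    Returns per-bin frequencies for both groups plus 2x2 chi-square tests of
    the top (all-tissues) bin and the tissue-specific (breadth 0-3) tail.
    Tests are refused (p None, with a reason) when expected counts are too
    small.
    """
    if not flag_set:
        raise ValidationError("empty flag set")
    unknown = flag_set - set(profiles)
    if unknown:
        raise ValidationError(f"flagged genes not profiled: {sorted(unknown)[:5]}")
    flagged_b = [profiles[g].breadth for g in profiles if g in flag_set]
    other_b = [profiles[g].breadth for g in profiles if g not in flag_set]

    def bin_counts(breadths):
        return [sum(1 for b in breadths if lo <= b <= hi) for lo, hi in bins]

    flag_counts, other_counts = bin_counts(flagged_b), bin_counts(other_b)
    n_flag, n_other = len(flagged_b), len(other_b)

    def tail_test(in_tail):
        f_in = sum(1 for b in flagged_b if in_tail(b))
        o_in = sum(1 for b in other_b if in_tail(b))
        chi2, p, reason = _chi2_2x2(
            [[f_in, n_flag - f_in], [o_in, n_other - o_in]]
        )
        return {
            "flagged_in": f_in,
            "other_in": o_in,
            "flagged_freq": f_in / n_flag if n_flag else float("nan"),
            "other_freq": o_in / n_other if n_other else float("nan"),
            "chi2": chi2,
            "p_value": p,
            "refused": reason,
        }

    max_breadth = max(hi for _, hi in bins)
    return {
        "bins": [_bin_label(lo, hi) for lo, hi in bins],
        "flagged_counts": flag_counts,
        "other_counts": other_counts,
        "flagged_freq": [c / n_flag for c in flag_counts] if n_flag else [],
        "other_freq": [c / n_other for c in other_counts] if n_other else [],
        "global_bin_test": tail_test(lambda b: b == max_breadth),
        "tissue_specific_test": tail_test(lambda b: b <= 3),
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Expression matrix TSV: gene_id column + one column per tissue."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValidationError(f"{path}: missing gene_id column")
    return df.set_index("gene_id")


def write_partition(partition: GenePartition, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    named = {
        "global": partition.global_set,
        "nonglobal": partition.nonglobal_set,
        "nonglobal_expressed_in_focal": partition.nonglobal_expressed_in_focal,
        "nonglobal_not_expressed_in_focal": partition.nonglobal_not_expressed_in_focal,
    }
    for name, genes in named.items():
        (outdir / f"{name}.txt").write_text(
            "\n".join(sorted(genes)) + ("\n" if genes else "")
        )


def read_gene_list(path: str | Path) -> set[str]:
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}
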