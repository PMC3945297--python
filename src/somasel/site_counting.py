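"""Per-gene counting of synonymous/non-synonymous and functional sites.

Sites are counted by unweighted enumeration of the three alternate bases at
every coding position: each possible single-base change contributes 1/3 of a
site to the category of its effect.  Functional (MF/LF) sites are the subset
of possible missense changes classified as damaging / benign by a
SIFT-like score table (damaging iff score <= 0.05) or a PolyPhen-like class
table (damaging iff possibly/probably damaging).

All tallies are kept as integer change counts; the fractional site totals
(N, S, MF, LF) are exposed as ``count / 3`` properties so that aggregation
over genes stays exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import _codon
from ._codon import (
    BASES,
    CODON_TO_AA,
    EFFECT64,
    MISSENSE_ALT_AAS,
    STOP_CODONS,
    codon_index,
    encode_cds,
)
from .errors import SchemeMismatchError, ValidationError

logger = logging.getLogger(__name__)

SIFT_DAMAGING_CUTOFF = 0.05  # score <= cutoff is damaging (MF)

POLYPHEN_CLASSES = ("benign", "possibly_damaging", "probably_damaging")
POLYPHEN_DAMAGING = frozenset({"possibly_damaging", "probably_damaging"})


class Effect(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"


_EFFECT_BY_CODE = {
    _codon.EFFECT_SYNONYMOUS: Effect.SYNONYMOUS,
    _codon.EFFECT_MISSENSE: Effect.MISSENSE,
    _codon.EFFECT_NONSENSE: Effect.NONSENSE,
}


class Scheme(str, Enum):
    SIFT = "sift"
    POLYPHEN = "polyphen"


@dataclass(frozen=True)
class GeneModel:
    """One coding transcript representing a gene (post longest-transcript pick)."""

    gene_id: str
    transcript_id: str
    cds: str
    is_census: bool = False
    is_essential: bool = False

    def __post_init__(self):
        object.__setattr__(self, "cds", self.cds.upper())
        if len(self.cds) < 3:
            raise ValidationError(
                f"{self.gene_id}/{self.transcript_id}: CDS shorter than one codon"
            )


@dataclass
class FunctionalityTable:
    """Per-change functionality predictions keyed by (gene, protein pos, alt aa).

    For the SIFT-like scheme values are scores in [0, 1]; for the
    PolyPhen-like scheme values are class strings.
    """

    scheme: Scheme
    entries: dict[tuple[str, int, str], float | str] = field(default_factory=dict)

    def add(self, gene_id: str, protein_pos: int, alt_aa: str, value) -> None:
        if protein_pos < 1:
            raise ValidationError(f"protein position must be >= 1, got {protein_pos}")
        if self.scheme is Scheme.SIFT:
            value = float(value)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"SIFT score out of [0,1]: {value}")
        else:
            if value not in POLYPHEN_CLASSES:
                raise ValidationError(f"unknown PolyPhen class: {value!r}")
        self.entries[(gene_id, protein_pos, alt_aa)] = value

    def is_damaging(self, gene_id: str, protein_pos: int, alt_aa: str) -> bool | None:
        """True if MF, False if LF, None if the change is unscored."""
        value = self.entries.get((gene_id, protein_pos, alt_aa))
        if value is None:
            return None
        if self.scheme is Scheme.SIFT:
            return value <= SIFT_DAMAGING_CUTOFF
        return value in POLYPHEN_DAMAGING


@dataclass
class SiteCounts:
    """Per-gene change tallies and the derived fractional site totals.

    Integer fields count possible single-base changes; each change is worth
    1/3 of a site.  ``N``/``S`` cover all possible changes of counted codons
    (so stop-gain alternates fall under ``N``); ``N_missense`` restricts to
    amino-acid-altering changes, which is what the functionality schemes and
    the observed missense substitution counts can see.
    """

    gene_id: str
    n_codons_counted: int = 0
    n_codons_skipped: int = 0
    nonsyn_changes: int = 0
    syn_changes: int = 0
    missense_changes: int = 0
    mf_changes_sift: int = 0
    lf_changes_sift: int = 0
    unscored_changes_sift: int = 0
    mf_changes_pph: int = 0
    lf_changes_pph: int = 0
    unscored_changes_pph: int = 0

    @property
    def N(self) -> float:
        return self.nonsyn_changes / 3

    @property
    def S(self) -> float:
        return self.syn_changes / 3

    @property
    def N_missense(self) -> float:
        return self.missense_changes / 3

    @property
    def nonsense_sites(self) -> float:
        return (self.nonsyn_changes - self.missense_changes) / 3

    @property
    def MF_sift(self) -> float:
        return self.mf_changes_sift / 3

    @property
    def LF_sift(self) -> float:
        return self.lf_changes_sift / 3

    @property
    def MF_pph(self) -> float:
        return self.mf_changes_pph / 3

    @property
    def LF_pph(self) -> float:
        return self.lf_changes_pph / 3

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        kwargs = {
            f.name: getattr(self, f.name) + getattr(other, f.name)
            for f in fields(self)
            if f.name != "gene_id"
        }
        return SiteCounts(gene_id="<aggregate>", **kwargs)


def validate_cds(gene: GeneModel) -> list[str]:
    """Split the CDS into codons, dropping a terminal stop; raise on defects.

    Returns the list of codons to count (terminal stop excluded).  A CDS
    whose length is not a multiple of 3, or that contains an internal stop
    codon, fails validation.  Codons with ambiguity codes are returned as-is
    and skipped by the counters.
    """
    cds = gene.cds
    if len(cds) % 3 != 0:
        raise ValidationError(
            f"{gene.gene_id}: CDS length {len(cds)} not divisible by 3"
        )
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValidationError(
                f"{gene.gene_id}: internal stop codon {codon} at codon {i + 1}"
            )
    return codons


def enumerate_possible_changes(
    codon: str,
) -> list[tuple[int, str, Effect]]:
    """List the 9 single-base changes of a codon with their coding effect.

    Returns ``(position in codon [0..2], alternate base, effect)`` tuples.
    Ambiguous codons and stop codons are rejected.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValidationError(f"ambiguous or malformed codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValidationError(f"stop codon {codon} has no counted changes")
    ci = codon_index(codon)
    out = []
    for pos in range(3):
        for alt_idx, alt in enumerate(BASES):
            code = EFFECT64[ci, pos, alt_idx]
            if code == _codon._NO_CHANGE:
                continue
            out.append((pos, alt, _EFFECT_BY_CODE[int(code)]))
    return out


def _counted_codon_indices(gene: GeneModel) -> tuple[np.ndarray, int]:
    """Codon indices of counted codons plus the number skipped for ambiguity."""
    codons = validate_cds(gene)
    if not codons:
        return np.empty(0, dtype=np.int64), 0
    enc = encode_cds("".join(codons)).reshape(-1, 3)
    ok = (enc >= 0).all(axis=1)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning(
            "%s: skipped %d codon(s) containing ambiguity codes",
            gene.gene_id,
            n_skipped,
        )
    enc = enc[ok].astype(np.int64)
    idx = enc[:, 0] * 16 + enc[:, 1] * 4 + enc[:, 2]
    # positions of counted codons within the codon list are needed for
    # protein coordinates, so return a masked index array instead
    full = np.full(len(codons), -1, dtype=np.int64)
    full[ok] = idx
    return full, n_skipped


def count_syn_nonsyn_sites(gene: GeneModel) -> SiteCounts:
    """Count non-synonymous and synonymous sites for one gene.

    Each coding position contributes (#non-synonymous alternates)/3 to N and
    (#synonymous alternates)/3 to S, so N + S equals 3 x counted codons.
    """
    idx, n_skipped = _counted_codon_indices(gene)
    counted = idx[idx >= 0]
    return SiteCounts(
        gene_id=gene.gene_id,
        n_codons_counted=int(counted.size),
        n_codons_skipped=n_skipped,
        nonsyn_changes=int(_codon.NONSYN_CHANGES64[counted].sum()),
        syn_changes=int(_codon.SYN_CHANGES64[counted].sum()),
        missense_changes=int(_codon.MISSENSE_CHANGES64[counted].sum()),
    )


def count_functional_sites(
    gene: GeneModel,
    table: FunctionalityTable,
    scheme: Scheme | None = None,
) -> SiteCounts:
    """Count MF/LF sites for one gene under one functionality scheme.

    Every possible missense change contributes 1/3 of a site to MF if the
    table classifies it damaging, else 1/3 to LF; synonymous and stop-gain
    changes belong to neither class, and unscored missense changes are
    tallied separately and excluded from both totals.
    """
    if scheme is not None and table.scheme is not scheme:
        raise SchemeMismatchError(
            f"expected {scheme.value} table, got {table.scheme.value}"
        )
    counts = count_syn_nonsyn_sites(gene)
    if not table.entries:
        logger.warning("%s: empty %s table; MF = LF = 0", gene.gene_id, table.scheme.value)
        return counts
    idx, _ = _counted_codon_indices(gene)
    mf = lf = unscored = 0
    for codon_i, ci in enumerate(idx):
        if ci < 0:  # ambiguous codon, skipped
            continue
        protein_pos = codon_i + 1
        for alt_aa, mult in MISSENSE_ALT_AAS[ci]:
            verdict = table.is_damaging(gene.gene_id, protein_pos, alt_aa)
            if verdict is None:
                unscored += mult
            elif verdict:
                mf += mult
            else:
                lf += mult
    if unscored:
        logger.debug(
            "%s: %d possible missense change(s) unscored by %s",
            gene.gene_id,
            unscored,
            table.scheme.value,
        )
    if table.scheme is Scheme.SIFT:
        counts.mf_changes_sift, counts.lf_changes_sift = mf, lf
        counts.unscored_changes_sift = unscored
    else:
        counts.mf_changes_pph, counts.lf_changes_pph = mf, lf
        counts.unscored_changes_pph = unscored
    return counts


def compute_site_counts(
    gene: GeneModel,
    sift_table: FunctionalityTable | None = None,
    pph_table: FunctionalityTable | None = None,
) -> SiteCounts:
    """N/S plus MF/LF under any provided schemes, in one SiteCounts."""
    counts = count_syn_nonsyn_sites(gene)
    if sift_table is not None:
        sc = count_functional_sites(gene, sift_table, Scheme.SIFT)
        counts.mf_changes_sift = sc.mf_changes_sift
        counts.lf_changes_sift = sc.lf_changes_sift
        counts.unscored_changes_sift = sc.unscored_changes_sift
    if pph_table is not None:
        pc = count_functional_sites(gene, pph_table, Scheme.POLYPHEN)
        counts.mf_changes_pph = pc.mf_changes_pph
        counts.lf_changes_pph = pc.lf_changes_pph
        counts.unscored_changes_pph = pc.unscored_changes_pph
    return counts


def aggregate_site_counts(
    site_counts: Iterable[SiteCounts] | Mapping[str, SiteCounts],
    gene_set: set[str] | None = None,
) -> SiteCounts:
    """Sum SiteCounts over a gene set (all genes when gene_set is None)."""
    if isinstance(site_counts, Mapping):
        site_counts = site_counts.values()
    total = SiteCounts(gene_id="<aggregate>")
    for sc in site_counts:
        if gene_set is None or sc.gene_id in gene_set:
            total = total + replace(sc, gene_id="<aggregate>")
    return total


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cds_fasta(path: str | Path) -> list[GeneModel]:
    """Read gene models from FASTA.

    Header convention: first token is the transcript id; ``gene=``,
    ``census=`` and ``essential=`` key/value attributes follow.
    """
    models = []
    for rec in SeqIO.parse(str(path), "fasta"):
        attrs = dict(
            tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
        )
        if "gene" not in attrs:
            raise ValidationError(f"{path}: record {rec.id} lacks a gene= attribute")
        models.append(
            GeneModel(
                gene_id=attrs["gene"],
                transcript_id=rec.id,
                cds=str(rec.seq),
                is_census=attrs.get("census", "0") == "1",
                is_essential=attrs.get("essential", "0") == "1",
            )
        )
    return models


def write_cds_fasta(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(
                f">{m.transcript_id} gene={m.gene_id} "
                f"census={int(m.is_census)} essential={int(m.is_essential)}\n"
            )
            for i in range(0, len(m.cds), 60):
                fh.write(m.cds[i : i + 60] + "\n")


def read_functionality_table(path: str | Path, scheme: Scheme) -> FunctionalityTable:
    """Read a TSV with columns gene_id, protein_pos, alt_aa, score|class."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "alt_aa": str})
    value_col = "score" if scheme is Scheme.SIFT else "class"
    required = {"gene_id", "protein_pos", "alt_aa", value_col}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    table = FunctionalityTable(scheme=scheme)
    for gene_id, pos, alt_aa, value in zip(
        df["gene_id"], df["protein_pos"], df["alt_aa"], df[value_col]
    ):
        table.add(gene_id, int(pos), alt_aa, value)
    return table


def write_functionality_table(table: FunctionalityTable, path: str | Path) -> None:
    value_col = "score" if table.scheme is Scheme.SIFT else "class"
    rows = [
        {"gene_id": g, "protein_pos": p, "alt_aa": a, value_col: v}
        for (g, p, a), v in sorted(table.entries.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "protein_pos", "alt_aa", value_col]).to_csv(
        path, sep="\t", index=False
    )


_INT_FIELDS = [f.name for f in fields(SiteCounts) if f.name != "gene_id"]
_FLOAT_COLS = ["N", "S", "N_missense", "MF_sift", "LF_sift", "MF_pph", "LF_pph"]


def write_site_counts_tsv(
    site_counts: Iterable[SiteCounts], path: str | Path
) -> None:
    rows = []
    for sc in site_counts:
        row = {"gene_id": sc.gene_id}
        row.update({name: getattr(sc, name) for name in _INT_FIELDS})
        row.update({name: getattr(sc, name) for name in _FLOAT_COLS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_site_counts_tsv(path: str | Path) -> dict[str, SiteCounts]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    out = {}
    for _, row in df.iterrows():
        out[row["gene_id"]] = SiteCounts(
            gene_id=row["gene_id"],
            **{name: int(row[name]) for name in _INT_FIELDS},
        )
    return out
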