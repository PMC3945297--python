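"""Parsing, classification, deduplication and filtering of substitutions.

Somatic substitutions arrive as a minimal MAF-style TSV, germline variants
as VCF with an AF INFO field.  Records are classified against the selected
gene models (effect from the translated codon change, MF/LF labels from the
functionality tables), deduplicated within tumors, and cleaned by the
nonsense/frameshift (patient, gene) exclusion rule before tallying.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ClassificationError, ValidationError
from .site_counting import (
    Effect,
    FunctionalityTable,
    GeneModel,
    Scheme,
    enumerate_possible_changes,
)

logger = logging.getLogger(__name__)

VARIANT_CLASSES = ("SNV", "frameshift_indel")

#: functionality labels carried by classified records
FUNC_MF = "MF"
FUNC_LF = "LF"
FUNC_UNSCORED = "unscored"
FUNC_NA = "not_applicable"


@dataclass(frozen=True)
class SubstitutionRecord:
    """One observed somatic or germline change (germline: empty patient_id)."""

    patient_id: str
    gene_id: str
    transcript_id: str
    cds_pos: int  # 1-based position within the CDS
    ref: str
    alt: str
    variant_class: str = "SNV"
    effect: Effect | None = None
    frameshift_flag: bool = False
    func_class_sift: str = FUNC_NA
    func_class_pph: str = FUNC_NA
    allele_freq: float | None = None

    @property
    def key(self) -> tuple:
        return (self.patient_id, self.gene_id, self.cds_pos, self.ref, self.alt)


@dataclass
class GroupCounts:
    """Substitution tallies over a gene set: numerators of the ratio stats."""

    gene_set_id: str
    n: int = 0  # missense substitutions
    s: int = 0  # synonymous substitutions
    nonsense: int = 0
    mf_sift: int = 0
    lf_sift: int = 0
    mf_pph: int = 0
    lf_pph: int = 0

    def __add__(self, other: "GroupCounts") -> "GroupCounts":
        return GroupCounts(
            gene_set_id=f"{self.gene_set_id}+{other.gene_set_id}",
            n=self.n + other.n,
            s=self.s + other.s,
            nonsense=self.nonsense + other.nonsense,
            mf_sift=self.mf_sift + other.mf_sift,
            lf_sift=self.lf_sift + other.lf_sift,
            mf_pph=self.mf_pph + other.mf_pph,
            lf_pph=self.lf_pph + other.lf_pph,
        )


def select_longest_transcript(
    gene_models: Iterable[GeneModel],
) -> dict[str, GeneModel]:
    """Keep one transcript per gene: longest CDS, ties to the smallest id."""
    chosen: dict[str, GeneModel] = {}
    for model in gene_models:
        cur = chosen.get(model.gene_id)
        if (
            cur is None
            or len(model.cds) > len(cur.cds)
            or (len(model.cds) == len(cur.cds) and model.transcript_id < cur.transcript_id)
        ):
            chosen[model.gene_id] = model
    return chosen


def _func_label(
    table: FunctionalityTable | None, gene_id: str, protein_pos: int, alt_aa: str
) -> str:
    if table is None:
        return FUNC_UNSCORED
    verdict = table.is_damaging(gene_id, protein_pos, alt_aa)
    if verdict is None:
        return FUNC_UNSCORED
    return FUNC_MF if verdict else FUNC_LF


def classify_substitution(
    record: SubstitutionRecord,
    gene_model: GeneModel,
    sift_table: FunctionalityTable | None = None,
    pph_table: FunctionalityTable | None = None,
) -> SubstitutionRecord:
    """Fill effect and MF/LF labels; raise ClassificationError on bad input.

    Frameshift records pass through with frameshift_flag set and no effect.
    """
    if record.variant_class == "frameshift_indel":
        return replace(
            record,
            frameshift_flag=True,
            effect=None,
            func_class_sift=FUNC_NA,
            func_class_pph=FUNC_NA,
        )
    cds = gene_model.cds
    if not 1 <= record.cds_pos <= len(cds):
        raise ClassificationError(
            f"{record.gene_id} pos {record.cds_pos}: outside CDS of length {len(cds)}"
        )
    if cds[record.cds_pos - 1] != record.ref.upper():
        raise ClassificationError(
            f"{record.gene_id} pos {record.cds_pos}: ref {record.ref} does not match "
            f"CDS base {cds[record.cds_pos - 1]}"
        )
    codon_i = (record.cds_pos - 1) // 3
    pos_in_codon = (record.cds_pos - 1) % 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    effect = None
    for pos, alt, eff in enumerate_possible_changes(codon):
        if pos == pos_in_codon and alt == record.alt.upper():
            effect = eff
            break
    if effect is None:
        raise ClassificationError(
            f"{record.gene_id} pos {record.cds_pos}: alt {record.alt} equals ref"
        )
    if effect is not Effect.MISSENSE:
        return replace(
            record,
            effect=effect,
            func_class_sift=FUNC_NA,
            func_class_pph=FUNC_NA,
        )
    mut = codon[:pos_in_codon] + record.alt.upper() + codon[pos_in_codon + 1 :]
    from ._codon import CODON_TO_AA

    alt_aa = CODON_TO_AA[mut]
    protein_pos = codon_i + 1
    return replace(
        record,
        effect=effect,
        func_class_sift=_func_label(sift_table, record.gene_id, protein_pos, alt_aa),
        func_class_pph=_func_label(pph_table, record.gene_id, protein_pos, alt_aa),
    )


def classify_records(
    records: Iterable[SubstitutionRecord],
    gene_models: Mapping[str, GeneModel],
    sift_table: FunctionalityTable | None = None,
    pph_table: FunctionalityTable | None = None,
) -> tuple[list[SubstitutionRecord], list[tuple[SubstitutionRecord, str]]]:
    """Classify a batch; returns (classified, rejected-with-reason)."""
    kept: list[SubstitutionRecord] = []
    rejected: list[tuple[SubstitutionRecord, str]] = []
    for rec in records:
        model = gene_models.get(rec.gene_id)
        if model is None:
            rejected.append((rec, f"unknown gene {rec.gene_id}"))
            continue
        try:
            kept.append(classify_substitution(rec, model, sift_table, pph_table))
        except ClassificationError as exc:
            rejected.append((rec, str(exc)))
    for rec, reason in rejected:
        logger.warning("rejected record %s: %s", rec.key, reason)
    return kept, rejected


def deduplicate_within_tumor(
    records: Sequence[SubstitutionRecord],
) -> list[SubstitutionRecord]:
    """Drop repeats of the same change within one patient; keep cross-patient
    recurrences (identical changes in different patients all count)."""
    seen: set[tuple] = set()
    out = []
    for rec in records:
        if rec.key in seen:
            continue
        seen.add(rec.key)
        out.append(rec)
    return out


def apply_nonsense_frameshift_filter(
    records: Sequence[SubstitutionRecord],
) -> tuple[list[SubstitutionRecord], list[SubstitutionRecord]]:
    """Remove every record of a (patient, gene) that carries a truncating event.

    Post-inactivation changes are presumed free of selection, so the whole
    (patient, gene) group — including the triggering nonsense/frameshift
    record itself — is moved to the removed list.
    """
    tainted = {
        (rec.patient_id, rec.gene_id)
        for rec in records
        if rec.effect is Effect.NONSENSE or rec.frameshift_flag
    }
    kept, removed = [], []
    for rec in records:
        if (rec.patient_id, rec.gene_id) in tainted:
            removed.append(rec)
        else:
            kept.append(rec)
    return kept, removed


def filter_germline_by_frequency(
    records: Sequence[SubstitutionRecord], min_freq: float = 0.1
) -> list[SubstitutionRecord]:
    """Keep germline records with allele frequency strictly above min_freq."""
    out = []
    for rec in records:
        if rec.allele_freq is None:
            logger.warning("germline record %s lacks allele_freq; dropped", rec.key)
            continue
        if rec.allele_freq > min_freq:
            out.append(rec)
    return out


def tally_group_counts(
    records: Iterable[SubstitutionRecord],
    gene_set: set[str],
    gene_set_id: str = "group",
) -> GroupCounts:
    """Count substitutions by class over a gene set.

    n counts missense, s synonymous; mf/lf per scheme are tallied only over
    scored missense records, so mf + lf <= n for each scheme.
    """
    counts = GroupCounts(gene_set_id=gene_set_id)
    if not gene_set:
        logger.warning("empty gene set %r: zero counts", gene_set_id)
        return counts
    for rec in records:
        if rec.gene_id not in gene_set:
            continue
        if rec.effect is Effect.SYNONYMOUS:
            counts.s += 1
        elif rec.effect is Effect.NONSENSE:
            counts.nonsense += 1
        elif rec.effect is Effect.MISSENSE:
            counts.n += 1
            if rec.func_class_sift == FUNC_MF:
                counts.mf_sift += 1
            elif rec.func_class_sift == FUNC_LF:
                counts.lf_sift += 1
            if rec.func_class_pph == FUNC_MF:
                counts.mf_pph += 1
            elif rec.func_class_pph == FUNC_LF:
                counts.lf_pph += 1
    return counts


def patient_zero_hit_summary(
    records: Iterable[SubstitutionRecord],
    gene_set: set[str],
    patient_ids: Iterable[str],
) -> dict:
    """Per-patient coverage of a designated gene set.

    Reports how many cohort patients carry no retained substitution in the
    gene set, as a count and a percentage of the cohort.
    """
    patients = sorted(set(patient_ids))
    if not patients:
        raise ValidationError("empty patient cohort")
    hit = {rec.patient_id for rec in records if rec.gene_id in gene_set}
    n_zero = sum(1 for p in patients if p not in hit)
    return {
        "n_patients": len(patients),
        "n_genes": len(gene_set),
        "n_zero_hit": n_zero,
        "pct_zero_hit": 100.0 * n_zero / len(patients),
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

MAF_COLUMNS = [
    "patient_id",
    "gene_id",
    "transcript_id",
    "cds_pos",
    "ref",
    "alt",
    "variant_class",
]


def read_maf(path: str | Path) -> list[SubstitutionRecord]:
    """Read a minimal MAF-style somatic substitution TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MAF_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.variant_class not in VARIANT_CLASSES:
            raise ValidationError(
                f"{path}:{i}: unknown variant_class {row.variant_class!r}"
            )
        records.append(
            SubstitutionRecord(
                patient_id=row.patient_id,
                gene_id=row.gene_id,
                transcript_id=row.transcript_id,
                cds_pos=int(row.cds_pos),
                ref=row.ref,
                alt=row.alt,
                variant_class=row.variant_class,
                frameshift_flag=row.variant_class == "frameshift_indel",
            )
        )
    return records


def write_maf(records: Iterable[SubstitutionRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "gene_id": r.gene_id,
            "transcript_id": r.transcript_id,
            "cds_pos": r.cds_pos,
            "ref": r.ref,
            "alt": r.alt,
            "variant_class": r.variant_class,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MAF_COLUMNS).to_csv(path, sep="\t", index=False)


def write_classified_tsv(
    records: Iterable[SubstitutionRecord], path: str | Path
) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "gene_id": r.gene_id,
            "transcript_id": r.transcript_id,
            "cds_pos": r.cds_pos,
            "ref": r.ref,
            "alt": r.alt,
            "variant_class": r.variant_class,
            "effect": r.effect.value if r.effect else "",
            "frameshift_flag": int(r.frameshift_flag),
            "func_class_sift": r.func_class_sift,
            "func_class_pph": r.func_class_pph,
            "allele_freq": "" if r.allele_freq is None else r.allele_freq,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_germline_vcf(path: str | Path) -> list[SubstitutionRecord]:
    """Read germline SNVs from VCF.

    CDS-space coordinates are carried in INFO (GENE, TRANSCRIPT, CDS_POS)
    and the allele frequency in AF.  Multi-allelic records are split into
    one record per alternate allele; AF may be a per-allele list.
    """
    from cyvcf2 import VCF

    records = []
    for variant in VCF(str(path)):
        gene = variant.INFO.get("GENE")
        transcript = variant.INFO.get("TRANSCRIPT") or ""
        cds_pos = variant.INFO.get("CDS_POS")
        if gene is None or cds_pos is None:
            logger.warning(
                "%s:%s lacks GENE/CDS_POS annotation; skipped", variant.CHROM, variant.POS
            )
            continue
        af = variant.INFO.get("AF")
        afs: list[float | None]
        if af is None:
            afs = [None] * len(variant.ALT)
        elif isinstance(af, (tuple, list)):
            afs = [float(a) for a in af]
        else:
            afs = [float(af)] * len(variant.ALT)
        for alt, freq in zip(variant.ALT, afs):
            if len(variant.REF) != 1 or len(alt) != 1:
                continue  # indels are not germline substitutions here
            records.append(
                SubstitutionRecord(
                    patient_id="",
                    gene_id=gene,
                    transcript_id=transcript,
                    cds_pos=int(cds_pos),
                    ref=variant.REF,
                    alt=alt,
                    allele_freq=freq,
                )
            )
    return records
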