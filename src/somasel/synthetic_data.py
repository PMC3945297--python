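"""Deterministic generators for every input the analysis consumes.

The simulator emulates the shape of the real inputs (tumor cohort MAF,
germline VCF with allele frequencies, per-change functionality tables,
tissue expression matrix, gene lists) with configurable selection structure:
raw mutations fall uniformly over coding sites with equal probability of the
three alternate bases, and selection acts as acceptance sampling — a
synonymous mutation is always retained, a less-functional missense mutation
with probability ``nonsyn_retention``, a more-functional missense mutation
with probability ``min(1, nonsyn_retention * mf_boost)``, and a stop gain
with probability ``nonsense_rate``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._codon import AA64, BASES, EFFECT64, MUTANT64
from . import _codon
from .errors import ValidationError
from .site_counting import (
    FunctionalityTable,
    GeneModel,
    Scheme,
    encode_cds,
    write_cds_fasta,
    write_functionality_table,
)
from .variant_processing import SubstitutionRecord, write_maf

logger = logging.getLogger(__name__)

_SENSE_CODON_INDICES = np.flatnonzero(~_codon.IS_STOP64)


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort; the seed fully determines output."""

    n_genes: int = 200
    cds_length_range: tuple[int, int] = (300, 1500)
    gc_content: float = 0.5
    n_patients: int = 300
    mutation_rate: float = 100.0  # expected mutations / patient / Mb of CDS
    nonsyn_retention: float = 1.0  # purifying strength on missense (1 = neutral)
    mf_boost: float = 1.0  # positive-selection multiplier on MF missense
    nonsense_rate: float = 0.5  # retention probability of stop gains
    mf_fraction: float = 0.5  # fraction of missense changes scored MF
    scheme_agreement: float = 0.9  # P(the two schemes agree on a change)
    duplicate_rate: float = 0.0  # P(emit a within-patient duplicate record)
    frameshift_rate: float = 0.0  # expected frameshift events / patient
    global_fraction: float = 0.4
    census_fraction: float = 0.05
    essential_fraction: float = 0.2
    n_germline_sites: int = 5000
    germline_nonsyn_retention: float = 0.1
    germline_af_alpha_beta: tuple[float, float] = (0.5, 0.5)
    n_tissues: int = 16
    focal_tissue: str = "tissue01"
    seed: int = 0

    def __post_init__(self):
        for name in (
            "gc_content",
            "nonsyn_retention",
            "nonsense_rate",
            "mf_fraction",
            "scheme_agreement",
            "duplicate_rate",
            "global_fraction",
            "census_fraction",
            "essential_fraction",
            "germline_nonsyn_retention",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.mf_boost < 1.0:
            raise ValidationError("mf_boost must be >= 1")
        lo, hi = self.cds_length_range
        if lo < 3 or hi < lo:
            raise ValidationError(f"infeasible cds_length_range {self.cds_length_range}")
        if self.nonsyn_retention * self.mf_boost > 1.0:
            logger.warning(
                "nonsyn_retention * mf_boost = %.3f > 1; MF retention clipped to 1",
                self.nonsyn_retention * self.mf_boost,
            )

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(self.n_tissues)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cds_length_range"] = list(d["cds_length_range"])
        d["germline_af_alpha_beta"] = list(d["germline_af_alpha_beta"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("cds_length_range", "germline_af_alpha_beta"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _rng(config: SimConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def generate_gene_models(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Random stop-free CDSs starting with ATG, with census/essential flags."""
    rng = _rng(config, rng)
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    # weight the 61 sense codons by their base composition
    codon_w = np.array(
        [
            base_p[ci // 16] * base_p[(ci // 4) % 4] * base_p[ci % 4]
            for ci in _SENSE_CODON_INDICES
        ]
    )
    codon_w /= codon_w.sum()
    lo, hi = config.cds_length_range
    models = []
    codon_strings = np.array(_codon.ALL_CODONS)
    for i in range(config.n_genes):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        body = rng.choice(_SENSE_CODON_INDICES, size=max(n_codons - 1, 0), p=codon_w)
        cds = "ATG" + "".join(codon_strings[body])
        models.append(
            GeneModel(
                gene_id=f"g{i + 1:05d}",
                transcript_id=f"t{i + 1:05d}",
                cds=cds,
                is_census=bool(rng.random() < config.census_fraction),
                is_essential=bool(rng.random() < config.essential_fraction),
            )
        )
    return models


def generate_functionality_tables(
    models: Sequence[GeneModel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[FunctionalityTable, FunctionalityTable]:
    """Score every possible missense change under both schemes.

    MF status is Bernoulli(mf_fraction) per change; the PolyPhen-like scheme
    agrees with the SIFT-like call with probability ``scheme_agreement``.
    """
    rng = _rng(config, rng)
    keys: list[tuple[str, int, str]] = []
    for model in models:
        enc = encode_cds(model.cds).reshape(-1, 3).astype(np.int64)
        idx = enc[:, 0] * 16 + enc[:, 1] * 4 + enc[:, 2]
        for codon_i, ci in enumerate(idx):
            for alt_aa, _ in _codon.MISSENSE_ALT_AAS[ci]:
                keys.append((model.gene_id, codon_i + 1, alt_aa))
    m = len(keys)
    is_mf = rng.random(m) < config.mf_fraction
    agree = rng.random(m) < config.scheme_agreement
    pph_mf = np.where(agree, is_mf, ~is_mf)
    sift_scores = np.where(
        is_mf, rng.uniform(0.0, 0.05, m), rng.uniform(0.0500001, 1.0, m)
    )
    pph_prob = rng.random(m) < 0.5
    sift = FunctionalityTable(scheme=Scheme.SIFT)
    pph = FunctionalityTable(scheme=Scheme.POLYPHEN)
    for key, score, mf_p, prob in zip(keys, sift_scores, pph_mf, pph_prob):
        sift.entries[key] = float(score)
        pph.entries[key] = (
            ("probably_damaging" if prob else "possibly_damaging") if mf_p else "benign"
        )
    return sift, pph


@dataclass
class _SiteIndex:
    """Flattened per-base view of a gene set, for vectorised mutation draws."""

    gene_ids: list[str]
    transcript_ids: list[str]
    gene_of_site: np.ndarray
    cds_pos_of_site: np.ndarray  # 1-based
    ref_base_of_site: np.ndarray
    codon_index_of_site: np.ndarray
    codon_ordinal_of_site: np.ndarray  # 0-based codon number within the gene
    pos_in_codon_of_site: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.gene_of_site.size


def _build_site_index(models: Sequence[GeneModel]) -> _SiteIndex:
    gene_of, cds_pos, ref, codon_idx, codon_ord, pos_in = [], [], [], [], [], []
    for gi, model in enumerate(models):
        enc = encode_cds(model.cds)
        L = enc.size
        codons = enc.reshape(-1, 3).astype(np.int64)
        idx = codons[:, 0] * 16 + codons[:, 1] * 4 + codons[:, 2]
        gene_of.append(np.full(L, gi, dtype=np.int64))
        cds_pos.append(np.arange(1, L + 1, dtype=np.int64))
        ref.append(enc.astype(np.int64))
        codon_idx.append(np.repeat(idx, 3))
        codon_ord.append(np.repeat(np.arange(L // 3, dtype=np.int64), 3))
        pos_in.append(np.tile(np.arange(3, dtype=np.int64), L // 3))
    return _SiteIndex(
        gene_ids=[m.gene_id for m in models],
        transcript_ids=[m.transcript_id for m in models],
        gene_of_site=np.concatenate(gene_of),
        cds_pos_of_site=np.concatenate(cds_pos),
        ref_base_of_site=np.concatenate(ref),
        codon_index_of_site=np.concatenate(codon_idx),
        codon_ordinal_of_site=np.concatenate(codon_ord),
        pos_in_codon_of_site=np.concatenate(pos_in),
    )


def _retention_probs(
    effect_code: np.ndarray,
    mf_mask: np.ndarray,
    nonsyn_retention: float,
    mf_boost: float,
    nonsense_rate: float,
) -> np.ndarray:
    probs = np.ones(effect_code.size)
    missense = effect_code == _codon.EFFECT_MISSENSE
    probs[missense & ~mf_mask] = nonsyn_retention
    probs[missense & mf_mask] = min(1.0, nonsyn_retention * mf_boost)
    probs[effect_code == _codon.EFFECT_NONSENSE] = nonsense_rate
    return probs


def _mf_mask(
    site_index: _SiteIndex,
    sites: np.ndarray,
    alts: np.ndarray,
    sift_table: FunctionalityTable | None,
) -> np.ndarray:
    """True where the mutation is missense and SIFT-like-scored damaging."""
    mask = np.zeros(sites.size, dtype=bool)
    if sift_table is None:
        return mask
    ci = site_index.codon_index_of_site[sites]
    pos = site_index.pos_in_codon_of_site[sites]
    effect = EFFECT64[ci, pos, alts]
    missense_idx = np.flatnonzero(effect == _codon.EFFECT_MISSENSE)
    mut_aa = AA64[MUTANT64[ci[missense_idx], pos[missense_idx], alts[missense_idx]]]
    for j, aa in zip(missense_idx, mut_aa):
        gene_id = site_index.gene_ids[site_index.gene_of_site[sites[j]]]
        protein_pos = int(site_index.codon_ordinal_of_site[sites[j]]) + 1
        verdict = sift_table.is_damaging(gene_id, protein_pos, aa)
        mask[j] = bool(verdict)
    return mask


def simulate_somatic_cohort(
    models: Sequence[GeneModel],
    sift_table: FunctionalityTable | None,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SubstitutionRecord]:
    """Tumor cohort of raw substitution records (MAF-style, unclassified).

    Selection uses the SIFT-like table's damaging calls; with no table all
    missense mutations are retained at ``nonsyn_retention``.
    """
    rng = _rng(config, rng)
    if not models or config.n_patients == 0:
        return []
    site_index = _build_site_index(models)
    lam = config.mutation_rate * site_index.n_sites / 1e6
    per_patient = rng.poisson(lam, size=config.n_patients)
    total = int(per_patient.sum())
    patient_of = np.repeat(np.arange(config.n_patients), per_patient)
    sites = rng.integers(0, site_index.n_sites, size=total)
    alts = (site_index.ref_base_of_site[sites] + rng.integers(1, 4, size=total)) % 4
    effect = EFFECT64[
        site_index.codon_index_of_site[sites],
        site_index.pos_in_codon_of_site[sites],
        alts,
    ]
    mf = _mf_mask(site_index, sites, alts, sift_table)
    keep_p = _retention_probs(
        effect, mf, config.nonsyn_retention, config.mf_boost, config.nonsense_rate
    )
    kept = rng.random(total) < keep_p
    dup_draw = rng.random(total) < config.duplicate_rate

    records: list[SubstitutionRecord] = []
    for j in np.flatnonzero(kept):
        s = sites[j]
        rec = SubstitutionRecord(
            patient_id=f"p{patient_of[j] + 1:04d}",
            gene_id=site_index.gene_ids[site_index.gene_of_site[s]],
            transcript_id=site_index.transcript_ids[site_index.gene_of_site[s]],
            cds_pos=int(site_index.cds_pos_of_site[s]),
            ref=BASES[site_index.ref_base_of_site[s]],
            alt=BASES[alts[j]],
        )
        records.append(rec)
        if dup_draw[j]:
            records.append(rec)

    if config.frameshift_rate > 0:
        n_fs = rng.poisson(config.frameshift_rate, size=config.n_patients)
        for pi, k in enumerate(n_fs):
            for _ in range(int(k)):
                s = int(rng.integers(0, site_index.n_sites))
                ref = BASES[site_index.ref_base_of_site[s]]
                records.append(
                    SubstitutionRecord(
                        patient_id=f"p{pi + 1:04d}",
                        gene_id=site_index.gene_ids[site_index.gene_of_site[s]],
                        transcript_id=site_index.transcript_ids[
                            site_index.gene_of_site[s]
                        ],
                        cds_pos=int(site_index.cds_pos_of_site[s]),
                        ref=ref,
                        alt=ref,  # placeholder; frameshifts carry no base change
                        variant_class="frameshift_indel",
                        frameshift_flag=True,
                    )
                )
    records.sort(key=lambda r: (r.patient_id, r.gene_id, r.cds_pos, r.alt))
    return records


def simulate_germline_panel(
    models: Sequence[GeneModel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SubstitutionRecord]:
    """Germline segregating sites under a strong purifying regime.

    Allele frequencies are drawn from Beta(alpha, beta); missense candidates
    are retained at ``germline_nonsyn_retention`` and stop gains at half
    that, so paired runs show germline dN/dS well below the somatic value.
    """
    rng = _rng(config, rng)
    if not models or config.n_germline_sites == 0:
        return []
    site_index = _build_site_index(models)
    n = config.n_germline_sites
    sites = rng.integers(0, site_index.n_sites, size=n)
    alts = (site_index.ref_base_of_site[sites] + rng.integers(1, 4, size=n)) % 4
    effect = EFFECT64[
        site_index.codon_index_of_site[sites],
        site_index.pos_in_codon_of_site[sites],
        alts,
    ]
    keep_p = _retention_probs(
        effect,
        np.zeros(n, dtype=bool),
        config.germline_nonsyn_retention,
        1.0,
        config.germline_nonsyn_retention / 2,
    )
    kept = rng.random(n) < keep_p
    alpha, beta = config.germline_af_alpha_beta
    freqs = rng.beta(alpha, beta, size=n)
    records = []
    seen: set[tuple] = set()
    for j in np.flatnonzero(kept):
        s = sites[j]
        gene_id = site_index.gene_ids[site_index.gene_of_site[s]]
        key = (gene_id, int(site_index.cds_pos_of_site[s]), BASES[alts[j]])
        if key in seen:  # one record per segregating site/allele
            continue
        seen.add(key)
        records.append(
            SubstitutionRecord(
                patient_id="",
                gene_id=gene_id,
                transcript_id=site_index.transcript_ids[site_index.gene_of_site[s]],
                cds_pos=int(site_index.cds_pos_of_site[s]),
                ref=BASES[site_index.ref_base_of_site[s]],
                alt=BASES[alts[j]],
                allele_freq=float(freqs[j]),
            )
        )
    records.sort(key=lambda r: (r.gene_id, r.cds_pos, r.alt))
    return records


def generate_expression_matrix(
    models: Sequence[GeneModel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """RPKM-style matrix: global genes clear the threshold in every tissue;
    the rest draw a breadth in 0..13 with the focal tissue included at
    probability 1/2."""
    rng = _rng(config, rng)
    tissues = config.tissues
    focal_idx = tissues.index(config.focal_tissue)
    n_t = len(tissues)
    rows = []
    for model in models:
        values = rng.uniform(0.0, 0.999, size=n_t)  # below-threshold baseline
        if rng.random() < config.global_fraction:
            values = rng.uniform(1.0, 100.0, size=n_t)
        else:
            breadth = int(rng.integers(0, n_t - 2))  # strict-mode margin
            chosen: list[int] = []
            if breadth > 0:
                if rng.random() < 0.5:
                    chosen.append(focal_idx)
                others = [i for i in range(n_t) if i != focal_idx]
                extra = rng.choice(
                    others, size=breadth - len(chosen), replace=False
                )
                chosen.extend(int(i) for i in extra)
            values[chosen] = rng.uniform(1.0, 100.0, size=len(chosen))
        rows.append([model.gene_id] + [round(float(v), 4) for v in values])
    return pd.DataFrame(rows, columns=["gene_id"] + tissues).set_index("gene_id")


# ---------------------------------------------------------------------------
# writers / orchestration
# ---------------------------------------------------------------------------

def write_germline_vcf(
    records: Sequence[SubstitutionRecord],
    models: Sequence[GeneModel],
    path: str | Path,
) -> None:
    """Minimal VCF 4.2 in CDS coordinates (one contig per gene)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">',
        '##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Transcript id">',
        '##INFO=<ID=CDS_POS,Number=1,Type=Integer,Description="1-based CDS position">',
    ]
    lines += [
        f"##contig=<ID={m.gene_id},length={len(m.cds)}>" for m in models
    ]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rec in records:
        info = (
            f"AF={rec.allele_freq:.6f};GENE={rec.gene_id};"
            f"TRANSCRIPT={rec.transcript_id};CDS_POS={rec.cds_pos}"
        )
        lines.append(
            f"{rec.gene_id}\t{rec.cds_pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.reset_index().to_csv(path, sep="\t", index=False)


def write_gene_lists(models: Sequence[GeneModel], outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, flag in (("census", "is_census"), ("essential", "is_essential")):
        genes = sorted(m.gene_id for m in models if getattr(m, flag))
        p = outdir / f"{name}.txt"
        p.write_text("\n".join(genes) + ("\n" if genes else ""))
        paths[name] = p
    return paths


def generate_all(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full input bundle into a directory; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    models = generate_gene_models(config, rng)
    sift, pph = generate_functionality_tables(models, config, rng)
    somatic = simulate_somatic_cohort(models, sift, config, rng)
    germline = simulate_germline_panel(models, config, rng)
    expression = generate_expression_matrix(models, config, rng)

    paths = {
        "fasta": outdir / "cds.fasta",
        "sift": outdir / "sift.tsv",
        "pph": outdir / "polyphen.tsv",
        "maf": outdir / "somatic.maf.tsv",
        "vcf": outdir / "germline.vcf",
        "expression": outdir / "expression.tsv",
        "config": outdir / "config.yaml",
    }
    write_cds_fasta(models, paths["fasta"])
    write_functionality_table(sift, paths["sift"])
    write_functionality_table(pph, paths["pph"])
    write_maf(somatic, paths["maf"])
    write_germline_vcf(germline, models, paths["vcf"])
    write_expression_tsv(expression, paths["expression"])
    paths.update(write_gene_lists(models, outdir))
    config.to_yaml(paths["config"])
    return paths
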