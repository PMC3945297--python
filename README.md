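# somasel

Selection statistics for somatic tumor cohorts: codon-level counting of
non-synonymous/synonymous (N/S) and more/less-functional (MF/LF) sites,
classification and filtering of somatic and germline substitutions, dN/dS
and dMF/dLF ratio statistics with chi-square tests, site-composition-corrected
comparisons between gene groups (globally vs non-globally expressed), a
per-gene positive-selection screen, and enrichment analyses — plus a
synthetic-data generator that emulates tumor cohorts and germline panels so
the whole pipeline is testable offline.

## Method summary

- **Site counting** enumerates the three alternate bases at every coding
  position (unweighted NG86-style counting): each possible single-base change
  contributes 1/3 of a site to its effect class. Stop-gain changes count as
  non-synonymous sites but are outside the MF/LF domain (functionality
  predictors score amino-acid substitutions only). A SIFT-like score of
  <= 0.05 is damaging (MF); a PolyPhen-like class of possibly/probably
  damaging is MF, benign is LF.
- **Variant processing** keeps one (longest-CDS) transcript per gene,
  classifies substitutions by translating the mutated codon, deduplicates
  identical changes within a tumor (cross-patient recurrences all count),
  removes every substitution of a (patient, gene) pair that carries a
  nonsense or frameshift event, and filters germline variants to allele
  frequency strictly above 0.1.
- **Statistics**: dN/dS = (n/N)/(s/S) and dMF/dLF = (mf/MF)/(lf/LF);
  departure from 1 is tested with a 1-df chi-square of the observed count
  split against the site split. Two gene groups are compared with a 2x2
  chi-square after dividing one group's numerator count by
  cf = (N_a/S_a)/(N_b/S_b), which removes site-composition confounding.
  Because observed non-synonymous counts cover missense changes only (stop
  gains are diverted to the truncation filter), dN/dS uses missense-only
  site totals by default (`stop_gain_in_sites=True` restores the full
  non-synonymous total).
- **Simulation** places mutations uniformly over coding sites and applies
  selection as acceptance sampling: synonymous changes are always retained,
  LF missense with probability `nonsyn_retention`, MF missense with
  probability `min(1, nonsyn_retention * mf_boost)`, stop gains at
  `nonsense_rate`. Neutral settings recover dN/dS = dMF/dLF = 1; the
  retention probability is recovered as the pooled dN/dS.

## CLI

```sh
# generate a synthetic input bundle (FASTA, MAF-style TSV, VCF,
# functionality tables, expression matrix, gene lists)
somasel simulate --seed 1 --outdir runs/inputs

# full analysis on existing inputs
somasel stats --fasta runs/inputs/cds.fasta --maf runs/inputs/somatic.maf.tsv \
  --expression runs/inputs/expression.tsv --sift runs/inputs/sift.tsv \
  --pph runs/inputs/polyphen.tsv --vcf runs/inputs/germline.vcf \
  --census runs/inputs/census.txt --outdir runs/out

# or both in one shot
somasel all --seed 1 --outdir runs/full

# render the report tables
somasel report --report-json runs/full/report.json
```

Other subcommands: `sites` (per-gene site counts), `classify`
(classification + dedup + truncation filter), `partition` (expression
breadth groups), `screen` (per-gene dN/dS screen). Logs go to stderr, data
to files; `report.json` archives the counts and site totals behind every
reported ratio.

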