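# gh1kit

Identification of linker-histone (H1) proteins among GH1-domain-containing
proteins, plus per-locus population-genetic diversity and selection
statistics — with seeded synthetic-data generators so the whole pipeline is
exercisable offline.

## What it does

**Protein side.** Given a protein FASTA and domain annotations (plain TSV or
HMMER `--domtblout`), gh1kit partitions each protein into NTD / GH1 / CTD,
detects AT-hook motifs, computes a physicochemical panel (MW, theoretical pI
via Bjellqvist pKa bisection, per-region lysine content and integer net
charge, 20-aa moving-sum charge profiles anchored at the GH1 boundary), maps
the 10 putative basic DNA-binding sites through a GH1 alignment, and combines
everything into a verdict: `H1`, `GH1_Myb`, `GH1_HMGA`, or `other`. It also
builds neighbor-joining trees from p-distances and assigns H1 variant names
(H1.0–H1.4) by mean distance to labeled references.

**Population side.** Given per-locus haplotype alignments (gapped FASTA),
coding coordinates and/or a VCF subset, it computes segregating sites, π
(total and by Nei–Gojobori site class: silent/synonymous/nonsynonymous),
Watterson's θ, Tajima's D, SNP/indel densities, and the maximum-likelihood
HKA test (Poisson model, profiled per-locus θ, χ²(1) likelihood-ratio test of
a focal-locus selection factor k).

**Synthetic data.** `gh1kit.synthetic_data` generates proteomes with planted
H1/GH1-Myb/GH1-HMGA/decoy proteins, neutral infinite-sites Kingman
coalescent samples with known θ, Poisson HKA counts with known (θ, T, k),
and coding-region populations with planted synonymous/nonsynonymous SNPs and
flank indels. All generators are pure functions of their parameters and seed.

## CLI

The console script `gh1kit` exposes:

```sh
gh1kit simulate --kind proteome --seed 7 --out data/        # synthetic inputs
gh1kit classify --proteins data/proteome.fasta --domains data/domains.tsv \
    --alignment data/gh1_alignment.fasta --reference-id __template__ --out report.tsv
gh1kit profile  --proteins ... --domains ...                # physicochemical panel
gh1kit sites    --alignment ... --reference-id ...          # binding-site conservation
gh1kit nj       --alignment ...                             # NJ tree (newick)
gh1kit assign-variant --alignment ... --labels labels.tsv   # H1.0–H1.4 nomenclature
gh1kit popgen   --alignments locus.fasta [--coding coding.tsv] [--variants x.vcf]
gh1kit hka      --counts hka_counts.tsv [--focal L0] --out hka.tsv
```

Thresholds can be set with flags or a `key = value` config file
(`--config`); flags win over the file, which wins over defaults
(CTD lysine ≥ 20 %, CTD net charge ≥ +20, minimum 20-aa window sum ≥ +1,
≥ 8/10 conserved binding sites).

## Layout

```
src/gh1kit/
  seqio.py           FASTA / domain-table / VCF-subset / newick I/O, data model
  architecture.py    NTD–GH1–CTD partition, AT-hooks, architecture groups
  physchem.py        MW, pI, lysine %, net charge, moving-sum charge profile
  binding_sites.py   reference site map + conservation scoring
  h1_classify.py     H1 verdict, p-distances, neighbor joining, variant naming
  popgen.py          S, π by site class, θw, Tajima's D, densities, ML-HKA
  synthetic_data.py  seeded generators for every stage
  cli.py             click-based command surface
tests/               pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py
```
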