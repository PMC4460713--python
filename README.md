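# ptmsnp

Detection and disease-association analysis of non-synonymous SNPs (nsSNPs)
that hit post-translational modification (PTM) sites.

## The problem

A missense or stop-gain SNP that lands on a phosphorylation, ubiquitination
or glycosylation site — or within its recognition motif — can abolish or
create a modification and thereby rewire signalling. Mapping nsSNPs onto PTM
sites sounds like a coordinate lookup, but the SNP annotations (RefSeq
protein space) and the PTM annotations (UniProt protein space) live on
databases whose sequences are *not* identical, so naive position matching
fails. `ptmsnp` implements the peptide-window alignment approach used to
build PTM-SNP catalogs, plus the downstream disease-association statistics,
for anyone who wants to run the analysis on their own SNP/PTM/GWAS tables or
study its behaviour on synthetic data with known ground truth.

## Method

**Windows.** For an nsSNP at protein position *i*, the *SNP sequence* is the
peptide window covering residues *i−7 … i+7* (positions beyond a terminus
padded with `-`). The *PTM site sequence* is the analogous ±7 window around
a PTM site.

**Sliding match.** The SNP window is slid across the PTM window one residue
at a time. For each offset *k* ∈ [−7, +7] the number of exactly identical
residues in the overlap is counted; candidates need overlap ≥ 8 and at most
1 mismatch (tolerating a single cross-database sequence discrepancy). The
unique best candidate (most identities; ties broken toward smaller |k|)
fixes the SNP's signed offset from the PTM site. When two offsets tie on
identities — the signature of a sequence repeat — the pair is re-resolved by
an affine-gap global alignment of the full protein sequences (BLOSUM62, gap
open 10.0, gap extend 0.5, free end gaps). Hits are classified *on-site*
(offset 0), *flanking* (offset ≠ 0), or *stop-gain affected* (any offset;
the variant truncates the protein), and de-duplicated per
(rsID, PTM protein, PTM position, PTM type).

**Disease association.** Hits are joined with disease-SNP catalogs by rsID,
summarized per trait, and each SNP class is tested for enrichment of
disease-associated SNPs with the one-sided Fisher exact test: with *N* SNPs
of which *K* are disease-associated, a class of size *n* containing *k*
associated SNPs has

&nbsp;&nbsp;&nbsp;&nbsp;p = P(X ≥ k),&nbsp;&nbsp; X ~ Hypergeometric(N, K, n),

computed in log space so that tails around 10⁻⁶⁷ survive.

**GWAS stage.** A raw case/control genotype panel can feed the catalog:
samples with missing rate > 3% are dropped, then SNPs with missing rate
> 1%, control-only Hardy–Weinberg exact-test p ≤ 10⁻⁴, or pooled MAF < 1%;
survivors are tested with the 1-df Cochran–Armitage trend test and SNPs with
p < 10⁻⁵ become catalog entries. LD pruning is deliberately absent so PTM-SNP
candidates are preserved.

## Worked example

Library use — the phosphorylation enrichment among PTM-SNPs and two site
coverage ratios, computed from the published count columns:

```python
from ptmsnp import hypergeom_upper_tail
from ptmsnp.detection import site_coverage_from_counts

p = hypergeom_upper_tail(179, 165489, 186, 179325)
print(f"phosphorylation enrichment p = {p:.3f}")

df = site_coverage_from_counts([
    ("Disulfide bond", 1750, 1230),
    ("Phosphorylation", 355203, 203830),
])
print(df.to_string(index=False))
```

```
phosphorylation enrichment p = 0.022
       ptm_type  n_sites  n_sites_hit  ratio
 Disulfide bond     1750         1230  0.703
Phosphorylation   355203       203830  0.574
          Total   356953       205060  0.574
```

179 of the 165,489 phosphorylation-type PTM-SNPs are disease-associated;
against 186 of 179,325 overall that is a significant excess (p ≈ 0.02),
while 70.3% of disulfide-bond sites and 57.4% of phosphorylation sites carry
at least one PTM-SNP.

Command line — simulate a small dataset and run the composite pipeline:

```sh
ptmsnp simulate --seed 1 --n-proteins 60 --n-snps 300 --n-ptm-sites 120 --out-dir demo
ptmsnp run --config demo/pipeline.yaml
```

```
detect: 292 rows
associate: 0 rows
enrich: 7 rows
```

292 of the 300 simulated SNPs resolve to a PTM-site hit (the remainder were
planted far from every site); `demo/out/hits.tsv` lists each hit with its
signed offset, category and resolution method, and `enrichment.tsv` holds
the per-PTM-type Fisher tests. At the default rare-disease background rate a
300-SNP simulation usually draws an empty catalog, hence the zero associate
rows; larger simulations (`--n-snps 5000`) populate it.

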