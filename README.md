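# gutherit

Heritability and host-genetic association analysis of gut-microbiome
abundances in a family-structured aquaculture design, with a viability
screen for distinguishing live gut bacteria from dead cells and feed-borne
contaminants.

The pipeline answers three questions about a tank-reared fish population
genotyped on a SNP array and profiled by paired 16S rRNA sequencing (one
library treated with propidium monoazide, PMA, and one untreated):

1. **Which OTUs are alive in the gut?** PMA blocks amplification of free
   DNA and DNA in membrane-compromised cells, so at equal rarefied depth
   the untreated/PMA count ratio separates live OTUs (ratio ≤ 3), dead
   cells (3–6) and contaminants (> 6).
2. **Is OTU abundance heritable?** An animal model with an additive
   genetic effect (covariance proportional to a VanRaden method-1 genomic
   relationship matrix, GRM) and a shared rearing-tank effect is fitted by
   AI-REML; heritability h² = σ²ₐ/(σ²ₐ+σ²ₜ+σ²ₑ) and tank fraction c² are
   reported with delta-method standard errors and a likelihood-ratio test
   for the genetic term. A leave-one-chromosome-out (LOCO) mixed-model
   GWAS scans individual SNPs with Bonferroni genome-wide control.
3. **Do OTU abundances predict performance?** Growth and feed-efficiency
   phenotypes are regressed on log OTU abundances in the same mixed model.

A first-class synthetic-data generator emulates the full study design
(families split across duplicate tanks, Mendelian SNP transmission,
compositional OTU counts with planted heritabilities, dead/contaminant
fold factors, and phenotype effects), so every stage can be validated
against known truths.

## Worked example

Run the whole chain on synthetic data (10 families × 2 tanks × 5 fish =
100 phenotyped animals, 500 SNPs on 4 chromosomes):

```bash
cat > config.yaml <<EOF
n_families: 10
tanks_per_family: 2
fish_per_tank: 5
n_snps: 500
n_chromosomes: 4
rarefaction_depth: 2000
EOF
gutherit all --config config.yaml --seed 42 --outdir run/
```

This simulates paired PMA/untreated OTU tables, screens them, builds the
GRM, and writes `run/h2_table.tsv`, `run/gwas_OTU1.tsv` and
`run/assoc_table.tsv`. With seed 42 all 100 samples pass depth QC, the
screen attributes 3.6 % of untreated reads to dead cells and 7.8 % to the
planted contaminant, and the variance-component table begins:

```
 otu  sigma_a2  sigma_t2  sigma_e2    h2    c2  chi2     p
OTU1     0.364     0.000     0.286 0.560 0.000 5.870 0.015
OTU2     0.028     0.098     0.724 0.033 0.115 0.032 0.857
OTU3     0.076     0.000     1.128 0.063 0.000 0.242 0.623
```

OTU1 is simulated with a planted heritability of 0.30; at n = 100 the
estimate 0.56 is within sampling error, and its genetic term is the only
one with a nominally significant likelihood-ratio test. The same stages
are available individually (`gutherit simulate | screen | qc | grm | h2 |
gwas | assoc`) and as library functions:

```python
from gutherit.io import PipelineConfig
from gutherit.pipeline import run_all

res = run_all(PipelineConfig(n_families=10, n_snps=500, n_chromosomes=4,
                             rarefaction_depth=2000, seed=42))
print(res["h2"][["otu", "h2", "c2", "p"]])
```

Numbers are bit-reproducible for a fixed seed.

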