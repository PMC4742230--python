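# cobel

Screen a personal genome for **conserved binding site eroding loci**:
positions where an individual's derived variants weaken transcription
factor binding sites that have been preserved across mammalian evolution —
and find the gene function or phenotype those erosions congregate next to.

Most disease-relevant variation is non-coding, individually weak, and
invisible to single-locus tests. This screen aggregates instead of testing
loci one at a time: it collects every conserved binding site an
individual's variants erode, then asks which biological process or
phenotype is unexpectedly loaded with erosions. The primary users are
regulatory-genomics and personal-genome researchers who want a
reproducible, fully synthetic-testable implementation of the approach.

## The method

1. **Conserved site prediction.** Each motif (a position frequency matrix
   over {A,C,G,T}) is scanned over both strands of the reference genome
   with the MATCH similarity score

   `score = (Σᵢ I(i)·f(i,bᵢ) − Min) / (Max − Min)`,  `I(i) = Σ_b f(i,b)·ln 4f(i,b)`,

   min–max normalized to [0,1]. A hit is kept when, in a multi-species
   alignment, at least 5 species preserve it (score ≥ cutoff in their
   gap-free orthologous window), the preserving species span ≥ 2
   substitutions/site of neutral branch length, and the site beats a
   CpG-preserving motif-shuffle null within its own alignment block
   (empirical conservation p ≤ 0.05, at most 5,000 sites per motif).
2. **Erosion calling.** Variants are polarized against an outgroup (kept
   only when the reference allele matches the outgroup base, hence is
   likely ancestral). All derived alleles inside a conserved site are
   substituted jointly; sites whose MATCH score drops by ≥ 5% (relative)
   are eroding loci, and overlapping eroded sites merge into one locus.
3. **Enrichment.** Genes get basal-plus-extension regulatory domains
   (5 kb upstream / 1 kb downstream of the TSS, extended to the nearest
   neighboring basal domain or 1 Mb). Per ontology term, a binomial test
   asks whether more loci fall in the term's domain union (genome fraction
   p) than the expected n·p, and a hypergeometric test checks the gene
   counts; both are Benjamini–Hochberg corrected. The top term must pass
   q ≤ 0.05 on both tests with binomial fold ≥ 2.
4. **Significance.** Matched-control permutations replace each locus with
   a random conserved site of identical motif, affinity (2 decimals) and
   conservation-p decade, and count how often controls reproduce the top
   term. A constrained shuffle of medical histories across individuals
   tests whether enrichment–history links exceed chance.

## Worked example

Everything is testable at toy scale with the built-in generator, which
plants perfectly conserved motif instances in the basal domains of genes
annotated to a chosen term and erodes 80% of them:

```python
from cobel import FixtureConfig, generate_fixture, screen

m = generate_fixture(FixtureConfig(seed=1))
result = screen(m.pwms, m.genome, m.alignment, m.tree, m.variants,
                m.outgroup, m.genes, m.chrom_lengths, m.ontology, seed=1)
print(result.summary)
```

prints

```
{'n_conserved_sites': 190, 'n_variants': 101, 'n_variants_ancestral': 101,
 'cobels': {'total': 32, 'het': 15, 'hom': 17,
            'per_tf': {'TF01': 5, 'TF02': 6, 'TF03': 6, 'TF04': 4, 'TF05': 6, 'TF06': 5}},
 'top_term': 'T_TARGET'}
```

190 conserved sites survive the filters (40 planted near target-term
genes plus 150 decoys), the individual's variants erode 32 of them, and
the enrichment recovers the planted term `T_TARGET` as the top hit. The
same run is available from the shell:

```bash
cobel simulate --seed 1 --out-dir fx/
cobel screen --config run.json      # paths + thresholds as JSON
```

The published worked example is equally direct: with 6,321 loci and a
domain union covering 0.45% of the genome, `binomial_region_test(6321, 57,
0.0045)` gives an expected count of 28.4 (prints as 28) and a fold of
2.00 for the 57 observed loci.

## Layout

| module | contents |
| --- | --- |
| `cobel.motif_model` | PWMs, information vectors, MATCH scores, affinity drops, CpG-preserving shuffles, MEME/TSV I/O |
| `cobel.conservation_scan` | genome scanning, species preservation, induced branch length, shuffle-null conservation p, filters, MAF/newick/BED I/O |
| `cobel.cobel_caller` | VCF/pgSnp loading, ancestral polarization, erosion calling and locus merging |
| `cobel.great_enrichment` | regulatory domains, ontology DAG with propagation, binomial/hypergeometric tests, FDR, top-term selection |
| `cobel.null_models` | matched control pools and sets, empirical p-values, cohort occurrence rates and allele frequencies |
| `cobel.history_association` | constrained history shuffles and the association permutation test |
| `cobel.synthetic_data` | the fixture generator (genome, alignment, tree, motifs, genes, ontology, variants, truth) |
| `cobel.pipeline`, `cobel.cli` | end-to-end orchestration and the `cobel` command |
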