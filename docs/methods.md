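# Methods

## Model and procedure

The screen treats a transcription factor's binding preference as a
position frequency matrix (PWM) and a concrete DNA window's affinity as
the MATCH similarity score: each position contributes its base's
frequency weighted by the position's information content
I(i) = Σ_b f(i,b)·ln(4·f(i,b)), and the weighted sum is min–max
normalized so the consensus scores exactly 1 and the per-position worst
sequence exactly 0. The score is a similarity, not a binding energy; its
virtue here is that it makes "a variant lowers affinity by at least 5%"
well defined and strand-symmetric (scoring is invariant under joint
reverse complementation of matrix and window).

A site is called *conserved* when three independent filters agree:

1. **Species support.** At least `min_species` (default 5) non-reference
   species score at or above the scan cutoff in their gap-free
   orthologous window, on the site's strand. Gaps and ambiguity codes
   disqualify a species for that site rather than being imputed.
2. **Branch length.** The preserving species, together with the
   reference, must span at least `min_branch_length` (default 2.0)
   substitutions/site of neutral branch length, measured as the total
   edge length of the subtree induced by those leaves. This guards
   against support coming entirely from a clump of near-identical
   genomes.
3. **Shuffle null.** The observed conservation must beat CpG-preserving
   column shuffles of the same motif, scanned within the *same* alignment
   block: the empirical p is (1 + #{shuffles whose best hit in the block
   attains at least the real site's preserving branch length}) /
   (1 + n_shuffles), and must be ≤ `max_conservation_p` (default 0.05).
   Scanning the same block controls for regional conservation without
   requiring a genome-wide conservation map.

Erosion calling polarizes variants against an outgroup (a variant is
usable only when the outgroup base exists and equals the reference
allele, so the alternate allele is derived), substitutes *all* of an
individual's derived alleles inside the site jointly (one derived
haplotype), and keeps sites whose relative MATCH-score drop reaches
`min_drop` (default 0.05). Overlapping eroded sites merge into one locus
represented by the site with the greatest drop (ties: higher ancestral
score, then leftmost). Heterozygous and homozygous variants count
equally; zygosity is recorded but unused downstream.

Enrichment follows the basal-plus-extension regulatory-domain model:
basal = 5 kb upstream / 1 kb downstream of the TSS (strand-aware),
extended on each side to the nearest flanking basal boundary of another
gene or by at most 1 Mb, clipped at chromosome ends. Per ontology term
(annotations propagated from descendants to ancestors through is_a
edges), a binomial tail tests the number of loci whose midpoint falls in
the union of the term's extended domains against the union's genome
fraction, and a hypergeometric tail tests annotated vs. unannotated genes
carrying loci. Both p-value families are Benjamini–Hochberg corrected
within each ontology namespace; a reportable top term needs q ≤ 0.05 on
both tests and binomial fold ≥ 2, and the winner is the smallest binomial
p (ties: larger fold, then lexicographic term id).

Matched-control significance replaces every locus with a random conserved
site of the same motif, the same affinity after rounding to two decimals,
and a conservation p in the same decade (floor of log10), then counts how
often the control sets reproduce the observed top term (or any member of
a related-term group: an ancestor plus all its descendants). The
empirical p is plain hits/shuffles — the published per-genome values at
10,000 shuffles imply a count/N estimator rather than (c+1)/(N+1) — and
per-genome p-values combine by multiplication. The history test shuffles
medical-history entries across individuals while preserving per-person
entry counts and the global entry multiset, requiring ≥ 80% of
(person, entry) pairings to change, and asks how often every individual's
top term remains linked to at least one of their (shuffled) entries in a
curated association matrix.

## Parameters that matter

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `min_species` | 5 | species | minimum cross-species support for a site |
| `min_branch_length` | 2.0 | subs/site | neutral divergence the support must span |
| `max_conservation_p` | 0.05 | — | shuffle-null significance cutoff |
| `max_sites_per_motif` | 5000 | sites | caps low-specificity motifs; ranked by (p asc, score desc, coordinate) |
| `score_cutoff` | 0.9 | MATCH score | hit threshold for the scan *and* for species preservation (one threshold, one fewer free parameter) |
| `n_shuffles_for_p` | 49 | shuffles | p resolution 0.02 at the 0.05 threshold; see numerical notes |
| `min_drop` | 0.05 | fraction | relative affinity loss defining erosion |
| `basal_up`/`basal_down` | 5000/1000 | bases | constitutive regulatory domain around the TSS |
| `max_extension` | 1,000,000 | bases | distal-regulation reach |
| `max_q`, `min_fold` | 0.05, 2.0 | — | reporting filters for the top term |

Open choices resolved as package defaults (each switchable): the 5%
erosion threshold is a *relative* drop (`drop_mode="absolute"`
available); species preservation uses the scan's score cutoff rather than
base identity; locus→gene attribution uses the region midpoint
(`attribution="overlap"` available); the association test requires all
persons to match (`min_persons` relaxes to k-of-n).

## The synthetic generator

`synthetic_data` emulates every input at toy scale: a single-chromosome
i.i.d. uniform genome (default 600 kb), 60 genes with jittered evenly
spaced TSSs, a 12-term two-level ontology whose target term annotates 8
genes, 6 sharp motifs (consensus base frequency 0.88, length 8, one
consensus CpG), a random bifurcating phylogeny of 8 species with branch
lengths uniform on [0.05, 0.5] (rescaled if needed so the full species
set spans ≥ 2 subs/site), and an aligned cohort produced by independent
Jukes–Cantor substitutions per species at its distance from the
reference. Five consensus instances are planted in each target gene's
basal domain and 150 decoys far from target genes (these populate the
matched-control pools); planted columns are copied unchanged to every
species, so conservation-filter recovery is deterministic rather than
stochastic and the acceptance surface is sharp. The simulated individual
erodes 80% of the planted target sites with one SNV at the site's
maximum-information position (consensus base → least frequent base, a
guaranteed ≥ 5% drop; 1/8 relative for the default motifs), sprinkles
background SNVs at 1e-4/base outside all planted sites, and ships an
outgroup track equal to the reference at every variant position so the
ancestral filter passes by construction.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: realistic base composition and repeats,
indels and alignment error, shared ancestry of substitutions (species
mutate independently), partially conserved sites, motifs with correlated
positions, linkage between variants, and ontologies with thousands of
terms where multiple-testing burden is material. The generator's defaults
are the conditions under which the recovery and null properties are
asserted; one deviation from the configured sketch is that the default
genome is 600 kb (not 500 kb) so the stated genome-size ≥ 10 ·
genes · 1 kb layout constraint holds at 60 genes.

All randomness flows from a single master seed; each component
(tree, motifs, genes/ontology, genome, alignment, individual) derives its
generator from the master seed plus a fixed documented offset, and the
manifest records them.

## Numerical notes

- The conservation p uses the (c+1)/(N+1) estimator, so p ∈ (0, 1] and a
  site preserved by zero species gets p = 1 exactly (a shuffle with no
  hit ties a zero branch length). The matched-control and history
  empirical p-values deliberately use plain c/N instead (see above).
- Shuffles that happen to reproduce a low-complexity consensus (repeated
  letters) place a floor on the attainable conservation p; with 49
  shuffles a minority of genuinely conserved sites of such motifs can
  land just above 0.05 and be dropped. The loss is conservative (it can
  only reduce downstream enrichment) and the planted-term recovery
  property holds despite it.
- PWM rows are normalized, then `pseudocount` (default 1e-3) probability
  mass is added per cell and the row renormalized, keeping ln terms
  finite; pseudocount 0 is allowed. Derived matrices (reverse
  complements, shuffles) carry the already-regularized frequencies so
  involution and column-multiset identities are exact.
- A fully uniform motif has Max = Min raw score; every window is then
  defined to score 1 (every window *is* a consensus). A reference window
  scoring 0 makes the relative drop undefined; such sites are flagged
  unscoreable and skipped.
- Windows containing N or other ambiguity codes are skipped, never
  scored. Sites spanning alignment-block boundaries are dropped; blocks
  are assumed stitched per reference chromosome.
- Ties everywhere break deterministically (argmax/argmin take the
  alphabetically first base; sorts are stable with explicit keys), so
  byte-identical reruns are a contract, not an accident: output files
  embed the tool version, a hash of the scientific configuration
  (excluding the output directory) and the seed, and log lines carry no
  timestamps.
- Empirical-p shuffle seeds derive as master + shuffle index.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
generator's default 600 kb / 8-species / 6-motif fixtures: a complete
screen takes a few seconds, and the recovery and null properties are
asserted over 20 seeds each (the acceptance script reports the same rates
over 8 seeds per condition, plus a 200-shuffle matched-control
calibration). The per-motif site cap and the 10,000-shuffle control
default only bind at real-genome scale.

## Known limitations

- The screen inherits the MATCH score's limitations: no energy model, no
  interdependent positions, dimers handled as pre-concatenated single
  matrices.
- Only SNVs are considered (no indels, no structural variants, no
  phasing); multi-sample VCFs use the first sample.
- Conservation is all-or-nothing per species at one score cutoff;
  per-base conservation scores are out of scope.
- Occurrence-rate and allele-frequency utilities operate on cohorts the
  caller supplies; no population-structure correction is performed.
- The association matrices are curated inputs; the package tests their
  implications but cannot generate them.
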