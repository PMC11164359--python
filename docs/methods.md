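# Methods

`mitocomp` implements the comparative-mitogenomics workflow used for small
AT-rich animal mitogenomes such as those of *Formica* ants: genome feature
accounting, nucleotide composition and strand-asymmetry skews, codon-usage
bias, pairwise Ka/Ks selection signatures, control-region and
intergenic-spacer structure, and distance-based phylogeny. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Coordinates and genome model

Genomes are circular; internal coordinates are 0-based half-open on the
J-strand (the majority strand, as deposited). A feature may wrap the
origin, in which case its `end` exceeds the sequence length and extraction
is modular. GenBank I/O converts to/from 1-based inclusive coordinates at
the boundary only. Gene names are normalized through a shipped synonym
table (COI → cox1, 12S → rrnS, tRNA-Met → trnM, ...); tRNA-Leu/Ser copies
are disambiguated by the anticodon qualifier. Unknown names degrade to a
warning with the raw name retained, so MITOS/GenBank dialect differences do
not abort parsing.

Gene order comparison anchors the circular order at cox1 (a conventional
anchor; the choice only fixes the rotation) and labels the order
`ancestral`, `trnM_translocation` (the Formicidae order, explained by
tandem duplication / random loss of the ancestral trnI-trnQ-trnM block), or
`other` with a report of missing genes.

Stop-codon classes follow the standard incomplete-stop convention: CDS
length ≡ 1 (mod 3) ⇒ `incomplete_T`, ≡ 2 ⇒ `incomplete_TA`; internal stops
are flagged per gene but never abort a survey.

## Composition and skews

AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C), both computed on the
J-strand. N and other ambiguity codes are excluded from numerators and
denominators alike; a skew whose base pair is absent is reported missing
rather than zero. Regional rows (PCGs, tRNAs, rRNAs, CR, concatenated
spacers) concatenate J-strand-oriented sequences as deposited, so regional
counts sum exactly to the whole-genome counts. Rounding happens only in
the reporting layer; internal values keep full precision.

Control-region boundaries are taken from the annotation when present;
a config switch (`cr_from_annotation: false`) instead uses the rrnS-trnM
gap, for records whose CR is not annotated explicitly.

## Codon usage

All codon statistics live in the 62-sense-codon universe of the
invertebrate mitochondrial code (stops TAA/TAG excluded); codons containing
ambiguity characters and trailing partial codons are dropped at counting.

* **RSCU**: k·n_c / Σ_family n, reported missing (not zero) for families
  with no observations.
* **ENC** generalizes Wright's estimator to the active genetic code: the
  degeneracy classes are derived from the code table rather than hardcoded
  to the standard-code 2/3/4/6 split, because the invertebrate
  mitochondrial code has twelve 2-fold, six 4-fold, one 6-fold (Leu) and
  one 8-fold (Ser) family and no 3-fold class. Per amino acid with n ≥ 2,
  F̂ = (nΣp² − 1)/(n − 1); F̂ ≤ 0 is treated as undefined (1/F̂ would
  diverge). A class with no defined F̂ is imputed as F̄ = 1/k with a
  warning. ENC = Σ_k m_k/F̄_k, clamped to [20, 62].
* **CBI** = (N_pref − N_rand)/(N_tot − N_rand) over amino acids with ≥ 2
  synonyms; the preferred set defaults to the dataset-modal codon per
  family (ties alphabetical) and can be fixed a priori, since tools differ
  in their preferred-codon convention.
* The **ENC-plot null curve** uses the conventional form
  ENC = 2 + s + 29/(s² + (1−s)²) regardless of code, as is standard for
  ENC-plot diagnostics. Points below the curve indicate codon usage more
  biased than composition alone explains.
* The **neutrality plot** (GC12 vs GC3) uses ordinary Pearson correlation
  (scipy); slope ≈ 1 indicates mutation-pressure dominance, ≈ 0 selection.

ENC for a genome is computed on the concatenated PCGs by default; a
per-gene-mean mode exists because published per-species values do not state
which convention their tool used.

## Ka/Ks

Nei–Gojobori (1986) pathway counting. Synonymous site counts per codon are
the per-position fraction of non-stop single-nucleotide neighbors that
preserve the amino acid (s + n = 3 exactly). Differences between two
codons are averaged over all minimal mutational pathways that avoid stop
codons; when no stop-free pathway exists (rare), all differences are
counted nonsynonymous and the case logged. Sites are averaged over the two
sequences; gapped/ambiguous/stop columns are removed pairwise (per-pair
deletion, the common default in distance software; a listwise mode is not
provided because the pipeline never needs it).

Two corrections: `ng86_jc` applies Jukes–Cantor to pS and pN; `kumar_k2p`
accumulates transition and transversion difference fractions separately
within the synonymous and nonsynonymous site classes and corrects each
class with the Kimura two-parameter formula. The two agree closely at the
low divergences typical within a genus; both are reported because
published "Kumar method" values are not reproducible to more than ~0.02
without the original tool.

Gene summaries average over all unordered sequence pairs. The bootstrap
(default 1,000 replicates) resamples codon columns, not nucleotides,
preserving codon structure; the SE is the standard deviation of the
replicate means.

Validation is by parameter recovery: sequences evolved at a known ω are
re-estimated within 10% at 10⁴ codons under the estimator's own
assumptions (κ = 1), and within [0.25, 0.35] for ω = 0.3 at κ = 2 on a
12-taxon tree — the NG86 family is known to be slightly conservative when
transitions are favoured, which is why the κ = 2 band is wider.

## Phylogeny

K2P distance d = −½ln(1 − 2P − Q) − ¼ln(1 − 2Q) with pairwise deletion of
gapped/ambiguous sites; a non-positive log argument raises a saturation
error rather than returning a number. Neighbor joining uses the
Studier–Keppler criterion Q(i,j) = (r − 2)d(i,j) − R_i − R_j with
deterministic lexicographic tie-breaking, so identical inputs always give
identical trees. Negative branch-length estimates are clamped to zero with
the deficit moved to the sister branch (logged). The final three clusters
are resolved as a trifurcating root, i.e. the tree is unrooted. Bootstrap
support is the percentage of column-resampled replicate trees containing
each internal bipartition of the full-data tree; replicates that saturate
are dropped and counted. NJ is exact on additive matrices, which is the
basis of the correctness tests.

Newick output is written directly (6-decimal branch lengths, integer-style
supports); parsing goes through dendropy.

## Noncoding detectors

* **Tandem repeats**: candidates are seeded wherever two exact consecutive
  copies of a unit occur, then extended while the running identity
  (fraction of positions matching the position one period earlier) stays
  above the threshold (default 0.85). Overlapping candidates are resolved
  by longer span, then higher identity, then smaller period — the
  smaller-period rule makes a pure k-periodic string report period k
  rather than a multiple. Defaults (min period 5, min 2.0 copies) follow
  common repeat-finder practice; published repeat-unit counts from web
  tools depend on score thresholds that are not recoverable, so
  cross-package comparisons should allow ±1 array.
* **Runs**: maximal homopolymer runs, default ≥ 6.
* **Motifs**: overlapping occurrences (TATATA contains TATA twice).
* **Consensus**: per column the minimal IUPAC code covering every base
  above `min_freq` (default 0: any observed base enters the code, which is
  how degenerate motifs like TAAATTAYA arise); gap-containing columns are
  excluded from the consensus string.
* **Hairpins**: exact Watson–Crick inverted repeats only (no GU wobble, no
  thermodynamics — this detects presence/absence of stems, not folding
  energies), selected greedily longest-stem-first without position reuse.

## Synthetic data

The generator emits the study conditions the analysis assumes: a 16.6 kb
circular genome (gene sizes realistic for an ant mitogenome; 13 PCGs
totalling 11,160 nt), A+T fraction 0.835, AT skew −0.02, GC skew −0.31 on
the J-strand, the Formica gene order with its 9-PCG/14-tRNA J-strand
split, ATN starts, TAA stops, no internal stops, and a 1 kb control region
containing a tandem-repeat array (default 24 nt × 4 copies), poly-A/poly-T
runs (8 nt) and a TATA cluster. Composition targets are met by a
correction pass that flips bases at non-functional positions (rRNAs,
spacers) in seeded random order until the whole-genome counts match; coding
genes and the CR's structured elements are never touched.

Codon sampling weights are the product of base probabilities (codon usage
as a neutral consequence of composition) times exp(bias) for the most
AT-rich codon of each family. `codon_bias = 0` is therefore pure mutation
pressure — under which ENC straddles the null curve, as it should — and
the default 1.0 adds a moderate selection-like preference that reproduces
the below-the-curve ENC-plot signature and ENC values around 30–34,
comparable to real ant mitogenomes.

The coding simulator is a Gillespie process on codons: the rate of a
single-nucleotide codon change is κ-weighted for transitions and
ω-weighted if nonsynonymous; changes into stops are forbidden. Branch
lengths are expected substitutions per nucleotide site at the root
composition (event rates are normalized by the root mean weight per site).
Event sampling buckets positions by codon identity, so cost per event is
O(62), not O(L).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no gene overlaps (overlapping reading frames
would couple two genes' codon constraints; real *Formica* genomes overlap
atp8/atp6), no indels, no among-site rate heterogeneity, no secondary
structure in tRNA/rRNA genes, and first/second codon positions more
AT-rich than real PCGs (real position-1/2 composition is constrained by
protein identity, which the generator does not model). Recovery tests
demonstrate estimator correctness under the stated model, not robustness
to alignment error or annotation noise.

## Pipeline and determinism

The pipeline writes TSV (UTF-8, "." decimals, `NA` for missing) with a
provenance header carrying the config hash and seed — deliberately no
timestamp, so re-running the same config yields byte-identical files.
Stage failures are isolated per genome and collected in
`run_manifest.json`; exit codes are 0/1/2 for success/partial/fatal. Every
exported number is recomputable by calling the owning module directly; the
pipeline adds no math of its own.

Problem sizes used by the validation suite and the reproduction script
(10⁴ codons for two-taxon recovery, 4,000 codons × 12 taxa for the
multi-taxon case, 100–1,000 bootstrap replicates, ≤ 8-taxon additive
matrices) were chosen as the smallest sizes at which the stochastic
recovery bands are comfortably stable across seeds.
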