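# Methods

This note documents the models and procedures implemented in `hsp20pipe`,
the parameters that matter, the synthetic data the tests run on, and the
numerical and design choices a maintainer would want to know about.

## Profile search and E-values

The family signature (the ~90-residue α-crystallin domain) is modeled as a
profile with match, insert and delete states in the Plan7 mould, kept
deliberately compact:

- **Match states** are alignment columns with < 50% gaps (the standard
  heuristic). Emissions are column counts smoothed with
  background-proportional pseudocounts totalling 2 observations per state;
  the background is the alignment's overall residue usage lightly smoothed
  toward uniform. Scores are log₂-odds against that background, so Viterbi
  scores are in bits.
- **Transitions** are fixed probabilities (match→match 0.9, →insert 0.05,
  →delete 0.05; insert and delete self-loops 0.6) rather than estimated
  from the seed alignment — with a dozen seed sequences there is too little
  signal to estimate 7 transition parameters per state, and the search
  results at desk scale are insensitive to them.
- **Alignment mode** is local: uniform entry into any match state (cost
  log₂ L) and free exit, so a domain is found anywhere inside a protein.
  Scoring is exact Viterbi dynamic programming; a row-vectorized scorer
  (delete chains resolved with a running maximum) is used for search, and
  a pointer-traceback variant recovers envelopes and the match-state
  rendering of each hit.
- **Statistics.** Optimal local-alignment scores on unrelated sequences
  are Gumbel distributed; the null is fitted by maximum likelihood to the
  scores of ≥ 200 (default 500) sequences drawn from the background
  composition at a reference length of 200 residues. The per-sequence
  p-value is the fitted tail probability with a first-order length
  correction (×ℓ/200), and the E-value multiplies by the number of
  sequences searched. Fit error at the 1%–10% tail is a few percent with
  500 null draws; the calibration tests therefore fit with 2000 draws so
  the 3×√expected Poisson band is dominated by counting noise, not fit
  noise.
- **Two-pass strategy.** Pass 1 scans with the seed profile at E < 0.01;
  hits passing E < 1e-20 are re-rendered on the match states (which *is* a
  multiple alignment) and train a species-specific profile for pass 2; the
  result is the union of both passes. The second pass pays off when the
  species family is centered away from the seed consensus — the test suite
  constructs exactly that scenario. If no hit survives the strict cut the
  seed profile is reused with a warning.
- **Confirmation** re-scans candidates with the profile. The original
  workflow confirms domains against three external databases; a re-scan
  with the same profile class is the reproducible stand-in.

The molecular-weight gate is a closed interval, [12, 42] kDa by default,
applied to the MW rounded to 2 decimals (the precision of the reported
tables). Survivors are named `<prefix>-1..n` by chromosome (natural order)
then start coordinate.

## Protein properties

Molecular weight sums average (isotope-weighted) residue masses plus one
water. pI solves net charge = 0 by bisection on [0, 14] to |q| < 1e-4
(≤ 60 iterations; the charge is strictly decreasing so the root is
bracketed). The pKa set is the Bjellqvist/ExPASy convention, including
residue-specific N-terminal values; the table is a swappable dataclass.
Both agree with the common reference implementations to within rounding.

## Duplication and synteny

All-vs-all similarity is Smith–Waterman (BLOSUM62, gap open 11 / extend 1)
through Biopython's pairwise aligner; E-values use Karlin–Altschul
statistics with the standard gapped-BLOSUM62 parameters (λ = 0.267,
K = 0.041) and the summed database length. Hits at E < 1e-10 are kept.

Genes are ranked 1..n per chromosome by start coordinate. Classification:
a similar pair anchored in a collinear block is WGD/segmental; otherwise a
same-chromosome pair with rank difference 1 is tandem; otherwise it is
reported as dispersed. Block membership is checked first, which is the
stated priority rule.

Collinear blocks are greedy best-first monotone chains of anchors in rank
space (both orientations, per-step gap ≤ 25 ranks, ≥ 5 anchors —
MCScanX-like defaults, configurable).

**Anchor selection (design choice).** In a genome-wide gene family every
member resembles every other through the shared domain, and those
dispersed domain-only hits readily chain into phantom "blocks" that then
steal genuine tandem pairs via the priority rule. Genuine block anchors
are recently duplicated gene copies: near-identical over (near) full
length. Intra-genome anchor candidates therefore must pass cscore ≥ 0.70
**and** coverage ≥ 0.90 of the shorter protein **and** identity ≥ 0.90.
The two extra requirements are complementary: a domain-only hit has high
identity but low coverage, while an alignment stretched across unrelated
flanks has coverage but diluted identity. Classification still sees every
hit. Cross-genome synteny uses the plain cscore ≥ 0.70 filter (score
normalized by the best score of either gene), as is conventional.

## Ka/Ks (NG86)

Codon alignments are built by threading the two coding sequences through a
global protein alignment (trailing stops stripped; each protein gap
becomes a whole-codon gap; translations are verified against the rows).
The estimator is Nei–Gojobori (1986): per-codon synonymous site fractions
over the non-stop single-base changes (S + N = 3 per codon), averaged over
the two sequences; differences counted by averaging over all substitution
orderings of multi-hit codons, discarding orderings that pass through a
stop (all orderings are used if every one does); Jukes–Cantor correction
d = −¾ ln(1 − 4p/3) of both proportions. p ≥ 0.74 is flagged saturated and
yields an undefined distance (the logarithm degenerates at p = ¾). The
ratio is undefined when Ks = 0; otherwise > 1, = 1, < 1 map to positive,
neutral, purifying selection. The original analysis used a model-averaged
estimator; NG86 is the canonical counting method with the same
sign-of-selection semantics at desk scale, and is validated against
exhaustive pathway enumeration and against simulated evolution at ω = 0.5
and ω = 2 (realized dN/dS tracks ω via acceptance probabilities
min(1, ω) / min(1, 1/ω) for non-synonymous/synonymous proposals).

## Phylogeny

Distances are Poisson-corrected, d = −ln(1 − p), with pairwise deletion
(per pair, only columns where neither sequence is gapped/unknown). A pair
differing at every usable site (p = 1) is an error, not infinity.
Neighbor joining is the classic Q-matrix algorithm with Studier–Keppler
updates; ties break to the first (lowest-index) minimum, and negative
branch lengths are clamped to zero on output. NJ is exact on additive
matrices — verified on random trees via an independent four-point-condition
oracle. Bootstraps resample columns with replacement, rebuild the tree,
and report for each internal bipartition of the full-data tree the
percentage of replicates containing it (1000 replicates by default). The
multiple alignment is an *input*: the pipeline's tree stage reuses the
profile's match-state rendering of each member (a by-product of
identification), which confines the tree to the domain — appropriate
since flanks are unalignable in this family. Subfamily labels are
reference-guided: each unlabeled leaf takes the label of its nearest
labeled leaf by patristic distance.

## Promoters and enrichment

Promoters are the 1.5-kb windows upstream of the gene start: for + strand
genes [start−1500, start−1] read forward, for − strand genes the reverse
complement of [end+1, end+1500], truncated at contig ends with the
realized length recorded. The cis-element catalog is an editable TSV of
named IUPAC motifs in three categories (stress-responsive, hormone-related,
development-related) seeded with the canonical plant-promoter motif names;
scanning is exact IUPAC matching on both strands with every overlapping
occurrence reported (no de-overlapping). Category summaries are percents
of all classified elements.

The two 15-bp HSE modules, nGAAnnTTCnnGAAn and nTTCnnGAAnnTTCn, are exact
degenerate patterns (not PWMs — the modules fix the GAA/TTC triplets, so
pattern matching is faithful). The modules are reverse complements of each
other, so each matching window is reported once: `module` names the motif
spelled by the promoter's forward strand, and `strand` is '+' for the
GAA-first reading, '−' for the TTC-first reading.

The HSE/up-regulation association is a two-tailed Fisher exact test:
hypergeometric point probabilities summed over all tables with the
observed margins whose probability does not exceed the observed table's
(probability-mass criterion, with a 1e-7 relative tie cushion). The odds
ratio is the sample ratio with the Haldane–Anscombe +0.5 correction when a
cell is zero; degenerate margins return p = 1 with a warning. "Up-regulated"
in the pipeline means the expression stage's heat call: z(HTS) > 1 and HTS
is the row's arg-max (threshold configurable).

## Expression

TPM divides count/length rates by their per-sample sum (×10⁶). Replicates
are collapsed to condition means before z-scoring; z-scores use the sample
standard deviation (ddof = 1, configurable); constant genes are flagged
and zeroed. Grouping is agglomerative clustering (average linkage,
Euclidean distance on z rows) cut at k = 3, with clusters renamed I, II,
III by descending size (ties broken by lowest gene index) so Group I is
always the largest — matching the convention that the heat-responsive
group dominates. Distance and linkage are unstated in the source workflow;
average/Euclidean is the default and both are configurable.

## The synthetic genome generator

The generator emulates the statistical structure the pipeline detects; its
defaults are the study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| n_chromosomes / chromosome_length_bp | 3 / 200 kb | genome scaffold |
| n_family_genes | 40 | planted domain-bearing genes |
| n_decoy_genes | 60 | background-composition genes |
| n_tandem_pairs / n_segmental_pairs | 9 / 6 | planted duplicate pairs |
| domain_length_aa / domain_mutation_rate | 90 / 0.1 | per-site substitution from the seed consensus |
| hse_planting_rate | 0.5 | P(promoter receives ≥ 1 HSE) |
| hse_upregulation_odds_ratio | 8 | odds multiplier for the up label |
| upregulation_base_rate | 0.25 | P(up) without an HSE (near the power optimum for the fixed odds ratio) |
| expression_noise_sd | 0.1 | log-scale replicate noise |
| group_proportions | 0.60/0.25/0.15 | expression archetype mix |

Construction details that matter downstream:

- Family proteins are M + random N-terminal flank (25–45 aa) + mutated
  domain + C-terminal flank (8–18 aa), ≈ 125–150 aa ≈ 14–17 kDa — inside
  the MW gate. Decoys draw i.i.d. from the seed alignment's residue
  background (so the search stage's false-positive behavior is calibrated)
  and never contain the domain.
- Tandem pairs are two adjacent genes; the partner's flanks diverge at 4%
  while the domain is copied, and its CDS derives from the ancestor's CDS
  with 5%-per-codon synonymous re-draws — so pairs have realistic,
  unsaturated Ks rather than independent codon usage. Segmental blocks
  copy a run of ≥ 5 consecutive genes (≤ 3 family + decoy anchors) to
  another chromosome; copies keep identical proteins with synonymous-only
  CDS divergence, so anchor detection is unaffected but Ks > 0.
- A decoy gene separates consecutive units so unrelated family genes are
  never rank-adjacent; intergenic gaps (≥ 3.1 kb) guarantee 1.5-kb
  promoter windows never overlap, so planted HSEs cannot collide.
- HSEs are planted as concrete instantiations of the two modules at
  recorded offsets; the up-regulation label is sampled per gene with
  P(up|HSE) derived from the odds ratio. Expression group labels are then
  drawn *conditionally on the up label* (up-labeled genes get the heat-up
  archetype with probability up to 0.9) while preserving the marginal
  group proportions — this couples HSE → up label → Group I → heat call,
  so the pipeline-level enrichment test has signal, and the label-balance
  property still holds.
- Expression: per-gene log-normal abundance, +2 (log scale, ≈ ×7.4) at the
  group's archetype condition (I: HTS, II: LTS, III: RTS), N(0, noise_sd)
  per replicate, each replicate column normalized to 10⁶.
- Everything flows from one `numpy` generator seeded with `seed`, so equal
  parameters give byte-identical artifacts.

**What the generator does not emulate:** introns and splicing, real codon
usage and composition biases, overlapping genes, repeat content, PWM-like
degenerate HSEs, read-level noise, and families whose members diverge in
length or domain count. Passing recovery tests therefore demonstrates the
pipeline's correctness on cleanly structured input, not its robustness to
the full messiness of real genomes.

## Problem sizes used by tests and the acceptance script

The suites run at the generator defaults above (100-gene genomes),
50 random additive matrices up to 12 taxa for NJ, all 2×2 tables with
total ≤ 30 for the Fisher oracle, all two-difference codon pairs for NG86,
100 replicates × 500 codons for the ω-sign experiment, 1000 null decoys for
E-value calibration, 100 cohorts for expression-group agreement, and 200
simulated cohorts for the enrichment power estimate.

## Known limitations

- The enrichment power experiment at the configured cohort size (40 genes,
  ~20/20 HSE split, odds ratio 8, two-tailed α = 0.01) has a theoretical
  power ceiling near 0.7 (normal-approximation bound; the exact Fisher
  test is more conservative still). The package reports the honest
  simulated power (~0.6); no baseline rate attains 0.8 under these
  conditions, which is visible in the power figures the acceptance run
  emits.
- E-values extrapolate a Gumbel fit far into its tail for strong hits;
  they are meaningful for ranking and thresholding near E ∈ [1e-3, 1], and
  order-of-magnitude only at E ≪ 1e-10.
- The NJ tie-break and clamping rules are stated conventions; other
  implementations may differ on degenerate (tied) inputs.
- Cross-genome synteny assumes disjoint gene ids and compares rank
  coordinates per genome; it has no model of local inversions shorter
  than the anchor gap.
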