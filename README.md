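# hsp20pipe

Genome-wide characterization of a small heat-shock protein (HSP20/sHSP)
gene family, as a tested, reusable pipeline. HSP20s are ~12–42 kDa
ATP-independent chaperones defined by the α-crystallin domain (ACD, Pfam
family PF00011); plant genomes typically carry 20–50 of them, expanded by
tandem and whole-genome/segmental duplication and strongly heat-inducible
through heat-shock elements (HSEs) in their promoters. The package
implements every stage of the standard family study and makes each stage
testable against a synthetic genome with a machine-readable truth manifest:

1. **Identification** — a profile model over match/insert/delete states is
   built from a seed domain alignment, scanned over the proteome by Viterbi
   dynamic programming with empirically calibrated Gumbel E-values
   (two-pass strategy: seed profile at *E* < 0.01, species-specific profile
   rebuilt from strict hits at *E* < 1e-20, union of both passes),
   confirmed by re-scan, gated to 12–42 kDa, and named by chromosomal
   position.
2. **Properties** — residue counts (CDS/3 − 1), average-mass molecular
   weights, and Bjellqvist-convention isoelectric points by bisection on
   the Henderson–Hasselbalch net charge.
3. **Duplication & synteny** — all-vs-all Smith–Waterman (BLOSUM62, affine
   gaps, Karlin–Altschul E-values, retained at *E* < 1e-10), gene ranks per
   chromosome, tandem duplicates (rank difference 1), WGD/segmental
   duplicates (anchored in collinear blocks chained in rank space; block
   membership has priority), and cross-genome synteny with the cscore ≥
   0.70 filter.
4. **Molecular evolution** — codon alignments threaded through protein
   alignments and NG86 Ka/Ks (site counting averaged over both sequences,
   pathway-averaged difference counting, Jukes–Cantor correction);
   Ka/Ks > 1, = 1, < 1 read as positive, neutral, purifying selection.
5. **Phylogeny** — Poisson-corrected distances (d = −ln(1 − p), pairwise
   deletion), classic neighbor joining (exact on additive matrices),
   bootstrap supports, Newick I/O, reference-guided subfamily labeling.
6. **Promoters** — 1.5-kb strand-aware upstream windows, an editable IUPAC
   cis-element catalog scanned on both strands, the two 15-bp HSE modules
   nGAAnnTTCnnGAAn / nTTCnnGAAnnTTCn, category summaries, and a two-tailed
   Fisher exact test (hypergeometric enumeration) of the HSE /
   up-regulation association.
7. **Expression** — TPM, per-gene z-scores over condition means,
   average-linkage clustering into three expression groups (Group I the
   largest, heat-responsive), and condition-specific up-regulation calls.

A packaged fixture transcribes the published 41-member family table of
African bermudagrass (*Cynodon transvaalensis*) HSP20s, and the report
stage emits tables in the same column roster.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
genome (seed 1: 100 genes on 3 chromosomes, 40 family members, 9 tandem
and 6 segmental duplicate pairs, HSEs planted at odds ratio 8 with
up-regulation):

```bash
python analysis/01_simulate_genome.py
python analysis/02_identify_family.py
python analysis/03_duplication_kaks.py
python analysis/04_expression_groups.py
python analysis/05_promoter_elements.py
python analysis/06_phylogeny.py
python analysis/07_report.py
```

prints, among other lines:

```
Simulated 100 genes on 3 chromosomes: 40 family members, 9 tandem and 6 segmental duplicate pairs planted.
Identified 40 family members from 40 candidates (MW gate [12.0, 42.0] kDa).
Residues 125-148, MW 14.41-17.25 kDa, pI 4.50-7.95.
788 similarity hits; 2 collinear blocks; 9 tandem and 6 WGD/segmental family pairs.
Ka/Ks over 15 duplicate pairs: {'purifying': 15}
29 HSE hits; HSE vs heat-up association: OR=2.52, two-tailed Fisher p=1.98e-01
```

i.e. identification recall is 1.0 (40/40 planted members, no decoys), the
duplicate classifier reproduces exactly the planted 9 + 6 pairs, and the
recently duplicated pairs show Ka/Ks < 1 (purifying, as expected for
near-identical copies). The HSE line illustrates the power limits of a
40-gene cohort: the association reaches the expression-derived heat call
only attenuated, and this particular seed yields a positive but
non-significant odds ratio (see `docs/methods.md` on enrichment power).
Artifacts (FASTA/GFF3/TSV/Newick/JSON) land in `results/pipeline/`.

The same stages are available as a CLI:

```bash
hsp20pipe --outdir out --seed 1 run-all
hsp20pipe --outdir out identify --mw-min 12 --mw-max 42
```

Exit codes: 0 success, 2 configuration error, 3 data error.

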