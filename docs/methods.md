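# Methods

## Classification model

A gene's paralog count *k* is the number of other genes of the same
species in its ortholog group. Genes with *k* ≤ 3 are called **stable**,
genes with *k* ≥ 4 **labile**; the cut reflects the observation (first
made in *Drosophila*) that genes with at most three duplications sit in
evolutionarily stable clades while larger expansions are lineage-specific
blooms. The per-species scope is the default because cross-species group
members are orthologs, not paralogs; a whole-group scope
(`scope="group"`) is provided for sensitivity analysis. Boundary behaviour
(*k* = 3 stable, *k* = 4 labile) is covered by explicit tests.

## Genomic features

Coordinates are 1-based inclusive (GFF3); every length is end − start + 1.
For multi-transcript genes the representative transcript is the one with
the greatest total exon length, ties broken by the lexicographically
smallest transcript id. Intron length is derived by subtraction,
L_intron = L_gene − L_exon, floored at zero with a warning when a
representative transcript does not span the gene. GC is computed over the
full gene span (introns included), ambiguity codes excluded from numerator
and denominator; whether the original gene-level %GC figures were
span-based or transcript-based is not documented upstream, so full-span is
a stated approximation. Strand is ignored — all features here are
strand-symmetric.

## Protein features

The profiling follows the EMBOSS/Pepstats conventions: average residue
masses plus one water for molecular weight; the formal-charge table
(D, E −1; K, R +1; H +0.5; B, Z −0.5) summed over the sequence; the EMBOSS
pKa set (N-terminus 8.6, C-terminus 3.6, C 8.5, D 3.9, E 4.1, H 6.5,
K 10.8, R 12.5, Y 10.1) for the isoelectric point, solved by bisection of
the monotone Henderson–Hasselbalch net-charge curve on pH [0, 14] (60
halvings, i.e. bracket width ~1e-17; verified against a 0.001-step grid
scan to ±0.01 pH). The nine residue categories overlap by design and are
not normalised against each other; Polar and Non-polar partition the 20
standard residues, so their percentages sum to 100 on B/Z-free input.

Hydrophobicity is the composition-weighted Kyte–Doolittle sum
H = Σ f_aa(%) · h_aa with frequency in **percent**, not fraction: typical
membrane-anchored P450 values are then ~−15 to −20, i.e. 100× the
conventional GRAVY value (the package asserts H/100 = GRAVY exactly).
B/Z/X are excluded from H, pI and (X only) molecular weight, with
warnings; they do count toward composition and category frequencies, whose
set definitions include B and Z.

## Redundancy culling

Identity is 100·matches/alignment-length from a global alignment
(BLOSUM62, gap open 10, gap extension 0.5; gap columns count in the
denominator, switchable to shorter-sequence length). Culling is greedy and
deterministic: the highest-identity pair above threshold loses its shorter
member (equal lengths: the lexicographically larger id) until no retained
pair exceeds the threshold. This reproduces the usual
"remove redundant, keep representative" behaviour, is idempotent, and is
order-independent; the retained set is maximal (every removed sequence
conflicts with a retained one).

## Group statistics

Each feature is compared with a two-sided Mann–Whitney U test: exact null
distribution for tie-free samples with n_x·n_y ≤ 400, otherwise the
normal approximation with midrank tie correction and (by default)
continuity correction. A combined sample with a single distinct value
carries no ordering information and reports p = 1 with a warning.
Significance is judged against α/m with the family size m declared per
table — 6 genomic features, 13 protein properties, 20 residue frequencies
— reproducing the familiar printed thresholds 0.0083, 0.0038 and 0.0025 at
α = 0.05 (displayed to 4 dp; the unrounded value decides). The three
families are corrected separately, matching the analysis the tables mirror,
rather than pooled into one global correction. Note the normal
approximation is only trusted against the exact p to ±0.01 for groups of
about 10 or more; below that the approximation deviates further, which is
inherent to the method, so small samples take the exact route anyway.

## Motif conservation

The five signature patterns are anchored scans, not discovered motifs: the
patterns are fully specified in the P450 literature, so de novo discovery
would add an external tool without new verifiable content. The scanner
reports all (possibly overlapping) occurrences; the anchoring policy keeps
at most one window per motif per protein, the first match starting after
the previous motif's anchored window, enforcing the biological N→C order
helix C < helix I < helix K < PERF < haem. The haem window is 15 columns —
the 11-position pattern span plus 4 trailing profiled-but-unconstrained
columns — so the full printed labile consensus PFSAGPRNCIGQRFA occupies
one window; the PERF window is its 9-position pattern span. Column
information content is log2(20) + Σ p·log2 p (0 to ~4.32 bits); consensus
ties break alphabetically.

## Enrichment summary

The module consumes any gene → term table (curated or predicted — term
*prediction* is deliberately out of scope) and reports per-term per-class
counts with percentages of the class total at 1 dp, round-half-up, plus an
upper-tail hypergeometric over-representation p per term with
Benjamini–Hochberg adjustment across terms. BH is reported because
multiple terms are always tested together, even though proportion tables
are often printed without adjustment.

## Synthetic cohorts

The generator emulates the study conditions: two classes with planted
contrasts, four species, 50 genes per class by default.

* **Gene structure set-points** are the published class medians: labile
  genes 3 exons totalling ~1524 bp with ~311 bp of intron at GC 47.2%;
  stable genes 4 exons totalling ~1518 bp with ~612 bp of intron at GC
  44.78%. One transcript per gene, with a 10% chance of a second, shorter
  isoform to exercise the longest-transcript rule. Genomic background
  sequence is i.i.d. at the class GC target — codon structure is not
  modelled because none of the analysed features depend on reading frame.
* **Protein composition set-points** are the published class median
  residue frequencies (normalised to sum 100): stable proteins richer in
  Cys, Arg, Leu, Trp; labile in Glu, Lys, Met. Proteins are built by
  quota sampling: a per-protein target composition (class set-point with
  residue-wise lognormal noise) is converted to exact residue counts by
  largest-remainder rounding and shuffled. Motif windows are spliced in at
  fixed relative offsets and charged against the quota, so the emitted
  composition matches the target regardless of motif content or haem
  policy.
* **Haem policy**: labile proteins carry the fixed consensus
  PFSAGPRNCIGQRFA; stable proteins carry pattern-sampled variants (pattern
  positions fixed, wildcards drawn from the composition), reproducing the
  total-conservation vs diverse-wildcards contrast.
* **Annotations**: each term annotates a fixed per-class fraction of
  genes (defaults follow the published development/detoxification
  proportions).
* **Ortholog groups** are constructed to recover the truth labels exactly
  under per-species counting, covering both boundary counts: stable genes
  form cross-species groups with 1–4 same-species members, labile genes
  species-specific families of 5–8. A cohort therefore needs ≥ 5 labile
  genes.

### Noise levels (and why they are what they are)

Within-class variances are not published, so they are generator design
choices, user-overridable in `CohortConfig`:

| knob | default | role |
| --- | --- | --- |
| `length_sd` | 40 res | protein length spread (P450s are a single fold of ~510 residues) |
| `composition_cv` | 0.04 | residue-wise lognormal CV of per-protein composition |
| `exon_count_sd` | 0.35 | exon counts concentrate at the class mode (~15% one-off) |
| `exon_length_cv` | 0.2 | per-exon length CV |
| `intron_length_cv` | 0.3 | per-intron length CV |

The composition and exon-count defaults come from an a-priori power
analysis: the planted contrasts are small (e.g. Glu 6.43 vs 6.12%, a 5%
relative difference), and for the pipeline to detect them reliably at 50
genes per class against the Bonferroni-corrected thresholds the
within-class noise must satisfy roughly CV ≤ 0.05 for composition and
exon-count sd ≤ 0.4 (a blanket CV of 0.3 makes several designed contrasts
statistically invisible at this cohort size). Quota sampling matters for
the same reason: i.i.d. residue draws alone would contribute
multinomial noise of ~1.1% sd per residue at length 510, swamping the
planted differences. These levels are also biologically sensible —
homologous single-fold family members have highly conserved global
composition and exon architecture.

### What the generator does not emulate

No phylogeny or birth–death duplication process (labels are planted, not
evolved); no sequence homology within or between classes beyond the shared
motif windows (real CYPs are 20–80% identical, so the culling stage is a
near no-op on synthetic cohorts and is exercised with planted
near-duplicates instead); no correlation between protein length and CDS
length (downstream stages never cross-check them; a strict coupling would
only constrain the generator); no UTRs, no CDS phase. Passing tests on
synthetic cohorts therefore demonstrate the *statistical machinery* —
classification, feature extraction, testing, conservation profiling — not
the biological claims about real CYP complements.

## Problem sizes in the test and acceptance runs

Planted-effect recovery uses 20 cohorts of 50 + 50 genes; type-I control
uses 200 null cohorts (both classes drawn from the stable distributions);
the enumeration oracle for the U statistic covers every tie-free size with
n_x·n_y ≤ 400; the permutation oracle uses 10^5 permutations at 30/30; the
pI grid scan uses 0.001-pH steps over [0, 14] on 100 random peptides.
Pipeline runs inside these loops skip the culling stage (identities in
random cohorts sit far below the 80% threshold, so it cannot change any
decision); culling is tested separately, end-to-end and against its own
oracles.

## Known limitations

Composition-weighted hydrophobicity ignores folding and residue context;
the isoelectric point model treats pKa values as context-free; identity
after global alignment penalises end gaps (a documented convention choice
— tools differ here); the proportion table's round-half-up display can
disagree with historical tables that mixed rounding modes; and the
stable/labile cut at three paralogs is a biological convention inherited
from the *Drosophila* work, not a fitted threshold.
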