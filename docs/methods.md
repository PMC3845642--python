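# Methods

## Scope and model of the data

The package analyses intronless protein-coding gene families of the
RNase A type: ~130-codon ORFs, one exon, recognisable by a CKXXNTF
signature motif, a His/Lys/His catalytic triad and 6–8 cysteines. The
unit of observation is a coding nucleotide sequence named
`<species>-<gene>` (first hyphen separates a 2–3 letter species code
from the gene label; a `ps` suffix declares a pseudogene). A bundled
registry covers the 20 study mammals; unknown codes pass through with a
warning so synthetic or user taxa work.

## Gene/pseudogene classification

A sequence is called functional iff (i) a reading frame exists with no
internal stop codon, (ii) it starts with ATG, and (iii) its codon count
lies within configurable bounds (default 100–160, around the canonical
~130 aa). Anything else is a pseudogene, with each defect located:
`premature_stop@codon`, `missing_start`, `truncated`, and — when a
functional same-lineage reference is supplied — `frameshift@codon` from
a global nucleotide alignment (gap runs of length ≢ 0 mod 3). Without a
reference, the frame with fewest internal stops is used (ties to frame
0); with a reference, the homologous region fixes frame 0. If all three
frames are stop-dominated and no reference is available the call is a
low-confidence `truncated` pseudogene. The ORF length bounds are
deliberately configuration, not biology: the literature gives only an
approximate protein length.

Canonical-feature annotation is alignment-based: the query protein is
aligned to the bundled bovine RNase A mature peptide and the triad is
read off at profile positions 12/41/119, because indels make absolute
coordinates unreliable. `canonical` means motif present AND triad
present AND 6–8 cysteines.

## Alignment

Alignment is protein-guided: global affine-gap pairwise alignment
(BLOSUM62, gap open 10, extend 0.5, first optimal traceback) and a
progressive MSA (average-linkage guide order on pairwise mismatch
fractions, profile–profile Gotoh alignment with mean-of-pairs column
scores). Codon rows are produced by exact back-translation — every
amino-acid column maps to one codon column, protein gaps to `---` — so
reading frames survive by construction. Pseudogenes participate in
stop-masked mode (stops translate to X and are treated as missing data).
The **complete deletion** rule then masks every codon column containing
a gap in any row; a `drop_ambiguous` variant also masks columns with
stop codons or non-ACGT bases, which is required before dN/dS counting.
Complete deletion is idempotent and refuses alignments with no
comparable column.

A practical caveat established during validation: at protein divergences
beyond roughly 25%, optimal affine-gap alignments of indel-free
sequences can score spurious gaps (extension at 0.5 is cheap), which
shuffles codon columns and inflates dS. The recent paralog groups and
within-lineage ortholog sets this pipeline targets are far below that
divergence; estimator-validation tests therefore feed the known
(indel-free) codon correspondence directly where alignment
reconstruction is not the thing under test.

## Distances and dN/dS

* p-distance: differing sites / compared sites.
* Kimura 2-parameter: d = −½·ln[(1−2P−Q)·√(1−2Q)] from transition (P)
  and transversion (Q) proportions; a domain violation raises a
  "saturated" error, and saturated pairs are flagged in distance
  matrices (NJ refuses flagged matrices).
* Modified Nei–Gojobori with Jukes–Cantor correction. Site counting
  weights the three possible changes at each codon position by the
  assumed transition/transversion ratio R (transition R, transversions
  1, normalised per position), so each position contributes one site and
  S + N = 3L exactly; changes that would create a stop codon count as
  nonsynonymous. R defaults to 2.0 and is exposed everywhere: the source
  analysis never states its R, which is why reproduction tolerances on
  dN/dS are ±0.05. With R = 1 the method reduces to the classic
  unweighted computation (verified against an independent implementation
  in the tests). Observed differences per codon pair are averaged over
  all minimal mutational pathways, excluding pathways through stop
  codons and falling back to all pathways when every one is blocked.
  Proportions pS = Sd/S and pN = Nd/N are corrected with
  d = −¾·ln(1 − 4p/3); p ≥ ¾ is reported as saturated, and dN/dS is
  undefined when dS = 0.
* Standard errors: codon-column bootstrap (resampling columns with
  replacement; SE = SD of replicate estimates; replicates where an
  estimator is undefined are dropped and counted). The per-column
  decomposition of site and difference counts makes replicates a vector
  operation. Seeded throughout; identical seeds give identical bytes.

## Trees

Neighbor joining uses the rate-corrected Q criterion with two
reproducibility rules: ties break lexicographically on cluster labels (a
cluster is labelled by its smallest tip), and negative branch lengths are
clamped to zero with the deficit moved to the sister branch of the same
join so path lengths are conserved. NJ is exact on additive matrices
(property-tested to n = 12, and cross-checked against an independent NJ
implementation). Bootstrap supports are percentages of column-resampled
replicate trees containing each internal bipartition; degenerate
replicates are dropped and counted. The default replicate count is
1,000 (the figure-level convention; the methods-level 2,000 is one
config value away). Monophyly queries root explicitly on a caller-given
outgroup — never implicitly.

## Family analyses

Lineage assignment scores each gene's protein against per-lineage
references (global alignment score normalised by the reference
self-score; below 0.3 → "Others"). Ortholog sets take one functional
gene per species, chosen at random among co-orthologs with a recorded
seed; sets of n members yield C(n,2) pairs. Paralog groups are maximal
clades in a rooted lineage tree whose functional tips all belong to one
species (≥2 of them); pseudogene tips may sit inside without breaking a
group. Gene sorting between two species is declared when, inside their
smallest joint clade, neither species' tips are monophyletic.

Selection summaries report, per group: mean pairwise dS and dN with
codon-bootstrap SEs, the mean of pairwise dN/dS ratios — pairs with
dS = 0 are excluded from the ratio mean and reported separately (the
"∞" convention for groups whose only pair has dS = 0) — the count of
pairs with dN/dS > 1, and a one-tail paired t-test of pairwise
dN − dS > 0, applied only to groups of three or more paralogs. The
mean-of-ratios reading is the default because a published group with
mean dN 0.091 and mean dS 0.053 prints a ratio of 2.002, which only the
mean of pairwise ratios reproduces; ratio-of-means is available as a
config alternative. The t-test treats pairwise values as paired
observations; pairs sharing members are not independent, so p-values are
indicative rather than exact — the same caveat applies to the published
table.

Saturation profiles sort ortholog-pair (dS, dN) points by dS, split at
the midpoint of the dS range, and call a plateau when the upper-half
slope of dN on dS falls below a configured fraction (default 0.25) of
the lower-half slope; the onset is the breakpoint minimising the
two-segment least-squares residual. This makes a qualitative visual
claim algorithmic; the thresholds are configuration, not an assertion
about the original procedure.

## Reconciliation and loss counting

The bundled species tree covers the 20 mammals with named internal nodes
(Hominini … Eutheria, Theria, Mammalia) and approximate divergence-time
branch lengths (My) taken from the published timetree — times are
inputs, never estimated. LCA reconciliation maps each rooted gene-tree
node to the LCA of its children's mappings; a node is a duplication iff
it maps to the same species node as one of its children; losses follow
the standard gap-filling rule, with each loss placed on the species
branch of the off-path sibling subtree. Dollo minimum-loss counting
assumes a single origin (default: the MRCA of present species; analyses
of the 13 ancient lineages pass the eutherian root) and places one loss
on every highest branch whose entire descendant species set lacks a
functional gene. Presence means "has ≥1 functional copy" by default;
counting pseudogene-bearing species as present is a flag, because the
published loss counts use the functional-only reading. Adding an absent
species never decreases the Dollo count, and for single-copy families
the Dollo count equals the reconciliation loss count.

## Physicochemistry

Net charge at pH is the Henderson–Hasselbalch sum of ±1/(1+10^±(pH−pKa))
over D, E, C, Y (acidic), H, K, R (basic) and the termini; pI is found
by bisection on [0, 14] to |charge| < 1e−4 (net charge is strictly
decreasing in pH, so the zero is unique; if no sign change exists the
boundary is returned with a warning). The default pKa table combines
ExPASy-style side-chain values with the textbook generic terminal pKa
(α-amino 9.0, α-carboxyl 2.1); on the bundled mature human ECP and EDN
peptides it reproduces the published pI ordering and spot values within
the ±0.3 tolerance that pKa-source uncertainty warrants. pI is computed
on the mature peptide when a signal-cleavage position is configured,
since secreted RNases are processed.

## Synthetic data generator

`simulate_family` runs a birth–death process along each species-tree
branch: every live copy duplicates at λ (default 0.002 /copy/My, with
optional per-branch overrides for lineage-specific bursts), is lost at μ
(0.001), and — if functional — pseudogenizes at ψ (0.001). Exponential
waiting times; at speciation all live copies enter both daughters.
These defaults make a single root gene produce family sizes, burst
frequencies and pseudogene fractions of the same order as the observed
20-mammal census over a 220-My tree.

Sequences evolve under a mutation–acceptance codon model rather than a
full rate-matrix exponential (transparency over elegance; recovery tests
are estimator-level, not likelihood-level): point mutations are proposed
at `subst_rate` per nt per My (default 0.0015, which yields ortholog-
scale dS of ~0.2–0.3 over typical eutherian path lengths) with
transition bias κ (default 2.0); synonymous proposals are accepted at
min(1, 1/ω) and nonsynonymous at min(1, ω), so their rate ratio is ω.
Functional mode rejects stop-creating changes and freezes the
initiation codon and terminal stop. ω is settable globally, per branch,
or for the new copy at each duplication. The root gene back-translates
a signal peptide plus the RNase A mature peptide with random synonymous
codons, so the motif and cysteine features are planted by construction.

Pseudogenized copies evolve neutrally (ω = 1), can still duplicate, and
decay: pseudogenization injects 1 + Poisson(2) lesions (premature stops
and ±1–2 nt frameshifting indels, the last always a frame-0 stop), and
further lesions accrue at 0.06 /My — the order implied by indel rates of
roughly a tenth of the point-substitution rate. Because stops can in
principle mutate back, a dead copy with few lesions and a long quiet
interval can resurrect a clean ORF; under the default rates this is a
≲10⁻³ tail event per pseudogene tip, observed once in ~1,000 simulated
tips during validation, and it is the one way classifier-vs-truth
closure can miss.

What the generator does not model: indels within functional genes (so
functional rows align gap-free by construction), gene conversion and
recombination (reported for rodent eosinophil-associated RNases), rate
variation among sites, and base-composition bias. Passing recovery tests
on simulated data therefore demonstrates correctness of the estimators
and event-mapping under the generating model — not robustness to
alignment error or conversion, which real data can add.

## Problem sizes and determinism

Test and acceptance runs are sized for a single CPU: simulator recovery
uses 60–130-codon root genes, 100 seeded replicate simulations for
duplication recovery, 200–1,000 bootstrap replicates, and NJ property
tests to 12 taxa. Every stochastic step takes an explicit seed
(numpy `default_rng`); reruns with the same configuration are
byte-identical, and the pipeline manifest records the config hash and
seeds.

## Reproduction inputs the package cannot bundle

The per-gene coding sequences underlying the published census, selection
table and platypus-duplicate identity exist only as a journal
supplement, so those reproduction checks read
`data/supplementary_dataset.fasta` if the user provides it and fail with
an explanatory message otherwise. The bundled census table is a
transcription of the published gene-count table; where the extracted
pseudogene subtotals of a few rows conflict with their printed row
totals, cells were kept as extracted and the functional counts — the
part the loss analyses consume — were reconciled with the absence lists
stated in the text.
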