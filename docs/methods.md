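# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Sequence core

**Mapping.** Reads map to the genome by exact, zero-mismatch full-length
match on both strands, resolved through a fixed-word k-mer index (default
word 18 for read mapping — the minimum read length — and word 7 for
homology seeding). Reads containing N never map, consistent with
zero-mismatch semantics. All intervals are 0-based half-open on the
forward strand; GFF3 export converts to 1-based inclusive.

**Folding.** Precursor-scale structures are predicted by a Nussinov-style
maximum-weight nested fold: pair weights GC = 3, AU = 2, GU = 1, minimum
hairpin loop 3 nt, and a stacking bonus of 0.5 per helix-continuing pair
computed with a two-matrix dynamic program (V = best score given (i,j)
paired; W = best score of the interval). The stacking term exists because
pure pair maximization is massively degenerate: structures that scatter the
same number of pairs tie with the genuine contiguous duplex, and which one
the traceback picks then decides duplex geometry at exactly the boundaries
the acceptance filters test. A small bonus on stacked pairs makes the
contiguous stem strictly optimal while keeping the objective exact and
checkable against brute-force enumeration (the test suite verifies
equality with an exhaustive structure enumeration up to 12 nt and with an
independent recursive maximizer up to 20 nt). Residual ties are broken in
the traceback by preferring split decompositions, which leaves terminal
bases unpaired rather than stretching an outermost pair across an
overhang. This is deliberately not a thermodynamic model: the pipeline
only needs hairpin presence and duplex geometry, and an exact integer-ish
objective is testable; a hook for an external thermodynamic folder can be
added behind the same `FoldResult` interface.

**Duplex geometry.** Given a fold and the mature/star intervals, *space*
is the number of nucleotides strictly between the loop-proximal ends of
the two intervals, and *max bulge* is the longest run of positions inside
either interval — between its first and last duplex-paired position — not
paired into the partner interval, so terminal overhangs never count as
bulges. The star arm of a fold is located as the longest consistent
partner run of the mature: nestedness makes partner positions strictly
decrease along the mature, genuine duplexes step by at most a bulge
(jump ≤ 8), and pairs into flanking sequence appear as large jumps and are
discarded. Loop-proximal stray pairs that would leave less than the
minimal 3-nt loop between the arms are trimmed from the run.

## Synthetic data

The generator emulates the statistical structure of a male/female
small-RNA sequencing study at desk scale:

| parameter | default | meaning |
|---|---|---|
| genome_length | 100 kb | random uniform-composition genome |
| n_loci | 30 | planted pre-miRNA hairpins, both strands |
| n_clustered_pairs / cluster_gap_bp | 2 / (73, 920) | clustered loci at exact gaps |
| mature_length_dist | peaked at 22 nt (18–30 support) | modal read length |
| u5_bias | 0.7 | probability the mature starts with U |
| star_fraction / arm_bias | 0.1 / derived | star/mature read ratio; arm split b = 1/(1+sf); an explicit arm_bias overrides |
| five_prime_jitter | {−2:.02, −1:.05, 0:.86, +1:.05, +2:.02} | mature 5'-start offsets |
| star_five_prime_jitter | broader (0.66 modal mass) | star ends are less precisely processed |
| libraries | 3 male + 3 female, 20 k reads | depths per library |
| lfc_magnitude / n_biased_loci | 2.0 / 10 | planted sex bias, ±lfc alternating |
| loop_len / star_overhang / n_mismatches | 8 / 2 / 2 | hairpin geometry |
| decoy_fraction / reference_decoy_fraction | 0.10 / 0.5 | background reads; half drawn from known-ncRNA sets |
| homolog_mutation_rate | 0.02 | per-base substitutions in sister genomes |

Hairpins carry a 2-nt 3' star overhang (the canonical Drosha/Dicer
signature; configurable 0–3) and, by default, two duplex mismatches placed
in the arm interior. The mismatches matter twice over: real precursors
are never perfectly complementary, and with perfect arms every mature read
would also map exactly onto the star arm of the opposite strand, creating
mirror loci that no real dataset produces. Mature sequences are resampled
until the constructed precursor folds into a clean canonical hairpin
(space equal to the loop length, bulges ≤ 3, ≥ 85 % of the mature paired)
— emulating the selection real pre-miRNAs are under; arbitrary random
sequences occasionally prefer alternative structures. Loop, overhang and
bulge fills are chosen from {A, C} against their local context to minimize
spurious pairability.

Per-locus abundances are log-normal (σ = 1) and shared across libraries;
sex bias multiplies the female mean by 2^(lfc/2) and divides the male mean
by the same factor. Library counts are Poisson; arm assignment is
binomial with the planted arm bias; qualities are constant (a substitution
error rate is available but off by default, since zero-mismatch mapping
downstream turns errors into decoys anyway). Decoy lengths are uniform on
16–32 nt so the length filter has work to do.

What the generator does **not** emulate: sequencing-quality profiles and
GC bias, 3' isomiRs and non-templated additions, piRNA/siRNA classes,
multi-chromosome genomes, and realistic repeat landscapes (repetitiveness
is exercised by planting identical loci, not by transposon models).
Passing recovery tests on this generator therefore demonstrates the
pipeline's correctness under its stated assumptions, not performance on
the full messiness of real libraries.

## Preprocessing

Adapter removal cuts at the leftmost full adapter occurrence, otherwise at
the longest terminal suffix matching an adapter prefix of ≥ 4 bases
(configurable); adapterless reads are retained. The length filter is
boundary-inclusive on 18–30 nt. Collapsing is count-conserving and orders
tags by total count, then lexicographically. Known-RNA removal is exact
substring containment against each reference set on either strand, with
precedence known_miRNA > rRNA > tRNA > snRNA > snoRNA when a tag hits
several classes (the precedence is a package decision; upstream practice
is unstated).

## Discovery

Mapped tags with more than 5 genomic hits are flagged repetitive and
excluded (operationalizing "non-repetitive loci were retained"); tags with
≤ 5 hits contribute full counts at each location. Read stacks (tags
sharing a 5' position) with ≥ 4 reads seed candidate windows; stack
seeding rather than proximity-chaining is essential because scattered
background reads would otherwise chain the whole genome into one cluster.
The window extends 70 nt toward the putative star side and 15 nt on the
other side; both orientations are folded and the one whose mature sits in
the longest duplex run is kept. The observed star is the most abundant
stack within ±5 nt of the fold-predicted star 5' end; evidence counts sum
all reads within ±2 nt (the jitter window) of each arm's 5' end, so a
single star read suffices. Acceptance requires ≥ 10 mature reads summed
over all libraries (the count rule is interpreted as summed, not
per-library), ≥ 1 star read, space in [3, 35] and bulge ≤ 5. Rejected
candidates carry machine-readable reasons (`no_hairpin`, `space`, `bulge`,
`no_star`, `low_mature`). Stacks inside an already-evaluated window (e.g.
the star of a called locus) do not re-seed. An optional fold-score cutoff
exists but is off by default.

## Profiles

Arm dominance uses ratio r = 2 (dominant arm must have at least twice the
other arm's reads); r is exposed because upstream work calls dominance
qualitatively. A switch requires both datasets dominant on opposite arms;
any codominant profile gives `indeterminate`, and the call is symmetric.
IsomiR spectra count read 5' starts within ±2 nt of the annotated end;
fidelity is the modal-offset fraction, and the mature-vs-star contrast
uses a two-sided sign test with ties dropped. Cross-dataset comparisons
match loci by caller-supplied identity, keeping this module independent of
the homology machinery.

## Comparative

Homolog search seeds on 7-mer words (word size mirroring low-stringency
BLAST usage), groups hits by diagonal, and extends ungapped across the
query; candidates need ≥ 80 % query coverage and ≥ 85 % identity — a
deliberate replacement for an E-value threshold, which would depend on
database size and scoring choices that are not pinned down, whereas the
real acceptance surface is the downstream hairpin validation. Each
candidate window (±90 nt flanks) is folded; a verdict of `homolog`
requires ≥ 12 pairs in the window (else `no_hairpin`), ≥ 50 % of the
matched segment paired into a single opposite-arm run, and space in
[3, 35] with bulge ≤ 5 (else `geometry_fail`). Conservation classes
(both / one / neither genome) summarize per-miRNA presence. Cluster
detection is single-linkage chaining with a 10 kb default gap (a common
inter-miRNA cluster convention; the threshold is exposed), singletons are
not clusters, and the seed is nucleotides 2–8 (7-mer default, 8-mer
option). The cluster fold-ratio divides the focal genome's gap by the
mean of the others and reports both raw and rounded values.

## Regulation

Target sites require an exact Watson–Crick complement of the seed in the
UTR (G:U disqualifies by construction) and a hybridization energy
ΔG ≤ −20 kcal/mol over the best ungapped duplex core, computed from the
ten Watson–Crick nearest-neighbor stack free energies (Turner 2004 ΔG°37
values) plus a +4.09 helix-initiation penalty; G:U pairs are excluded from
the energy core to keep every constant in the table verifiable. Absolute
energies therefore differ from full thermodynamic hybridization models,
which is why the threshold is configurable. Consensus demands both
criteria — a two-of-two rule standing in for the usual two-of-three
multi-program consensus, since a third alignment-scoring predictor is
deliberately out of scope.

Differential expression pools counts per condition and applies a
two-sided exact binomial test against the size-factor-expected female
proportion. Library depths use median-of-ratios size factors rather than
raw totals: with deep libraries, the compositional shift induced by truly
biased loci otherwise makes null loci significant (the same motivation as
TMM/DESeq normalization). A dispersion-inflated normal variant is
available for overdispersed data. Raw p < 0.05 defines a bias call —
matching upstream practice — with BH-FDR reported alongside; the BH
step-up is implemented directly and property-tested against an independent
reference implementation. Enrichment is a one-sided Fisher exact test per
annotation term on user-supplied gene→term maps. 2^−ΔΔCt is the standard
relative-quantification closed form.

## Pipeline

`run_all` executes simulate → preprocess → discover → profiles → homologs
→ clusters → targets → diffexp → enrich in one process, writing stage
outputs under `NN_<stage>/` with a SHA-256 manifest; identical config and
seed give byte-identical manifests. Config validation collects all errors
(unknown keys, type errors, bound violations, min_len > max_len) rather
than failing on the first, and logs a note when a value departs from the
standard analysis defaults.

## Problem sizes and determinism

The default study is a 100 kb genome with 30 loci and six 20 k-read
libraries; recovery tests for arm usage and fidelity use 50 loci, DE
calibration uses 500 null miRNAs at 100 k depth, the mapper oracle runs 50
genomes up to 100 kb, and the fold oracle enumerates structures up to
20 nt — sizes chosen so the whole suite and the acceptance script each run
in minutes on a laptop while leaving the statistical assertions
well-powered. Every stochastic step flows from explicit seeds
(`numpy.random.default_rng`), and all recovery claims in the test suite
are computed, not asserted from memory.

## Known limitations

- The folder ignores thermodynamics (no dangles, no special loops); it is
  a structure-presence and geometry instrument, not an energy model.
- The energy table covers WC stacks only; G:U-containing duplexes are
  scored by their WC runs.
- Homology has no gapped extension, so indel-rich homologs beyond the
  bulge tolerance are missed by design.
- The exact binomial DE test assumes Poisson-level replicate variation;
  for strongly overdispersed real data use the dispersion-inflated
  variant (or treat the raw p-values as anticonservative).
- Multi-mapping reads (≤ 5 hits) are counted fully at every locus, which
  can double-count tags shared between near-identical loci.
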