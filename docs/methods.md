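# Methods

## Clonotype model

A clonotype is `(TRBV family, TRBJ family, CDR3β amino-acid sequence)`.
Family normalization strips the allele suffix (`*01`), then truncates at
the first hyphen; multi-gene annotations (`TRBV20-1/TRBV20OR9-2`,
`TRAV14/DV4`) use the first listed gene. This matches IMGT family
semantics and deliberately merges rearrangements that single-cell and bulk
platforms report at different gene-level resolution, which is what makes
clones comparable across the spatial, single-cell, and bulk inputs.

CDR3s containing a stop (`*`) or frameshift (`_`) are non-productive and
excluded from clonotypes throughout: phenotyped and cytokine-secreting
cells necessarily carry productive receptors, so non-productive junctions
are noise for every analysis here. Rejection is per-record (counted, not
fatal).

**α-chain rescue.** A β-less cell with at least one α chain is assigned
clone K iff every cell sharing that α and carrying a *sequenced* β maps to
K (and at least one exists). α identity for rescue is the exact
`(V gene, J gene, nucleotide CDR3)` tuple — stricter than β clone identity —
to minimize false rescue through convergent α junctions. Rescued
assignments are flagged and never used as evidence themselves, which makes
the operation idempotent and order-independent. Cells whose α evidence is
split between clones, or absent, stay unassigned.

**Phenotype calls.** Single cells carry metacluster labels A (terminally
differentiated), B, C (progenitor/memory-like), D (dividing), naive, or
unassigned. A clone is "AD" if its A+D cell count strictly exceeds its B+C
count, "BC" for the reverse, "ambiguous" on a tie (excluded from two-group
contrasts but reported), and "unclassified" with no A–D cells. The strict
majority rule is the simplest deterministic reduction of per-clone cell
mixtures to the two-group contrast the spatial tests need.

## Diversity, overlap, specificity

Shannon index uses natural logarithm over clone frequencies. Morisita-Horn
is computed on the union key set with zero-filled counts:
`MH = 2 Σ xᵢyᵢ / ((Σxᵢ²/X² + Σyᵢ²/Y²) · X · Y)`. Both error on empty
repertoires rather than returning a sentinel; the pairwise overlap matrix
marks rows for empty repertoires NaN.

The CEFX (microbial peptide pool) specificity filter keeps clone K iff
`count⁺(K) ≥ 2` and `freq⁺(K) ≥ 5 · freq⁻(K)` between the IFNγ⁺ and IFNγ⁻
sorted repertoires. A zero IFNγ⁻ frequency satisfies the ratio clause —
any finite frequency is ≥ 5 × 0 — so clones absent from the IFNγ⁻ table
need only the count clause. Known-specificity lookup requires exact
equality of all six fields (CDR3α, TRAV, TRAJ, CDR3β, TRBV, TRBJ) at gene
level with alleles stripped; families are *not* collapsed here because the
database records genes.

Clone ranking breaks count ties lexicographically on the key so cumulative
frequency tables are reproducible.

## Spot demultiplexing

Read 1 is `barcode (16 nt) + UMI (12 nt) [+ pad]`; both lengths are
configurable (the defaults are the spatial platform's v1 read-1
structure). Barcode correction: exact whitelist members map to
themselves; otherwise a barcode is assigned to the *unique* whitelist
entry at Hamming distance 1, with `N` mismatching every base; ambiguity or
distance ≥ 2 discards the read. No quality weighting is used. UMIs are
deduplicated by exact string identity on the `(clone, spot, UMI)` triple —
no directional-network collapsing — which is the conservative choice and
keeps counts a pure function of the read multiset (order- and
duplication-invariant). Every read is tallied under exactly one fate
(assigned / no_clone / too_short / barcode_unassigned); reads on
out-of-tissue spots stay in the matrix but are excluded from all
downstream statistics via the grid's in-tissue flag. Read-id matching
strips whitespace comments and `/1`,`/2` mate suffixes, since caller
exports and FASTQ headers disagree on suffix conventions.

Supporting-read exports from an external clone caller are accepted
directly (TSV of read id → clone id; conflicting duplicate ids are dropped
as unsafe evidence). The built-in lite caller exists so the pipeline is
testable end-to-end without an external aligner: ungapped seed-and-extend
(k = 12 seeds, match +1 / mismatch −1, best contiguous run per shared
diagonal), best V and J by score with lexicographic tie-break, CDR3 from
the conserved V cysteine codon through the J FGxG phenylalanine codon
inclusive (the common caller convention, so keys are comparable across
sources). It handles substitutions only — no indels, no D-segment calls,
no consensus — and is not a replacement for a production aligner.
Identical read sequences are annotated once and the result reused, so
PCR-duplicated, error-free libraries cost one alignment per distinct
molecule sequence.

## Spatial statistics

Spot coordinates derive from the hexagonal-offset array indices:
`x = col · pitch/2`, `y = row · pitch·√3/2`, with a configurable
center-to-center pitch (default 100 µm, the platform's spacing), so all
six neighbors of a spot lie one pitch away. The tumor border is implicit:
a spot's distance is the Euclidean distance to the nearest
tumor-parenchyma spot center (0 for tumor spots), computed with a k-d
tree. No polygonal boundary is fit — border-adjacent stroma spots score
one pitch, not zero.

Per-clone tumor fraction = 100 × (UMIs on tumor spots) / (UMIs on
in-tissue spots); clones with zero in-tissue UMIs are undefined (NaN) and
excluded downstream. All region labels other than the configured tumor
set (stroma, inflammation, …) count as non-tumor for fractions and
distances; region-resolved tables keep the full labels.

The KS test runs on UMI-expanded distance samples (each UMI outside the
tumor is one observation); the p-value uses the asymptotic two-sample
distribution, switching to the exact computation when both expanded sizes
are ≤ 25. The Mann-Whitney U on per-clone tumor fractions uses the
two-sided tie-corrected normal approximation (with continuity correction);
U counts pairs with x > y plus half the ties. Both delegate p-value
evaluation to scipy.stats; the U statistic and ECDF definitions are
verified against brute-force pair counting in the tests. The spatial gene
detection filter keeps a gene iff total counts ≥ 10 *and* expressing
spots ≥ 3.

Because the printed summary "tumor fraction of expanded clones vs overall
expression" can be read per-clone or UMI-aggregated, the expanded-clone
table reports per-clone fractions and attaches the overall
gene-expression tumor fraction as a reference attribute, so either
summary is available.

## Synthetic data

The generator emulates the study's inputs with known ground truth:

- **Tissue**: hexagonal grid (default 30 × 30 spots, 100 µm pitch) with a
  contiguous disc of tumor parenchyma (default radius 800 µm, ≈ a quarter
  of the tissue), an inflammation ring, and stroma; all spots in-tissue.
  Whitelist barcodes are rejection-sampled to pairwise Hamming distance
  ≥ 3, so 1-mismatch correction is provably unambiguous.
- **Repertoire**: default 50 clones with Zipf(1) rank-frequency weights
  (a heavy-tailed clone-size spectrum, as real expanded repertoires
  show), random CDR3s anchored `C…F` over a bundled toy reference of 6 V
  and 4 J segments (including two TRBV6 members to exercise family
  collapsing), phenotype A/D vs B/C assigned 50/50.
- **Placement**: each UMI of a clone lands on a tumor spot with
  probability `p_tumor[phenotype]` (defaults 0.8 for A/D, 0.2 for B/C,
  the planted localization effect), uniform within the compartment.
- **Reads**: per UMI, a fixed number of copies (default 3); read 2 is the
  V-segment suffix from a configurable primer start through the planted
  CDR3 into the J segment. Substitution errors are applied per region
  (barcode / UMI / insert) at configurable rates, zero by default. No
  indels are simulated, matching the lite caller's ungapped model.
- **Matched tables**: single-cell contigs with one α chain per clone and
  a configurable fraction of β-less (rescuable) cells; metacluster labels
  drawn from the clone's own group at configurable purity (default 1.0);
  IFNγ⁺/IFNγ⁻ count tables whose designated specific clones satisfy both
  filter clauses by construction while all others violate at least one
  (the construction is verified internally before returning).

Everything is deterministic under the master seed, with per-stage derived
seeds so stages are independently reproducible; FASTQ output is
byte-identical across runs.

What the simulator does **not** emulate: transcriptome background,
chimeric or indel-bearing reads, UMI collisions across molecules of the
same clone at one spot (UMIs are drawn distinct), ambient RNA, doublets,
segment-sequence homology between V genes, or histology. Passing
round-trip tests therefore demonstrate correctness of the bookkeeping and
statistics under the stated error model, not robustness to every artifact
of real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script run the round trip at ~99,000
reads (50 clones, 33,000 molecules, 3 reads each), barcode-correction
checks at 7,000 reads with 1%/base barcode error, oracle comparisons on
1,000 random instances per statistic, test calibration on 1,000 null
replicates (n = 30 per group), and power analysis on 200 replicates of 20
clones per group × 30 UMIs — sizes chosen to make sampling error small
relative to the effects being measured while keeping a full run in tens
of seconds. The planted-coverage check uses clone-wise binomial 99%
intervals and requires ≥ 97% empirical coverage, since with 8,000 planted
clone-fractions about 1% fall outside their interval by construction.

Known limitations: the lite caller's tie-breaking prefers
lexicographically smaller segment names, so references with (near-)
duplicated sequences resolve arbitrarily but deterministically; Hamming-1
barcode correction assumes a well-separated whitelist (real platform
lists have minimum distance ≥ 2, not always ≥ 3 — at distance-2 pairs a
1-error barcode can be ambiguous and is then conservatively discarded);
the Mann-Whitney normal approximation is inaccurate below ~8 observations
per group, where the test is underpowered anyway.
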