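# Methods

## Scope and model

`numtscreen` analyses partial sequences of a protein-coding
mitochondrial barcode gene (the motivating case is the ~1.5 kb mtCOI
gene of the *Bemisia tabaci* species complex, with its two alternative
657 bp barcode regions: the 3′ region used by the whitefly community,
taken here as positions 783–1,439 so that the window ends at position
1,439, and the 5′ Folmer region, taken by default as positions 1–657;
both are configurable). Three connected analyses are implemented: a
four-criterion screen for nuclear mitochondrial pseudogenes (NUMTs) and
erroneous sequences, Jukes–Cantor divergence in fixed regions and
sliding windows, and threshold-based species delimitation with
cross-region concordance checking.

The gene coordinate convention is 1-based inclusive throughout
(GenBank style). The full gene length is always taken from the input
alignment, never hard-coded.

## Pairwise alignment and INDEL calling

Partial haplotypes are mapped onto a full-length reference gene by a
semiglobal affine-gap alignment (Gotoh three-state dynamic programme):
reference overhangs are free, gaps cost `gap_open + L·gap_extend`.
Default scoring is match +2, mismatch −1, gap_open −6, gap_extend −1.
The relatively expensive gap opening deliberately discourages spurious
terminal micro-indels in high-identity mappings, because the INDEL
criterion of the screen must reflect true length variants.

Numerical/determinism choices:

- Traceback ties are broken in a fixed order (match/mismatch over
  deletion over insertion), and afterwards every gap run is shifted to
  its left-most score-equivalent position. Within a homopolymer run a
  single-base indel has no unique placement; the screen reports the
  left-most coordinate and records the homopolymer run length in the
  evidence.
- A gap run abutting the 5′ or 3′ terminus of the partial is treated as
  amplicon overhang, not as an INDEL; only interior gaps count.
- Mapping identity below a configurable floor (default 60% of aligned
  columns) raises an "unalignable" error — the signature of
  wrong-locus or reverse-complemented input. The mapper does not
  auto-orient.
- The implementation is verified in the test suite against two
  independent oracles: an exhaustive plain-recursion alignment score
  for all pairs up to 12 bp, and Biopython's `PairwiseAligner` under
  the equivalent scoring on longer random pairs.

Multigene concatenations extract each annotated gene (minus-strand
features reverse-complemented to 5′→3′), align unequal-length copies
pairwise-progressively (centre-star on the first sample), drop every
column containing a gap so all samples contribute flush-trimmed genes
of one length, and join genes in the requested order with half-open
boundary offsets recorded.

## The pseudogene screen

A haplotype is a potential NUMT/erroneous sequence if it fails any of:

- **(i) interior INDELs** relative to its group's reference gene.
- **(ii) premature stop codons**, translating frame-trimmed sequence
  under the invertebrate mitochondrial genetic code (NCBI table 5;
  TGA = Trp, ATA = Met). Only INDEL-free sequences can be read in
  frame, so criterion ii is gated on i. A stop occupying the gene's
  terminal codon is not premature.
- **(iii) anomalous polymorphism**, any of three tests:
  - *terminal cluster*: a stretch of ≥ `cluster_min_len` bp (default
    9) at either sequence end whose non-synonymous substitution
    density is ≥ `cluster_density` (default 1 per 10 bp) **and** which
    contains at least `cluster_min_subs` substitutions (default 2).
    The minimum-count term is this package's addition: with the
    density rule alone, any single non-synonymous change within 10 bp
    of an end would count as a "cluster", which is not what the term
    means. The window scan is capped at `cluster_max_len` (default
    120 bp, just above the largest reported pseudogene stretch of
    116 bp). Synonymy is evaluated codon-wise by substituting the
    observed base into the reference codon at the mapped position.
  - *outlier*: whole-sequence divergence from the group majority-rule
    consensus ≥ `outlier_pct` (default 4.0%, sitting between normal
    within-group spreads ≤ ~1.4% and observed pseudogene outliers near
    4.8–5.3%). Run only when the group has ≥ 3 haplotypes.
  - *decoy identity*: identity to any sequence of a user-supplied
    local decoy set (other species, chloroplast) exceeding identity to
    the group consensus. This replaces a remote BLAST check with an
    offline, deterministic comparison; an empty decoy set disables the
    test and the evidence notes it.

  None of the criterion-iii cut-offs is prescribed by the source
  analysis, which reported flagged cases but no thresholds; the
  defaults above bracket those cases and are all config-exposed, so
  reproducing a published summary validates the procedure rather than
  the exact numbers.
- **(iv) conserved-site amino-acid changes**: the frame-trimmed
  translation is compared to a panel of reference proteins (≥ 2 rows;
  aligned progressively when of unequal length). A column is conserved
  when all panel rows share one residue and none has a gap; any
  differing residue at a conserved column flags the haplotype.
  Criterion iv is gated on i and ii (only sequences that pass both are
  analysed at the amino-acid level), and translations shorter than 30
  aa return a "too short to assess" status instead of a flag.

Per-group summaries report raw per-criterion counts (a haplotype may
appear in several columns) plus a union that counts each haplotype
once, with `percent = round(100·union/total, 1)`. Unalignable records
are listed separately and excluded from the counts; groups with zero
alignable haplotypes are omitted.

## Divergence

The distance is the Jukes–Cantor corrected divergence over all
compared sites, `d = −(3/4)·ln(1 − (4/3)·p)`, undefined for
`p ≥ 0.75`. Sites are compared under pairwise deletion: per pair,
columns where either residue is a gap or an IUPAC ambiguity code are
excluded (ambiguity codes are retained on ingest and handled only
here). The between-group statistic is the arithmetic mean of corrected
distances over all inter-group pairs (Dxy-style); sliding-window
profiles also record the per-window min/max over pairs, since
published comparisons often quote per-population ranges.

Windows start at 1, 1+step, … while they fit; the final partial window
is discarded (window 657 bp, step 5 bp over a 1,542 bp alignment gives
178 windows). Window values are computed from cumulative mismatch/site
scans and are exactly equal to recomputing the whole-region statistic
on the window's columns; a window spanning the whole alignment equals
the whole-region divergence identically. Matrices are exported as
percent TSV (unit stated in a header comment) or per-site square
PHYLIP for external tree software; tree inference itself is out of
scope.

## Delimitation

Samples are partitioned by single linkage at a percent threshold
(default 3.5): joined iff connected by a chain of pairwise divergences
strictly below the threshold. The boundary is splitting — a pair at
exactly 3.5% forms two clusters — matching the "equal to or higher
than" phrasing of the threshold's definition; this matters because the
motivating case sits at roughly 2.5–4.8% depending on the gene region.
Single linkage formalises the divergence-gap reading of the threshold
criterion; complete linkage is available for sensitivity analysis. The
discordance report lists every pair whose co-cluster membership
differs between regions, with the pairwise value in each region.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume,
so every stage is testable without downloads:

- A random codon sequence (default 514 codons = 1,542 bp, ATG start,
  no internal stop) acts as the root gene. A fixed fraction of codons
  (default 0.6) is marked conserved; the set is drawn once per seed
  and shared with the panel builder, so the panel's conserved mask
  equals the generator's truth by construction.
- Groups follow a star phylogeny: each group ancestor sits at half its
  `to_sibling` target from the root (two siblings with equal targets
  realise the target between them), and each haplotype at half the
  `within` target from its ancestor. Substitutions are
  Jukes–Cantor-style (uniform across bases) with the substitution
  count fixed at the target expectation and sites drawn without
  replacement, weighted by an optional region rate profile — i.e. a JC
  process conditioned on its substitution count. This keeps realised
  divergences tight around their targets (well within binomial
  sampling bands), which matters because the delimitation scenario
  plants effects only ~1 percentage point from the 3.5% boundary.
  Mutations at conserved codons are restricted to synonymous changes;
  no mutation may create a stop; codons broken by two interacting
  substitutions are repaired by reverting the later site.
  Unattainable targets raise an error suggesting a lower value.
- Measured between-group divergence of haplotypes (as opposed to
  ancestors) additionally contains the within-group tip depths, as in
  any real population sample.
- NUMT classes: *indel* (1–4 bp interior, homopolymer-biased
  placement), *stop* (an in-frame TAA/TAG planted mid-sequence),
  *terminal-cluster* (a 9–116 bp terminal stretch with non-synonymous
  substitutions at ~0.25/bp), *global-divergent* (unconstrained
  substitutions at ~5.3% per site), and *decoy-chimera* (5′ third from
  the parent, remainder from a decoy). Every lesion is recorded with
  coordinates in the truth table.
- Default study conditions: three groups patterned on the
  Mediterranean whitefly subclades — two close siblings (n = 14 and
  12, within 0.8%, between ~1.2%) and one group near the boundary
  (n = 10, within 0.6%, ~2.2% to the siblings) — with ten NUMTs per
  deterministic class, five chimeras and two decoys. The boundary
  scenario (`asl_scenario_config`) uses two groups of two haplotypes
  at a 3.3% ancestor target under a 2:1 5′/3′ rate profile, placing
  the 3′ barcode near 2.3% and the 5′ barcode near 4.5%; the contrast
  is slightly wider than the 3.81–3.96% vs 1.98–2.74% pattern that
  motivates it, so the planted effect stands clear of the sampling
  noise inherent to 657 bp windows.

What the generator does **not** emulate: within-group genealogy
(haplotypes are independent draws from the ancestor, no coalescent
structure), recombination, transition/transversion bias or
among-site rate variation beyond the block profile, sequencing error,
length polymorphism of deposited sequences, and base-composition
skew. Passing tests therefore demonstrate that the pipeline recovers
planted structure under its own model assumptions, not that the
thresholds are optimal for field data.

All outputs are reproducible from (config, seed): re-generating from
the config echoed into a fixture is byte-identical.

## Problem sizes and runtimes

The bundled analyses are desk-scale by design: the default study is 81
partial haplotypes of 657 bp against 1,542 bp references (a full
screen runs in a few seconds), and the boundary scenario uses four
full-length sequences. The accession-based reproduction (real
mitogenomes) runs in minutes once sequences are local; it requires a
one-time download via `scripts/fetch_accessions.py` because the
records cannot be redistributed with the package.

## Known limitations

- The screen assumes the reference gene starts at codon position 1;
  references extracted from annotated mitogenomes satisfy this.
- The centre-star progressive aligner is adequate for near-identical
  gene copies but is not a general multiple-sequence-alignment
  heuristic; codon-aware alignment is not implemented.
- Criterion-iii thresholds are heuristics; on real data they should be
  read as a triage, not a verdict, and borderline cases inspected via
  the evidence table.
- The 5′ barcode default (positions 1–657) is a convention; locating
  the exact Folmer fragment on a new gene may require primer
  landmarks, and the region is configurable everywhere it is used.
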