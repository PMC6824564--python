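# Methods

## The model

A small inversion (SI) locus is modeled as a hairpin: a 5′ arm *s*, a
loop *l*, and the 3′ arm equal to revcomp(*s*). A flip-flop mutation
replaces *l* by revcomp(*l*) and nothing else. Across a set of aligned
plastomes an SI is a homologous hairpin locus at which at least two
orientations of the loop are observed. The analysis therefore
decomposes into: find hairpins per genome; group them into homologous
loci across genomes; orient every observed loop against a reference;
and map the resulting binary character on a tree.

## Hairpin detection

For every candidate loop interval the stem is grown outward one pair at
a time. The pair closing the loop and the outermost pair must be
Watson–Crick; up to `max_mismatch` interior positions may mismatch
(default 0; mismatch tolerance is intended for cross-species work where
a taxon's arm carries substitutions). A candidate is kept when the
final arm length lies in [`min_stem`, `max_stem`]. Among overlapping
candidates whose loop intervals intersect, any candidate with a
strictly shorter stem than a rival is suppressed; equal-stem rivals are
both kept. This suppression rule is deliberately position-free so that
detection commutes exactly with reverse complementation (the mirrored
sequence yields the mirrored locus set), a property the test suite
checks against an O(n³) enumeration oracle.

Defaults: `min_stem` 8 (the shortest arm among the curated reference
loci), `min_loop` 4 (the reference set contains 4 bp loops, so "longer
than 4" is read as ≥ 4), `max_loop` 30.

## Free energy

ΔG = Σ nearest-neighbor stack energies over the arm + a loop-length
penalty, using the unified DNA/DNA stack table at 37 °C and a
length-indexed hairpin-loop initiation table (linear interpolation
between tabulated sizes, Jacobson–Stockmayer extrapolation above 30).
The model intentionally omits terminal mismatches, dangling ends and
sequence-dependent loop terms: the load-bearing property is that ΔG is
a function of the stem and the loop length only, so the two
orientations of any SI score identically — exactly, not approximately.
Absolute values differ from folding-program output by up to ~2 kcal/mol
depending on parameter set; `stem_duplex_dg` exposes the stem-only sum
separately, and the parameter tables can be swapped via `ThermoParams`.

## Orientation, subtypes and closure

`classify_orientation` calls A when the observed loop's Levenshtein
distance to the reference loop is strictly smaller than to its reverse
complement, B on the strict converse, and ambiguous on ties (which
covers every reverse-complement-palindromic loop; such loops have no
observable orientation and are excluded from SI calling). Subtypes
group identical observed loops within an orientation, numbered by
decreasing taxon count then first occurrence. Closure between forms is
checked with a free-end-gap (infix) edit distance — one form may carry
extra flanking bases relative to the reverse complement of the other,
as happens in the curated reference set — with a default budget of 3
edits.

The A form is the majority orientation; on an exact tie the form
carried by the first taxon in input order is named A. Permuting taxa
therefore never changes the locus set or the orientation partition,
only (on ties) which side is called "A".

## Homology grouping

Hairpins from different taxa belong to one locus when the alignment
columns under their stem arms overlap with Jaccard ≥ 0.5 (single
linkage). Grouping uses the arms, not the loops, because loop sequence
divergence is the signal itself. Loci observed in fewer than
`min_taxa_with_stem` taxa (default 15 of 20) are dropped as unreliable,
and loci monomorphic in orientation are not SIs.

## Quadripartite partition

The partition is the maximal-length exact inverted-repeat pair on the
circle (found by binary search over repeat length with a rolling-hash
table and literal verification; monotonicity holds because any length-L
repeat pair contains length-(L−1) pairs). The larger single-copy arc is
LSC. Among equally maximal pairs the geometry with the smallest LSC
start after canonical rotation is chosen. Exact matching (no mismatch
tolerance) reflects genomes whose IR copies are identical; detection is
rotation-invariant, which the tests exercise directly.

## SSR scanning

For each unit length 1–5 the genome is scanned for maximal runs with
that period; a locus spans the whole copies only, anchored at the
leftmost phase, and qualifies at ≥ 10/5/4/3/2 copies for mono- through
penta-motifs ("more than ten times" is read as at least ten because
10 bp mono-runs are part of the reported data). Motifs are canonicalized
to the lexicographically smallest rotation on the given strand (AT and
TA collapse; A-runs and T-runs stay distinct), non-primitive motifs are
skipped so each physical repeat is reported once, and runs containing N
are broken. Cross-taxon SSR comparison (unit ≥ 2 only) matches loci by
alignment-column overlap and labels each locus conserved (equal copy
number everywhere), autapomorphic (exactly one deviant taxon) or
synapomorphic.

## Nucleotide diversity

π in a window is Nei's average pairwise proportion of differing sites,
computed over valid sites only — columns where *every* row has an
unambiguous base (complete deletion per window; a `pairwise` mode is
available). The denominator is the valid-site count, not the window
length, so gap-rich spacers are not deflated; windows with zero valid
sites report π as missing rather than 0, and partial tail windows are
dropped. Defaults: 600 bp window, 200 bp step. Hotspots are maximal
runs of windows with π ≥ 0.015, ranked by peak.

## Parsimony mapping

Characters are binary (A/B) with '?' treated as the unrestricted set in
the Fitch bottom-up pass; polytomies use multi-child
intersection/union. For a binary character every minimum reconstruction
is fixed once the root state is chosen, so ACCTRAN reduces to the root
choice: the candidate whose change list has the rootward-most depth
profile wins, with a final tie broken toward the state of the first
non-missing leaf in canonical order (children sorted by smallest
descendant label). That anchor makes the reconstruction equivariant
under relabeling A↔B — lengths unchanged, change directions swapped —
which a brute-force enumeration oracle verifies on random trees up to
12 leaves.

## Synthetic data

The simulator assembles an ancestor from named blocks (genes, optionally
multi-exon, and spacers) for LSC and SSC plus an inverted-repeat pair,
plants hairpins and SSRs at fixed offsets, and evolves the genome along
a rooted tree under Jukes–Cantor (exact per-site transition
probabilities per branch). Design choices that matter for
interpretation:

- **Protection.** Planted elements (plus 1 bp guards chosen so arms and
  runs cannot extend by chance) are excluded from substitution; this is
  a simulation convenience that guarantees truth-table recovery, and a
  `hostile` flag lifts it to exercise stem-erosion behavior. Background
  sequence is scrubbed so no accidental SSR meets the class thresholds
  in the ancestor; substitutions along branches can still create a few,
  so truth assertions at nonzero rates are subset-based for SSRs.
- **Flips.** A flip branch reverse-complements the planted loop in the
  child and is inherited below; two flips on a path cancel. The truth
  table records per-taxon orientations with the same majority/tie rule
  the caller uses.
- **IR evolution.** Within each taxon IRa is set to revcomp(IRb) after
  substitution (concerted evolution), and IR sites mutate at
  `ir_rate_scale` (default 0.3) times the single-copy rate, emulating
  the mutation-removing gene conversion that makes real IRs conserved.
- **No indels** by default, so the true alignment is column-exact; an
  indel-free world is the main idealization — real spacers align with
  gaps, and homology grouping on real data inherits alignment error.
  Passing tests on synthetic data therefore demonstrate correctness of
  the algorithms given a correct alignment, not robustness to
  misalignment.

`survey_like_config` builds a 20-taxon dataset that mirrors the
structure of the curated reference set: the same eleven stem/loop
constructs planted in spacers, genes and an intron named after the real
flanking genes, flips placed to yield five autapomorphic and six
multi-flip loci, and SSRs of every motif class.

## Problem sizes and numerics

Synthetic genomes in the shipped configurations are ~3–9 kb with IRs of
0.3–1 kb — small enough that detection, calling and simulation all run
in seconds while exercising every code path; all coordinates are
0-based half-open in memory and 1-based inclusive in reports. All
randomness flows from a single integer seed through one generator.

## Known limitations

- The thermodynamic model is a stem-stack + loop-penalty approximation;
  no multiloops, bulges, dangling ends or terminal-mismatch terms.
- Exact-match IR detection will underestimate the IR when the two
  copies differ by even one base (configurable mismatch tolerance is
  not implemented for the partition step).
- SI calling assumes the provided alignment is correct; there is no
  realignment or alignment-error model.
- Imperfect/interrupted SSRs and compound-locus merging are out of
  scope; only perfect repeats are reported.
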