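# Methods

This note documents the sequence model behind the synthetic generator, the
detection algorithms and their parameters, the numerical choices that are
load-bearing for the reported results, and the known limitations.

## Channel sequence model

A channel subunit is modelled as one or two 6TM repeats, each consisting of
six transmembrane segments (S1–S6) separated by polar loops, with:

* an **S4 voltage sensor**: a 21-residue segment carrying `k` R/K charges at
  a 3-residue period (positions 1, 4, 7, …, 19 within the segment; charges
  beyond the 7 in-register slots overflow to registers 2 and then 0), the
  remaining positions filled from a hydrophobic/small alphabet;
* an **S4–S5 linker** whose length separates the two architectures
  (CNBD-channels short, Kv-like long);
* a **selectivity filter** between S5 and S6, matching either the 5-mer
  K-channel pattern `[TSC][AA]G[YF]G` (e.g. TVGYG, TVGFG, SVGFG) or the
  4-mer variant `[TSC][AA]G[ED]` (e.g. TIGE); `X` never matches;
* optionally a cytoplasmic **C-linker + CNBD** after S6, built from 17
  canonical elements in fixed order
  `A' B' C' D' E' F' b1 b2 b3 b4 A PBC b5 b6 b7 b8 B`, with arbitrary
  subsets deletable.

The generator (`chanarch.synthetic`) emits sequences from this model
together with exact ground-truth segment coordinates. Blocks are drawn from
segment-appropriate alphabets (TM: `ILVFMA`; loops: `NQDEPHST`; S4 filler:
`LIVFAST`) and then mutated under a BLOSUM62-guided model (per-site rate
0.2, 75% of substitutions conservative), which keeps repeats of a tandem
channel below ~30% mutual identity while preserving detectable structure.
All randomness flows from a single integer seed; per-spec seeds are derived
as `(seed * 100003 + 7919 * (i + 1)) mod 2^31`, so datasets are
byte-reproducible.

**What the generator emulates:** the architectural dichotomies (linker
length distributions N(4.4, 1.5) vs N(11.1, 2.2), rounded; CNBD presence;
S4 charge counts 3–8 including rich/poor mixtures; HCN-style S/T middle
residues; element-deletion menus; two-repeat tandems with asymmetric S4
charge content such as the 8-vs-5 tandem `2Aph1292`). **What it does not
emulate:** real evolutionary covariation between sites, indel processes
inside transmembrane segments, signal peptides/terminal domains beyond
simple polar padding, and base-composition or codon-level effects. Absolute
identity values between synthetic sequences are therefore calibration
artefacts of the mutation model, not evolutionary distances.

## Topology assignment

`chanarch.topology.assign_6tm`:

1. **Hydropathy profile**: Kyte–Doolittle values averaged over a sliding
   window of 19 residues.
2. **TM segment calling**: maximal runs above threshold 1.6 seed candidate
   segments; short cores (≥5 residues) are expanded and segment edges are
   refined against the raw (unwindowed) hydropathy with cutoff 1.0;
   accepted segments are 15–30 residues.
3. **S4 localisation by charge periodicity**: within the region between S3
   and S5, the 21-residue window maximising in-register R/K content is
   taken as S4. This is done *before* trusting the hydropathy boundaries,
   because an S4 with few charges and a short linker can fuse with S5 into
   a single hydrophobic run. When the charge-anchored S4 window overruns
   the hydropathy-called S5 start, S5's start is advanced past the S4
   window and past the following polar run (raw hydropathy < 1.0), bounded
   so S5 keeps its minimum length.
4. **Repeat handling**: twelve TM segments with a second filter motif are
   split into two 6TM repeats; sequences that do not yield a consistent
   6TM assignment are flagged rather than force-fitted.

Recovery is scored against ground truth with ±2 residues of slack per
boundary; on a 200-channel sweep across both groups, S4 charge counts 3–8
and the study linker distributions, recovery is 98.5% and recovered S4
windows contain the exact generated charge count in 100% of channels.

## Determinants

Per repeat (`chanarch.determinants`): filter motif and class
(canonical / variant / non-canonical / absent), S4 R/K count (rich ≥ 7),
the residue at the S4 middle position (read by alignment to a built-in
synthetic S4 reference, `LRILRVFKLISLFRILKVLRI`, middle index 10), the
HCN-style signature (R/K-rich **and** S/T at the middle position), linker
length and class (short < 10), and CNBD status. Linker summaries use the
sample standard deviation (ddof = 1) and flag single-observation groups.

## C-linker/CNBD element mapping

The post-S6 region is aligned semi-globally (free terminal gaps) to a
177-column annotated synthetic template (`data/cnbd_reference.synthetic.fasta`)
whose columns are labelled with the 17 elements. An element is called
**present** iff:

1. **coverage** ≥ 0.5 — at least half of its template columns align to
   residues, and
2. **excision delta** ≥ 7.25 — removing the element's columns from the
   template and re-aligning lowers the optimal score by at least 7.25
   (BLOSUM62 units).

The excision test exists because criterion 1 alone is unreliable: global
aligners smear flanking or tail residues across deleted template columns
("draping"), which can give a genuinely deleted element full coverage and
high chance identity. The threshold 7.25 is the midpoint of an empirically
measured gap: over 2010 truly present and 540 deleted-and-draped element
observations from the generator, present elements scored deltas ≥ 7.5 and
draped ones ≤ 7.0 (scores are quantised in 0.5 steps under the affine gap
model), giving perfect separation on the calibration set.

A region is considered a CNBD at all only if the mapped span is ≥ 10
residues and the overall alignment identity is ≥ 0.24 (`IDENTITY_FLOOR`).
The floor was calibrated against a null of shuffled post-S6 regions
(null identity: mean 0.117, p99 0.196, max 0.228 over 500 shuffles) versus
true heavy-deletion channels (minimum 0.323); 0.24 rejects 500/500 shuffles
while accepting all true CNBDs, including ten-element deletions.

## Pairwise alignment scoring

All residue-level homology mapping uses BLOSUM62 with affine gaps, open 10
and extend 0.5. The DP engine truncates gap penalties to integers, which
would silently turn the 0.5 extension into 0; alignment is therefore run in
doubled-score space (matrix ×2, penalties −20/−1) and the score halved back,
which realises the intended costs exactly. This was verified against an
independent Gotoh dynamic-programming implementation (see
`tests/test_align.py`).

**Percent identity** is matches / alignment columns × 100 — gap columns
count in the denominator. This convention is load-bearing for the ≤30%
inter-repeat identity bound. Because co-optimal alignments can differ in
column count, the two input sequences are ordered canonically (sorted)
before aligning so that identity is symmetric in its arguments.

## Tandem splitting

Channels with two detected repeats are cut at the midpoint of the
inter-repeat region (between repeat 1's S6 end and repeat 2's S1 start) by
default; an `end_of_repeat1` mode cuts at the S6 boundary instead. The two
units exactly partition the parent sequence. Inter-repeat identity on the
standard cohort's ten tandems peaks at 27.6%.

## Alignment curation

`remove_nonconservative_columns(alignment, max_gap_frac, min_identity)`
keeps a column iff its gap fraction is ≤ `max_gap_frac` and its majority
residue fraction (among non-gaps) is ≥ `min_identity`. The filter is
idempotent and returns the retained-column index map. An optional
`strip_terminal_domains` step removes columns outside the S1–S6 core for
mixed datasets where only some sequences carry a CNBD.

## Tree statistics

Trees are parsed with unrooted semantics. Internal-node labels `95` or
`100/0.97` are read as (bootstrap, posterior) supports; the scale is
inferred from value ranges. A tip set is **monophyletic** iff it is exactly
one side of some bipartition — clade sets, their complements, and
pendant-edge complements are all candidate sides. **Robinson–Foulds**
distance counts bipartitions present in exactly one tree and is normalised
by 2(n−3). Both were validated against brute-force bipartition enumeration
and an independent library implementation for all tree sizes up to 8 tips.
Repeat congruence prunes a tree to its `1x*` and `2x*` tips separately,
relabels to parent identifiers, and reports the RF distance between the two
induced trees; repeat separation tests monophyly of each repeat set.

## Limitations

* Topology assignment assumes a plain 6TM (or 2×6TM) architecture with
  polar termini; heavily decorated N-terminal domains (e.g. long
  hydrophobic signal anchors) could produce spurious TM calls.
* The CNBD template, presence thresholds and identity floor were calibrated
  on generator output; applying them to natural sequences would warrant
  recalibration against a biological null.
* The ±2-residue boundary tolerance, the 21-residue S4 window and the
  3-residue charge register are model commitments, not fitted values.
* RF and monophyly computations enumerate bipartitions explicitly and are
  intended for the small trees of this analysis, not for thousands of tips.
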