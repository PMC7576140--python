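# chanarch

Annotation and comparative analysis of 6TM and 6TM-CNBD ion-channel
pore-subunit architectures.

## The problem

Voltage-gated-like cation channels built on the six-transmembrane (6TM)
fold split into two recurring architectures:

* **Kv-like** subunits: an S1–S6 transmembrane core with a charge-rich S4
  voltage sensor, a **long** S4–S5 linker (on the order of 11 residues)
  coupling the sensor to the pore, and no large cytoplasmic cassette after S6.
* **CNBD-channels** (HCN/CNG/EAG-style): the same 6TM core but with a
  **short** S4–S5 linker (~4–5 residues) and a cytoplasmic
  C-linker + cyclic-nucleotide-binding domain (CNBD) downstream of S6, built
  from 17 canonical elements (helices A′–F′, A, B, the phosphate-binding
  cassette PBC, and β-strands b1–b8). Lineage-specific losses prune subsets
  of these elements, leaving "reduced CNBD" channels.

Some channels carry **two** 6TM repeats in tandem on one polypeptide; the two
repeats can differ in S4 charge content (e.g. 8 charges in repeat 1 vs 5 in
repeat 2) and must be split into separate units before phylogenetics, where
the question becomes whether first and second repeats form separate,
mutually congruent clades.

`chanarch` provides:

* hydropathy-based 6TM topology assignment (S1–S6, charge-anchored S4,
  S4–S5 linker, selectivity filter motif),
* per-repeat determinant profiling (filter class, S4 R/K count and middle
  residue, HCN-style signature, linker class),
* C-linker/CNBD element presence/absence mapping against an annotated
  synthetic template, robust to aligner gap-smearing via an excision test,
* tandem-repeat detection, splitting, and inter-repeat identity,
* alignment column curation and tree statistics (clade monophyly,
  Robinson–Foulds congruence of repeat clades),
* a deterministic synthetic-channel generator with ground-truth
  annotations, used for calibration and testing throughout.

## Worked example

Generate the standard 54-channel cohort (22 CNBD-channel singles, 22 Kv-like
singles, 5 tandems of each group) and run the full pipeline:

```sh
$ chanarch simulate --seed 1 --out-fasta cohort.fasta --out-truth truth.tsv
wrote 54 channels to cohort.fasta (seed=1)

$ chanarch run --fasta cohort.fasta --outdir run --seed 1
[chanarch:annotate] 54 sequences, 64 repeats
[chanarch:cnbd] 32/64 repeats carry a CNBD
[chanarch:determinants] 64 repeat profiles
[chanarch:split-tandem] 10 tandem channels split
```

`run/profiles.tsv` carries one row per repeat:

```
id        repeat  group         filter_motif  filter_class  s4_rk_count  s4_middle  hcn_signature  rk_rich  linker_length  linker_class  has_cnbd  absent_elements
cnbd000   1       CNBD-channel  TVGYG         canonical     7            S          True           True     6              short         True
cnbd003   1       CNBD-channel  TVGYG         canonical     8            -          False          True     5              short         True      C',D',E',F',PBC,b5,b6,b7,b8,B
2Aph1292  1       Kv-like       TVGYG         canonical     8            R          False          True     5              short         False     ...
2Aph1292  2       Kv-like       TVGYG         canonical     5            K          False          False    8              short         False     ...
```

Note the tandem `2Aph1292`: a Kv-like two-repeat channel whose repeats carry
8 and 5 S4 charges respectively. `cnbd003` is a reduced-CNBD channel — the
CNBD is present but ten of its seventeen elements are absent.

Summarising the S4–S5 linkers by group (`analysis/03_determinant_profiles.py`):

```
       group   n     mean       sd
CNBD-channel  32  4.46875  1.367465
     Kv-like  32 10.78125  2.090445
```

reproduces the short-vs-long linker dichotomy. Group classification agrees
with the generating labels for 54/54 channels; topology recovery within
±2 residues per boundary is 61/64 repeats on this cohort and 98.5% on a
broader 200-channel sweep; the maximum inter-repeat identity among the ten
split tandems is 27.6% (consistent with the ≤30% divergence the generator
targets).

The same stages are available individually (`chanarch annotate`,
`chanarch determinants`, `chanarch cnbd`, `chanarch split-tandem`,
`chanarch curate-msa`, `chanarch tree-stats`); see `--help` on each.

## Tests

```sh
pip install -e '.[test]'
pytest -q
```

The suite covers unit behaviour, seeded property-based tests (hypothesis)
and the acceptance criteria in `tests/test_acceptance.py`.

## Layout

```
src/chanarch/     library code (topology, determinants, cnbd, tandem,
                  align, msa, trees, synthetic, pipeline, cli)
src/chanarch/data/  annotated synthetic C-linker/CNBD template
analysis/         numbered thin drivers writing tables under results/
scripts/          acceptance.py (end-to-end quantity recomputation)
docs/methods.md   model, parameters, calibrations and limitations
tests/            pytest suite
```

Methodological details — detection thresholds, alignment scoring, the
excision-based element-presence test and its calibration, and what the
synthetic generator does and does not emulate — are documented in
[docs/methods.md](docs/methods.md).
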