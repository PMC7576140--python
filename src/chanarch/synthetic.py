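"""Synthetic channel proteins and repeat trees with machine-readable ground truth.

The generator emulates the architecture of 6TM / 6TM-CNBD channel pore
subunits: hydrophobic transmembrane segments S1-S3, S5, S6; an amphipathic S4
with arginine/lysine at three-residue spacing (optionally with the HCN-style
serine/threonine at the middle register position); a P-loop carrying a
selectivity-filter motif embedded verbatim; an optional C-linker + CNBD block
copied from the built-in element template with chosen elements excised; and
optional two-repeat tandem concatenation. Trees carry the 1x/2x tip naming of
tandem repeats with controllable congruence between the two repeat clades.

Alphabets and layout constants are fixed by design so that hydropathy-based
detection is exercised without per-run tuning. What the generator does NOT
emulate: realistic substitution processes along a phylogeny, transcriptome
fragmentation, or frameshifts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from chanarch.cnbd import load_reference
from chanarch.types import ELEMENT_ORDER, ChannelSequence

#: Alphabet for hydrophobic TM segments (all KD >= 1.8).
TM_ALPHABET = "ILVFMA"
#: Polar loop alphabet. Deliberately G/Y/F/R/K-free so loops can neither match
#: the selectivity-filter patterns nor contribute S4 charges.
LOOP_ALPHABET = "NQDEPHST"
#: Non-charged S4 positions: mixed hydrophobic/polar, keeping S4 amphipathic
#: (mean KD below the TM threshold) so hydropathy alone cannot find it.
S4_FILL_ALPHABET = "LIVFAST"

#: Default inter-segment loop lengths (residues).
DEFAULT_LOOPS = {
    "nterm": 12,
    "s1_s2": 12,
    "s2_s3": 12,
    "s3_s4": 6,
    "s4_s5": 5,
    "ploop_pre": 8,
    "ploop_post": 8,
    "cterm": 12,
    "inter_repeat": 24,
}

_VALID_ELEMENTS = set(ELEMENT_ORDER)


class SpecError(ValueError):
    """Raised when a SynthChannelSpec is internally contradictory."""


@dataclass
class SynthChannelSpec:
    """Declarative description of one synthetic channel (per-repeat lists)."""

    n_repeats: int = 1
    s4_rk_counts: list[int] = field(default_factory=lambda: [6])
    s4_middle_polar: list[bool] = field(default_factory=lambda: [False])
    filter_motifs: list[str] = field(default_factory=lambda: ["TVGYG"])
    has_cnbd: list[bool] = field(default_factory=lambda: [False])
    deleted_elements: list[list[str]] = field(default_factory=lambda: [[]])
    loop_lengths: dict = field(default_factory=dict)
    tm_length: int = 21
    # Per-repeat divergence of the CNBD block from the shared template.
    # 0.2 with the conservative substitution model leaves each repeat clearly
    # alignable to the template while keeping the two repeats of a tandem
    # channel at the low (<=30%) whole-repeat identity characteristic of
    # anciently duplicated repeats.
    mutation_rate: float = 0.2
    id: str | None = None
    group: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_repeats not in (1, 2):
            raise SpecError(f"n_repeats must be 1 or 2, got {self.n_repeats}")
        for name in ("s4_rk_counts", "s4_middle_polar", "filter_motifs",
                     "has_cnbd", "deleted_elements"):
            if len(getattr(self, name)) != self.n_repeats:
                raise SpecError(
                    f"{name} must have one entry per repeat "
                    f"({self.n_repeats}), got {len(getattr(self, name))}"
                )
        for k in self.s4_rk_counts:
            if not (0 <= k <= self.tm_length):
                raise SpecError(f"s4_rk_counts entry {k} outside [0, tm_length]")
        for m in self.filter_motifs:
            if len(m) not in (4, 5):
                raise SpecError(f"filter_motifs entry {m!r} must have length 4 or 5")
        for r, (cn, dele) in enumerate(zip(self.has_cnbd, self.deleted_elements)):
            bad = set(dele) - _VALID_ELEMENTS
            if bad:
                raise SpecError(f"deleted_elements: unknown elements {sorted(bad)}")
            if dele and not cn:
                raise SpecError(
                    f"deleted_elements given for repeat {r + 1} but has_cnbd is false"
                )
        for k, v in self.loop_lengths.items():
            if k not in DEFAULT_LOOPS:
                raise SpecError(f"loop_lengths: unknown gap name {k!r}")


@dataclass
class TruthSegment:
    repeat: int
    label: str
    start: int
    end: int


@dataclass
class TopologyTruth:
    """Ground-truth coordinates for one generated channel."""

    segments: list[TruthSegment] = field(default_factory=list)
    repeat_boundaries: list[tuple[int, int]] = field(default_factory=list)
    filter_positions: list[int] = field(default_factory=list)

    def segment(self, repeat: int, label: str) -> TruthSegment:
        for s in self.segments:
            if s.repeat == repeat and s.label == label:
                return s
        raise KeyError(f"no truth segment {label} in repeat {repeat}")

    def linker_length(self, repeat: int) -> int:
        return self.segment(repeat, "S5").start - self.segment(repeat, "S4").end


def _loop_len(spec: SynthChannelSpec, name: str, repeat0: int) -> int:
    v = spec.loop_lengths.get(name, DEFAULT_LOOPS[name])
    if isinstance(v, (list, tuple)):
        return int(v[repeat0])
    return int(v)


def _s4_slots(tm_length: int, middle_polar: bool, k: int) -> tuple[list[int], int]:
    """Charge positions for S4: period-3 registers, first at offset 1.

    The middle register slot hosts S/T when ``middle_polar``. Counts beyond the
    primary register spill into a second register starting at offset 2, then a
    third at offset 0 (a 21-residue single register caps at 7 charges, while
    observed tandem repeats reach 8).
    """
    middle = 1 + 3 * round((tm_length // 2 - 1) / 3)
    order: list[int] = []
    for offset in (1, 2, 0):
        order.extend(range(offset, tm_length, 3))
    if middle_polar:
        order = [p for p in order if p != middle]
    return sorted(order[:k]), middle


def _make_s4(spec: SynthChannelSpec, repeat0: int, rng: np.random.Generator) -> str:
    k = spec.s4_rk_counts[repeat0]
    polar = spec.s4_middle_polar[repeat0]
    slots, middle = _s4_slots(spec.tm_length, polar, k)
    res = list(rng.choice(list(S4_FILL_ALPHABET), size=spec.tm_length))
    if polar:
        res[middle] = rng.choice(["S", "T"])
    for p in slots:
        res[p] = rng.choice(["R", "K"])
    return "".join(res)


_AAS = list("ACDEFGHIKLMNPQRSTVWY")
_CONSERVATIVE: dict[str, list[str]] = {}


def _conservative_choices(aa: str) -> list[str]:
    """Residues scoring >= 0 against ``aa`` under BLOSUM62 (identity excluded)."""
    if not _CONSERVATIVE:
        import biotite.sequence as bseq
        import biotite.sequence.align as balign

        mat = balign.SubstitutionMatrix.std_protein_matrix()
        for a in _AAS:
            _CONSERVATIVE[a] = [
                b for b in _AAS if b != a and mat.get_score(a, b) >= 0
            ] or [b for b in _AAS if b != a]
    return _CONSERVATIVE[aa]


def _mutate(block: str, rate: float, rng: np.random.Generator) -> str:
    """Point-substitute at ``rate``; three of four substitutions conservative.

    Divergence in real homologous domains is biased toward biochemically
    similar residues; a purely uniform replacement model would make synthetic
    homologs far less alignable than real ones at the same distance.
    """
    if rate <= 0:
        return block
    res = list(block)
    for i in range(len(res)):
        if rng.random() >= rate:
            continue
        if rng.random() < 0.75:
            res[i] = rng.choice(_conservative_choices(res[i]))
        else:
            res[i] = rng.choice([a for a in _AAS if a != res[i]])
    return "".join(res)


def generate_channel(spec: SynthChannelSpec) -> tuple[ChannelSequence, TopologyTruth]:
    """Build one synthetic channel and its ground-truth topology.

    Deterministic given ``spec`` (including ``spec.seed``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ref = load_reference()
    parts: list[str] = []
    truth = TopologyTruth()
    pos = 0

    def emit(s: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(s)
        start, pos_end = pos, pos + len(s)
        pos = pos_end
        return start, pos_end

    def loop(name: str, repeat0: int) -> None:
        n = _loop_len(spec, name, repeat0)
        if n > 0:
            emit("".join(rng.choice(list(LOOP_ALPHABET), size=n)))

    for r in range(spec.n_repeats):
        rep = r + 1
        rep_start = pos
        if r == 0:
            loop("nterm", r)
        for label, gap_after in (("S1", "s1_s2"), ("S2", "s2_s3"), ("S3", "s3_s4")):
            span = emit("".join(rng.choice(list(TM_ALPHABET), size=spec.tm_length)))
            truth.segments.append(TruthSegment(rep, label, *span))
            loop(gap_after, r)
        span = emit(_make_s4(spec, r, rng))
        truth.segments.append(TruthSegment(rep, "S4", *span))
        loop("s4_s5", r)
        span = emit("".join(rng.choice(list(TM_ALPHABET), size=spec.tm_length)))
        truth.segments.append(TruthSegment(rep, "S5", *span))
        ploop_start = pos
        loop("ploop_pre", r)
        fstart, _ = emit(spec.filter_motifs[r])
        truth.filter_positions.append(fstart)
        loop("ploop_post", r)
        truth.segments.append(TruthSegment(rep, "Ploop", ploop_start, pos))
        span = emit("".join(rng.choice(list(TM_ALPHABET), size=spec.tm_length)))
        truth.segments.append(TruthSegment(rep, "S6", *span))
        if spec.has_cnbd[r]:
            deleted = set(spec.deleted_elements[r])
            keep = [
                i for i in range(len(ref.sequence))
                if ref.labels[i] not in deleted
            ]
            block = "".join(ref.sequence[i] for i in keep)
            block = _mutate(block, spec.mutation_rate, rng)
            bstart, bend = emit(block)
            col_of = {orig: bstart + new for new, orig in enumerate(keep)}
            for span_name, (lo, hi) in (("Clinker", ref.clinker_cols),
                                        ("CNBD", ref.cnbd_cols)):
                cols = [col_of[i] for i in range(lo, hi) if i in col_of]
                if cols:
                    truth.segments.append(
                        TruthSegment(rep, span_name, min(cols), max(cols) + 1)
                    )
        loop("cterm", r)
        truth.repeat_boundaries.append((rep_start, pos))
        if r == 0 and spec.n_repeats == 2:
            loop("inter_repeat", r)

    seq = ChannelSequence(
        id=spec.id or "syn", residues="".join(parts), group=spec.group,
        source="synthetic",
    )
    return seq, truth


def generate_dataset(
    specs: list[SynthChannelSpec],
    seed: int = 0,
    fasta_path=None,
    truth_path=None,
) -> tuple[list[ChannelSequence], list[TopologyTruth]]:
    """Generate one record per spec; optionally write FASTA + truth TSV/JSON.

    Specs without an explicit id are auto-named ``syn000``...; duplicate
    requested identifiers are an error. Per-spec seeds, when left at 0, are
    derived deterministically from ``seed`` and the spec index.
    """
    if not specs:
        raise ValueError("empty spec list")
    seqs: list[ChannelSequence] = []
    truths: list[TopologyTruth] = []
    ids: set[str] = set()
    for i, spec in enumerate(specs):
        spec = replace(spec)
        if spec.id is None:
            spec.id = f"syn{i:03d}"
        if spec.seed == 0:
            spec.seed = (int(seed) * 100003 + 7919 * (i + 1)) % (2**31)
        if spec.id in ids:
            raise ValueError(f"duplicate identifier {spec.id!r}")
        ids.add(spec.id)
        seq, truth = generate_channel(spec)
        seqs.append(seq)
        truths.append(truth)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for s in seqs:
                fh.write(f">{s.id} group={s.group or 'NA'}\n")
                for j in range(0, len(s.residues), 60):
                    fh.write(s.residues[j : j + 60] + "\n")
    if truth_path is not None:
        truth_path = str(truth_path)
        if truth_path.endswith(".json"):
            payload = [
                {
                    "id": s.id,
                    "segments": [vars(t) for t in tr.segments],
                    "repeat_boundaries": tr.repeat_boundaries,
                    "filter_positions": tr.filter_positions,
                }
                for s, tr in zip(seqs, truths)
            ]
            with open(truth_path, "w") as fh:
                json.dump(payload, fh, indent=1)
        else:
            with open(truth_path, "w") as fh:
                fh.write("id\trepeat\tlabel\tstart\tend\n")
                for s, tr in zip(seqs, truths):
                    for t in tr.segments:
                        fh.write(f"{s.id}\t{t.repeat}\t{t.label}\t{t.start}\t{t.end}\n")
    return seqs, truths


# ---------------------------------------------------------------------------
# study cohort: the conditions the downstream analyses are exercised under
# ---------------------------------------------------------------------------

def study_cohort(seed: int = 1, n_cnbd_single: int = 22, n_kv_single: int = 22,
                 n_cnbd_tandem: int = 5, n_kv_tandem: int = 5
                 ) -> list[SynthChannelSpec]:
    """Spec list emulating the study's channel inventory.

    CNBD-channels carry short S4-S5 linkers (rounded draws from N(4.4, 1.5))
    and a C-linker+CNBD block, a subset with HCN-style middle-S/T S4s and a
    subset with element deletions; Kv-like channels have long linkers (rounded
    N(11.1, 2.2)) and no CNBD. S4 charge counts span 3-8 in both groups so
    R/K-rich, poor and mixed clades all occur. A 2Aph1292-style Kv-like tandem
    with 8 vs 5 S4 charges and short-first/long-second linkers is included.
    """
    rng = np.random.default_rng(seed)

    def short_linker() -> int:
        return int(np.clip(round(rng.normal(4.4, 1.5)), 1, 9))

    def long_linker() -> int:
        return int(np.clip(round(rng.normal(11.1, 2.2)), 5, 20))

    filters = ["TVGYG", "TVGFG", "SVGFG", "TVGYG", "CIGYG", "TVGYG"]
    deletion_menu = [["b7"], ["b5", "b7", "b8", "B"], ["b7", "b8", "B"],
                     ["C'", "D'", "E'", "F'", "b5", "b6", "b7", "b8", "PBC", "B"]]
    specs: list[SynthChannelSpec] = []
    for i in range(n_cnbd_single):
        hcn_like = i % 4 == 0
        k = int(rng.integers(7, 9)) if hcn_like else int(rng.integers(3, 9))
        dele = deletion_menu[i % len(deletion_menu)] if i % 7 == 3 else []
        specs.append(SynthChannelSpec(
            n_repeats=1, s4_rk_counts=[k], s4_middle_polar=[hcn_like],
            filter_motifs=[filters[i % len(filters)]], has_cnbd=[True],
            deleted_elements=[dele],
            loop_lengths={"s4_s5": short_linker()},
            id=f"cnbd{i:03d}", group="CNBD-channel",
        ))
    for i in range(n_kv_single):
        specs.append(SynthChannelSpec(
            n_repeats=1, s4_rk_counts=[int(rng.integers(3, 9))],
            s4_middle_polar=[False],
            filter_motifs=[filters[i % 4]], has_cnbd=[False],
            deleted_elements=[[]],
            loop_lengths={"s4_s5": long_linker()},
            id=f"kv{i:03d}", group="Kv-like",
        ))
    for i in range(n_cnbd_tandem):
        specs.append(SynthChannelSpec(
            n_repeats=2,
            s4_rk_counts=[int(rng.integers(4, 9)), int(rng.integers(4, 9))],
            s4_middle_polar=[False, False],
            filter_motifs=["TVGYG", "TVGFG"], has_cnbd=[True, True],
            deleted_elements=[[], deletion_menu[i % len(deletion_menu)] if i % 2 else []],
            loop_lengths={"s4_s5": [short_linker(), short_linker()]},
            id=f"2Ct{i:03d}", group="CNBD-channel",
        ))
    for i in range(n_kv_tandem):
        if i == 0:
            specs.append(SynthChannelSpec(
                n_repeats=2, s4_rk_counts=[8, 5], s4_middle_polar=[False, False],
                filter_motifs=["TVGYG", "TVGYG"], has_cnbd=[False, False],
                deleted_elements=[[], []],
                loop_lengths={"s4_s5": [short_linker(), long_linker()]},
                id="2Aph1292", group="Kv-like",
            ))
        else:
            specs.append(SynthChannelSpec(
                n_repeats=2,
                s4_rk_counts=[int(rng.integers(4, 9)), int(rng.integers(3, 7))],
                s4_middle_polar=[False, False],
                filter_motifs=["TVGYG", "TVGYG"], has_cnbd=[False, False],
                deleted_elements=[[], []],
                loop_lengths={"s4_s5": [long_linker(), long_linker()]},
                id=f"2Kt{i:03d}", group="Kv-like",
            ))
    return specs


# ---------------------------------------------------------------------------
# repeat trees
# ---------------------------------------------------------------------------

def _random_topology(labels: list[str], rng: np.random.Generator):
    """Random binary topology by sequential pair joining (coalescent-style)."""
    nodes: list = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]


def _relabel(top, mapping):
    if isinstance(top, tuple):
        return tuple(_relabel(t, mapping) for t in top)
    return mapping[top]


def _to_newick(top, rng: np.random.Generator) -> str:
    if isinstance(top, tuple):
        inner = ",".join(f"{_to_newick(t, rng)}:{rng.exponential(1.0):.4f}"
                         for t in top)
        return f"({inner})"
    return top


def generate_repeat_tree(n_tandem: int, n_single: int, congruent: bool,
                         seed: int = 0) -> tuple[str, dict]:
    """Newick tree whose 1x/2x repeat clades are congruent or reshuffled.

    Tips ``1xtd<i>`` and ``2xtd<i>`` for each tandem channel plus ``sng<i>``
    singleton tips. With ``congruent=True`` the second-repeat clade is a
    topological copy of the first-repeat clade (RF distance 0 after mapping
    tips to parent identifiers); with ``False`` the tip assignment of the
    second clade is randomly permuted. Returns (newick string, tip metadata).
    """
    if n_tandem < 2:
        raise ValueError("n_tandem must be >= 2 (repeat congruence undefined)")
    if n_tandem == 2:
        warnings.warn(
            "n_tandem=2: only one unrooted 2-tip topology exists; "
            "congruence is trivially 0", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    fams = [f"td{i}" for i in range(n_tandem)]
    top1 = _random_topology([f"1x{f}" for f in fams], rng)
    if congruent:
        mapping = {f"1x{f}": f"2x{f}" for f in fams}
    else:
        perm = list(fams)
        rng.shuffle(perm)
        mapping = {f"1x{a}": f"2x{b}" for a, b in zip(fams, perm)}
    top2 = _relabel(top1, mapping)
    core = (top1, top2)
    for i in range(n_single):
        core = (core, f"sng{i}")
    newick = _to_newick(core, rng) + ";"
    meta = {}
    for f in fams:
        meta[f"1x{f}"] = {"family": f, "repeat": 1}
        meta[f"2x{f}"] = {"family": f, "repeat": 2}
    for i in range(n_single):
        meta[f"sng{i}"] = {"family": f"sng{i}", "repeat": 0}
    return newick, meta
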