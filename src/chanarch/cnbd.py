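"""C-linker + CNBD detection, element-deletion reporting, and group assignment.

The region downstream of S6 is globally aligned (terminal gaps free) to a
single built-in element template whose columns are labelled with the 17
canonical secondary-structure elements, in left-to-right order: C-linker
helices A'-F', then beta-strands 1-4, helix A, the phosphate-binding cassette
(PBC), beta-strands 5-8 and helix B. An element is called present when at
least half of its template columns align to residues and excising its columns
from the template lowers the optimal alignment score (chance-draped residues
do not contribute real score, so excision arbitrates borderline coverage); a
region whose overall alignment identity falls below the detection floor
carries no CNBD at all.

The shipped template is a synthetic HCN1-style layout (see
``data/cnbd_reference.synthetic.fasta``): element order and approximate
lengths follow the canonical HCN C-terminal architecture, the residue content
is generated, not a database sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from chanarch import align
from chanarch.types import (
    CLINKER_ELEMENTS,
    CNBDMap,
    ChannelSequence,
    DeterminantProfile,
    ELEMENT_ORDER,
    TopologyModel,
)

PRESENCE_THRESHOLD = 0.5   # fraction of element columns that must align
IDENTITY_FLOOR = 0.24      # below this overall identity: no CNBD at all (calibrated
                           # against the shuffled-region null distribution)
MIN_REGION_LEN = 10        # shorter C-terminal regions cannot host a CNBD
EXCISION_DELTA_MIN = 7.25  # minimum score drop on excising an element's
                           # template columns for the element to count as
                           # present (sits in the empirical gap between
                           # chance-draped and genuinely aligned elements)

_CODE_TO_ELEMENT = {
    "a": "A'", "b": "B'", "c": "C'", "d": "D'", "e": "E'", "f": "F'",
    "1": "b1", "2": "b2", "3": "b3", "4": "b4", "5": "b5", "6": "b6",
    "7": "b7", "8": "b8", "A": "A", "P": "PBC", "B": "B", "-": None,
}


@dataclass
class ElementReference:
    """The element template: sequence plus per-column element labels."""

    sequence: str
    labels: list  # per-column element name or None

    element_cols: dict[str, list[int]] = field(default_factory=dict)
    clinker_cols: tuple[int, int] = (0, 0)
    cnbd_cols: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.labels):
            raise ValueError("reference sequence/label length mismatch")
        for e in ELEMENT_ORDER:
            self.element_cols[e] = [i for i, l in enumerate(self.labels) if l == e]
            if not self.element_cols[e]:
                raise ValueError(f"reference lacks element {e}")
        cl = [i for i, l in enumerate(self.labels) if l in CLINKER_ELEMENTS]
        cn = [i for i, l in enumerate(self.labels)
              if l is not None and l not in CLINKER_ELEMENTS]
        self.clinker_cols = (min(cl), max(cl) + 1)
        self.cnbd_cols = (min(cn), max(cn) + 1)


_REFERENCE: ElementReference | None = None


def load_reference() -> ElementReference:
    """Load (and cache) the shipped synthetic element template."""
    global _REFERENCE
    if _REFERENCE is None:
        text = (
            resources.files("chanarch").joinpath("data/cnbd_reference.synthetic.fasta")
            .read_text()
        )
        records: list[list[str]] = []
        for line in text.splitlines():
            if line.startswith(">"):
                records.append([])
            elif line.strip():
                records[-1].append(line.strip())
        seq = "".join(records[0])
        codes = "".join(records[1])
        _REFERENCE = ElementReference(seq, [_CODE_TO_ELEMENT[c] for c in codes])
    return _REFERENCE


def _excision_delta(
    ref: ElementReference, element: str, region: str, full_score: float
) -> float:
    """Score drop when the element's columns are removed from the reference."""
    cols = set(ref.element_cols[element])
    reduced = "".join(a for i, a in enumerate(ref.sequence) if i not in cols)
    aln = align.global_align(reduced, region, terminal_penalty=False)
    return full_score - aln.score


def detect_cnbd(
    seq: ChannelSequence,
    model: TopologyModel,
    repeat: int = 1,
    ref: ElementReference | None = None,
    presence_threshold: float = PRESENCE_THRESHOLD,
    identity_floor: float = IDENTITY_FLOOR,
) -> CNBDMap:
    """Map C-linker/CNBD elements for one repeat; absence is a result.

    The searched region runs from the end of the repeat's S6 to the start of
    the next repeat's S1 (or the sequence end).
    """
    ref = ref or load_reference()
    rep = next((r for r in model.repeats if r.index == repeat), None)
    if rep is None or "S6" not in rep.segments:
        raise ValueError(f"{seq.id}: repeat {repeat} has no S6 annotation")
    region_start = rep.segments["S6"].end
    nxt = next((r for r in model.repeats if r.index == repeat + 1), None)
    region_end = nxt.segments["S1"].start if nxt else len(seq.residues)
    region = seq.residues[region_start:region_end]

    cmap = CNBDMap(
        sequence_id=seq.id, repeat=repeat, has_cnbd=False, identity=0.0,
        elements={e: "absent" for e in ELEMENT_ORDER},
        coverage={e: 0.0 for e in ELEMENT_ORDER},
    )
    if len(region) < MIN_REGION_LEN:
        return cmap

    aln = align.global_align(ref.sequence, region, terminal_penalty=False)
    cmap.identity = align.identity_fraction(aln)
    if cmap.identity < identity_floor:
        return cmap

    ref_to_query: dict[int, int] = {}
    for i, j in align.trace_pairs(aln):
        if i >= 0 and j >= 0:
            ref_to_query[i] = j
    any_present = False
    for e in ELEMENT_ORDER:
        cols = ref.element_cols[e]
        cov = sum(1 for c in cols if c in ref_to_query) / len(cols)
        cmap.coverage[e] = cov
        # a deleted element can still collect high coverage when the aligner
        # drapes flanking/tail residues over its columns (chance matches score
        # positively, so the optimum absorbs them). Excising the element's
        # columns from the template arbitrates: a present element contributes
        # real diagonal score, so removing it lowers the optimal score by at
        # least EXCISION_DELTA_MIN; a draped one does not.
        if cov >= presence_threshold and (
            _excision_delta(ref, e, region, aln.score) >= EXCISION_DELTA_MIN
        ):
            cmap.elements[e] = "present"
            any_present = True
    cmap.has_cnbd = any_present
    for name, (lo, hi) in (("clinker_span", ref.clinker_cols),
                           ("cnbd_span", ref.cnbd_cols)):
        qs = [ref_to_query[c] for c in range(lo, hi) if c in ref_to_query]
        if qs:
            setattr(cmap, name,
                    (region_start + min(qs), region_start + max(qs) + 1))
    # hedge for truncated C-termini: the sequence ends inside the aligned span
    aligned_ref_cols = sorted(ref_to_query)
    if (aligned_ref_cols and region_end == len(seq.residues)
            and aligned_ref_cols[-1] < len(ref.sequence) - 10):
        cmap.flags.append("possibly_truncated")
    return cmap


def element_report(maps: list[CNBDMap]) -> list[dict]:
    """One row per (sequence, repeat) listing absent elements in canonical order."""
    rows = []
    for m in maps:
        rows.append({
            "id": m.sequence_id,
            "repeat": m.repeat,
            "has_cnbd": m.has_cnbd,
            "absent": ",".join(m.absent_elements()),
            "flags": ";".join(m.flags),
        })
    return rows


def classify_group(
    profiles: DeterminantProfile | list[DeterminantProfile],
) -> tuple[str, list[str]]:
    """Kv-like vs CNBD-channel assignment for one channel (all its repeats).

    CNBD-channel iff any repeat carries a CNBD; a CNBD with at least one
    element absent yields the additional ``reduced CNBD`` flag (partial
    C-region reductions still classify as CNBD-channels).
    """
    if isinstance(profiles, DeterminantProfile):
        profiles = [profiles]
    flags: list[str] = []
    has = any(p.has_cnbd for p in profiles)
    if not has:
        return "Kv-like", flags
    reduced = any(
        p.has_cnbd and any(v == "absent" for v in p.cnbd_elements.values())
        for p in profiles
    )
    if reduced:
        flags.append("reduced CNBD")
    return "CNBD-channel", flags
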