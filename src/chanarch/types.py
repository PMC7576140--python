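"""Core domain types shared by all analysis stages.

Coordinates are 0-based half-open throughout. Element names follow the canonical
left-to-right order of the C-linker (primed helices A'-F') followed by the CNBD
(beta-strands b1-b8 written ``b1`` ... ``b8``, helices A and B, and the
phosphate-binding cassette ``PBC``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

#: Fixed left-to-right order of C-linker + CNBD secondary-structure elements.
ELEMENT_ORDER: tuple[str, ...] = (
    "A'", "B'", "C'", "D'", "E'", "F'",
    "b1", "b2", "b3", "b4", "A", "PBC", "b5", "b6", "b7", "b8", "B",
)

#: Elements belonging to the C-linker (the rest form the CNBD proper).
CLINKER_ELEMENTS: tuple[str, ...] = ("A'", "B'", "C'", "D'", "E'", "F'")


@dataclass
class ChannelSequence:
    """One candidate channel protein.

    ``residues`` is an ungapped string over the 20-letter amino-acid alphabet;
    ``X`` is permitted and treated as unknown.
    """

    id: str
    residues: str
    group: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - AA20 - {"X"}
        if bad:
            raise ValueError(
                f"{self.id}: invalid characters {sorted(bad)} (gaps are not allowed)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TMSegment:
    """A labelled transmembrane span with its mean hydropathy."""

    label: str
    start: int
    end: int
    mean_hydropathy: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span {self.label}: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatAnnotation:
    """Annotation of one 6TM(-CNBD) repeat within a sequence.

    ``segments`` maps S1..S6 to :class:`TMSegment`; S4 may be absent when no
    charge-periodic region was found. ``ploop`` spans the inter-segment region
    between S5 and S6 that carries the selectivity-filter motif.
    """

    index: int  # 1-based repeat index
    segments: dict[str, TMSegment]
    ploop: tuple[int, int] | None = None
    filter_start: int | None = None
    filter_motif: str = ""
    clinker: tuple[int, int] | None = None
    cnbd: tuple[int, int] | None = None
    flags: list[str] = field(default_factory=list)

    def span(self) -> tuple[int, int]:
        """Outer span from S1 start to the last annotated element end."""
        start = self.segments["S1"].start
        end = self.segments["S6"].end
        if self.cnbd is not None:
            end = max(end, self.cnbd[1])
        return start, end


@dataclass
class TopologyModel:
    """Per-sequence 6TM topology annotation (one entry per pore anchor)."""

    sequence_id: str
    repeats: list[RepeatAnnotation] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


@dataclass
class DeterminantProfile:
    """The four functional-determinant readouts for one repeat.

    ``rk_rich`` means the S4 span carries seven or more arginine/lysine
    residues; ``hcn_signature`` additionally requires serine/threonine at the
    homologous middle S4 position. ``linker_class`` is ``short`` for S4-S5
    linkers under ten residues, else ``long``.
    """

    sequence_id: str
    repeat: int
    filter_motif: str
    filter_class: str  # canonical | variant | non-canonical | absent
    s4_rk_count: int
    s4_middle_residue: str
    hcn_signature: bool
    rk_rich: bool
    linker_length: int
    linker_class: str  # short | long
    has_cnbd: bool = False
    cnbd_elements: dict[str, str] = field(default_factory=dict)
    group: str | None = None

    def __post_init__(self) -> None:
        if self.s4_rk_count < 0 or self.linker_length < 0:
            raise ValueError("negative count/length")
        expected = "short" if self.linker_length < 10 else "long"
        if self.linker_class != expected:
            raise ValueError(
                f"linker_class {self.linker_class!r} inconsistent with "
                f"length {self.linker_length}"
            )
        if self.rk_rich != (self.s4_rk_count >= 7):
            raise ValueError("rk_rich inconsistent with s4_rk_count")


@dataclass
class RepeatUnit:
    """One repeat cut out of a tandem channel, named 1x/2x + parent id."""

    parent_id: str
    repeat_index: int
    sequence: str
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.repeat_index < 1:
            raise ValueError("repeat_index must be >= 1")
        if not self.sequence:
            raise ValueError("empty repeat unit")

    @property
    def name(self) -> str:
        return f"{self.repeat_index}x{self.parent_id}"


@dataclass
class CNBDMap:
    """Per-repeat presence/absence map of C-linker + CNBD elements."""

    sequence_id: str
    repeat: int
    has_cnbd: bool
    identity: float  # alignment identity to the reference, in [0, 1]
    elements: dict[str, str] = field(default_factory=dict)  # name -> present|absent
    coverage: dict[str, float] = field(default_factory=dict)
    clinker_span: tuple[int, int] | None = None
    cnbd_span: tuple[int, int] | None = None
    flags: list[str] = field(default_factory=list)

    def absent_elements(self) -> list[str]:
        return [e for e in ELEMENT_ORDER if self.elements.get(e) == "absent"]
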