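"""Tandem-channel detection, repeat splitting (1x/2x naming), inter-repeat identity.

Two-repeat tandem channels carry two complete 6TM(-CNBD) blocks on one
polypeptide; for alignment and tree building each repeat is analysed as a
separate sequence named ``1x<id>`` / ``2x<id>``. The cut point is the midpoint
of the inter-repeat region, so the two units tile the parent exactly (the
inter-repeat linker residues are retained, half in each unit).
"""

from __future__ import annotations

from chanarch import align
from chanarch.types import ChannelSequence, RepeatUnit, TopologyModel


def detect_repeats(model: TopologyModel, min_tm_len: int = 15) -> int:
    """Validated repeat count for an annotated sequence.

    Two repeats require two pore anchors each with a full complement of
    upstream TM spans and non-overlapping outer spans; anything else counts as
    one repeat (or zero, when no valid repeat was annotated -- the model then
    carries an explanatory flag such as ``ambiguous_tandem``).
    """
    complete = [
        r for r in model.repeats
        if all(l in r.segments for l in ("S1", "S2", "S3", "S5", "S6"))
    ]
    if len(complete) >= 2:
        a, b = complete[0].span(), complete[1].span()
        if a[1] <= b[0]:
            return 2
    return 1 if complete else 0


def split_tandem(
    seq: ChannelSequence,
    model: TopologyModel,
    boundary_mode: str = "midpoint",
) -> list[RepeatUnit]:
    """Cut a two-repeat tandem channel into its 1x/2x repeat units.

    ``boundary_mode='midpoint'`` (default) places the cut at the midpoint of
    the inter-repeat region between the end of repeat 1's last annotated
    element (S6, or its CNBD when present) and repeat 2's S1;
    ``'end_of_repeat1'`` cuts directly after repeat 1's last element. Units
    partition the parent: no residue is lost or duplicated.
    """
    if detect_repeats(model) != 2:
        raise ValueError(f"{seq.id}: not a validated two-repeat tandem")
    r1, r2 = model.repeats[0], model.repeats[1]
    last1 = r1.segments["S6"].end
    if r1.cnbd is not None:
        last1 = max(last1, r1.cnbd[1])
    first2 = r2.segments["S1"].start
    if boundary_mode == "midpoint":
        boundary = (last1 + first2) // 2
    elif boundary_mode == "end_of_repeat1":
        boundary = last1
    else:
        raise ValueError(f"unknown boundary_mode {boundary_mode!r}")
    n = len(seq.residues)
    return [
        RepeatUnit(seq.id, 1, seq.residues[:boundary], (0, boundary)),
        RepeatUnit(seq.id, 2, seq.residues[boundary:], (boundary, n)),
    ]


def repeat_identity(unit1: RepeatUnit, unit2: RepeatUnit) -> float:
    """Percent identity between two repeat units.

    Global Needleman-Wunsch alignment, BLOSUM62, gap open 10 / extend 0.5;
    identity = matches / alignment columns x 100 (gap columns count in the
    denominator).
    """
    return align.percent_identity(unit1.sequence, unit2.sequence)


def units_to_fasta(units: list[RepeatUnit], path) -> None:
    """Write repeat units as FASTA, preserving the parent id in the description."""
    with open(path, "w") as fh:
        for u in units:
            fh.write(f">{u.name} parent={u.parent_id} span={u.span[0]}-{u.span[1]}\n")
            for j in range(0, len(u.sequence), 60):
                fh.write(u.sequence[j : j + 60] + "\n")
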