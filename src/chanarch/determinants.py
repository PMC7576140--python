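"""The four functional-determinant readouts, per repeat, and group summaries.

Determinants: (1) selectivity-filter motif class; (2) S4 voltage-sensor charge
content -- the count of arginine/lysine residues in the S4 span, with a channel
called R/K-rich at seven or more, and the HCN-style signature when the
homologous middle S4 position carries serine/threonine; (3) S4-S5 linker
length with the short/long dichotomy at ten residues; (4) C-linker/CNBD
element composition (delegated to :mod:`chanarch.cnbd`).

Histidine is never counted as a positive residue: only R and K contribute.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

from chanarch import align
from chanarch.types import ChannelSequence, CNBDMap, DeterminantProfile, TopologyModel

RK_RICH_THRESHOLD = 7      # "seven and more" R/K residues
SHORT_LINKER_MAX = 10      # linkers under ten residues are short

#: Synthetic HCN-style S4 reference: 21 residues, charges on the three-residue
#: register, serine at the middle register position (index 10). Stands in for a
#: database S4 sequence; generated, not extracted.
S4_REFERENCE = "LRILRVFKLISLFRILKVLRI"
S4_REFERENCE_MIDDLE = 10

_CANONICAL = {"TVGYG", "TVGFG"}
_VARIANT_RE = re.compile(r"[TSC][ACDEFGHIKLMNPQRSTVWY]G[YF]G$")


def classify_filter(motif: str) -> str:
    """Classify a recovered pore motif.

    ``canonical`` for the consensus TVGY/FG itself; ``variant`` for consensus
    -pattern motifs with substitutions (e.g. serine or cysteine for the
    threonine); ``non-canonical`` for any other recovered motif (e.g. the
    TIGE filter of metazoan CNG channels); ``absent`` for an empty motif.
    """
    if not motif:
        return "absent"
    if len(motif) not in (4, 5):
        raise ValueError(f"motif must have length 4 or 5, got {motif!r}")
    if motif in _CANONICAL:
        return "canonical"
    if _VARIANT_RE.match(motif):
        return "variant"
    return "non-canonical"


def profile_s4(
    model: TopologyModel, seq: ChannelSequence, repeat: int = 1
) -> tuple[int, str, bool, bool]:
    """S4 charge statistics for one repeat.

    Returns ``(rk_count, middle_residue, hcn_signature, rk_rich)``. The middle
    residue is read from the column of a global alignment of the S4 span to
    the built-in S4 reference that pairs with the reference's middle S/T
    position; ``-`` denotes a gap at that column.
    """
    rep = next((r for r in model.repeats if r.index == repeat), None)
    if rep is None or "S4" not in rep.segments:
        raise ValueError(f"{seq.id}: repeat {repeat} has no S4 span")
    s4 = rep.segments["S4"]
    span = seq.residues[s4.start : s4.end]
    count = sum(1 for a in span if a in "RK")
    aln = align.global_align(S4_REFERENCE, span, terminal_penalty=True)
    middle = "-"
    for i, j in align.trace_pairs(aln):
        if i == S4_REFERENCE_MIDDLE:
            middle = span[j] if j >= 0 else "-"
            break
    rich = count >= RK_RICH_THRESHOLD
    signature = rich and middle in ("S", "T")
    return count, middle, signature, rich


def linker_length(model: TopologyModel, repeat: int = 1) -> tuple[int, str]:
    """S4-S5 linker length = start(S5) - end(S4); short iff under ten."""
    rep = next((r for r in model.repeats if r.index == repeat), None)
    if rep is None:
        raise ValueError(f"repeat {repeat} not annotated")
    for label in ("S4", "S5"):
        if label not in rep.segments:
            raise ValueError(f"repeat {repeat} has no {label} span")
    s4, s5 = rep.segments["S4"], rep.segments["S5"]
    if s4.end > s5.start:
        raise ValueError(
            f"annotation inconsistency: S4 [{s4.start},{s4.end}) overlaps "
            f"S5 [{s5.start},{s5.end})"
        )
    length = s5.start - s4.end
    return length, ("short" if length < SHORT_LINKER_MAX else "long")


def build_profile(
    seq: ChannelSequence,
    model: TopologyModel,
    repeat: int = 1,
    cnbd_map: CNBDMap | None = None,
) -> DeterminantProfile:
    """Assemble the full determinant profile for one repeat."""
    rep = next(r for r in model.repeats if r.index == repeat)
    count, middle, signature, rich = profile_s4(model, seq, repeat)
    length, lclass = linker_length(model, repeat)
    return DeterminantProfile(
        sequence_id=seq.id,
        repeat=repeat,
        filter_motif=rep.filter_motif,
        filter_class=classify_filter(rep.filter_motif),
        s4_rk_count=count,
        s4_middle_residue=middle,
        hcn_signature=signature,
        rk_rich=rich,
        linker_length=length,
        linker_class=lclass,
        has_cnbd=cnbd_map.has_cnbd if cnbd_map else False,
        cnbd_elements=dict(cnbd_map.elements) if cnbd_map else {},
        group=seq.group,
    )


def summarize_linkers(
    profiles: list[DeterminantProfile], group_by: str = "group"
) -> pd.DataFrame:
    """Per-group linker-length statistics: n, mean, sample SD (n-1).

    A group with a single profile reports SD 0 with a ``single_observation``
    warning flag rather than NaN.
    """
    if not profiles:
        raise ValueError("empty profile list")
    df = pd.DataFrame(
        {
            "group": [getattr(p, group_by) if group_by != "group" else p.group
                      for p in profiles],
            "linker_length": [p.linker_length for p in profiles],
        }
    )
    rows = []
    for g, sub in df.groupby("group", dropna=False):
        vals = sub["linker_length"].to_numpy(float)
        flag = ""
        if len(vals) == 1:
            sd = 0.0
            flag = "single_observation"
            warnings.warn(f"group {g!r}: single observation, SD reported as 0",
                          stacklevel=2)
        else:
            sd = float(np.std(vals, ddof=1))
        rows.append(dict(group=g, n=len(vals), mean=float(np.mean(vals)),
                         sd=sd, flag=flag))
    return pd.DataFrame(rows)


def profiles_to_frame(profiles: list[DeterminantProfile]) -> pd.DataFrame:
    """Flatten profiles to a TSV-ready table (one row per repeat)."""
    rows = []
    for p in profiles:
        rows.append({
            "id": p.sequence_id, "repeat": p.repeat, "group": p.group,
            "filter_motif": p.filter_motif, "filter_class": p.filter_class,
            "s4_rk_count": p.s4_rk_count, "s4_middle": p.s4_middle_residue,
            "hcn_signature": p.hcn_signature, "rk_rich": p.rk_rich,
            "linker_length": p.linker_length, "linker_class": p.linker_class,
            "has_cnbd": p.has_cnbd,
            "absent_elements": ",".join(
                e for e, v in p.cnbd_elements.items() if v == "absent"),
        })
    return pd.DataFrame(rows)
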