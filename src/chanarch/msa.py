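"""Alignment I/O and automated curation (column filtering, domain stripping).

The curation steps reproduce, with explicit thresholds, what is usually done
by hand before tree inference on divergent channel alignments: drop
non-conservative columns (too gappy or too variable) and, for datasets mixing
Kv-like with CNBD-channels, strip the non-conservative N-/C-terminal domains
-- including C-linkers and CNBDs -- entirely, keeping only the S1-S6 core.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from chanarch.types import TopologyModel

GAP = "-"


@dataclass
class Alignment:
    """An aligned FASTA in memory: ordered (id, row) pairs of equal length."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            dup = [i for i, c in Counter(self.ids).items() if c > 1]
            raise ValueError(f"duplicate record ids: {dup}")
        if self.rows:
            n = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != n:
                    raise ValueError(
                        f"ragged alignment: record {rid!r} has length "
                        f"{len(row)}, expected {n}"
                    )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA; '.' gaps are normalised to '-'."""
    ids: list[str] = []
    rows: list[str] = []
    with open(path) as fh:
        cur: list[str] = []
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if ids:
                    rows.append("".join(cur))
                ids.append(line[1:].split()[0])
                cur = []
            elif line:
                cur.append(line.replace(".", GAP))
        if ids:
            rows.append("".join(cur))
    return Alignment(ids, rows)


def write_alignment(aln: Alignment, path, header: str | None = None) -> None:
    """Write aligned FASTA (60-column wrap); optional provenance header comment."""
    with open(path, "w") as fh:
        if header:
            fh.write(f";{header}\n")
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n")
            for j in range(0, len(row), 60):
                fh.write(row[j : j + 60] + "\n")


def remove_nonconservative_columns(
    aln: Alignment, max_gap_frac: float = 0.75, min_identity: float = 0.0
) -> tuple[Alignment, list[int]]:
    """Keep columns that are both gap-sparse and conserved enough.

    A column is retained iff its gap fraction is <= ``max_gap_frac`` AND the
    frequency of its most common residue (gaps excluded) is >= ``min_identity``.
    Returns the filtered alignment and the original indices of retained
    columns (strictly increasing). Row order is unchanged; the operation is
    idempotent at fixed thresholds.
    """
    if not (0 <= max_gap_frac <= 1) or not (0 <= min_identity <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if aln.n_rows == 0 or aln.n_cols == 0:
        raise ValueError("empty alignment")
    mat = np.array([list(r) for r in aln.rows])
    keep: list[int] = []
    for c in range(aln.n_cols):
        col = mat[:, c]
        gaps = np.sum(col == GAP)
        if gaps / len(col) > max_gap_frac:
            continue
        residues = col[col != GAP]
        if len(residues) == 0:
            continue
        top = Counter(residues.tolist()).most_common(1)[0][1]
        if top / len(residues) < min_identity:
            continue
        keep.append(c)
    rows = ["".join(r[c] for c in keep) for r in aln.rows]
    return Alignment(list(aln.ids), rows), keep


def strip_terminal_domains(
    aln: Alignment,
    annotations: dict[str, TopologyModel],
    mixed: bool = False,
) -> Alignment:
    """Drop columns outside the S1-S6 core of the annotated sequences.

    A column is removed when, for at least half of its non-gap rows, the
    residue falls outside the union of annotated repeat spans (S1 start to S6
    end, per repeat). With ``mixed=True`` (datasets mixing Kv-like and
    CNBD-channels) any column containing a residue from an annotated
    C-linker/CNBD span is removed unconditionally.
    """
    for rid in aln.ids:
        if rid not in annotations:
            raise ValueError(f"unannotated alignment row: {rid!r}")

    core: dict[str, list[tuple[int, int]]] = {}
    cterm: dict[str, list[tuple[int, int]]] = {}
    for rid in aln.ids:
        model = annotations[rid]
        core[rid] = [
            (r.segments["S1"].start, r.segments["S6"].end)
            for r in model.repeats
            if "S1" in r.segments and "S6" in r.segments
        ]
        spans = []
        for r in model.repeats:
            if r.clinker is not None:
                spans.append(r.clinker)
            if r.cnbd is not None:
                spans.append(r.cnbd)
        cterm[rid] = spans

    # residue index in the ungapped sequence, per (row, column)
    mats = {
        rid: (np.frombuffer(row.encode(), dtype="S1") != GAP.encode())
        for rid, row in zip(aln.ids, aln.rows)
    }
    pos_of = {rid: np.cumsum(m) - 1 for rid, m in mats.items()}

    keep: list[int] = []
    for c in range(aln.n_cols):
        outside = 0
        nongap = 0
        in_cterm = False
        for rid in aln.ids:
            if not mats[rid][c]:
                continue
            nongap += 1
            pos = int(pos_of[rid][c])
            if not any(s <= pos < e for s, e in core[rid]):
                outside += 1
            if any(s <= pos < e for s, e in cterm[rid]):
                in_cterm = True
        if mixed and in_cterm:
            continue
        if nongap > 0 and outside * 2 >= nongap:
            continue
        keep.append(c)
    rows = ["".join(r[c] for c in keep) for r in aln.rows]
    return Alignment(list(aln.ids), rows)
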