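"""6TM topology annotation by hydropathy segmentation anchored on the pore motif.

The annotation strategy mirrors how channel pore subunits are organised: the
selectivity-filter motif (consensus TVGY/FG) sits in the P-loop between S5 and
S6, so every motif occurrence that is flanked by transmembrane spans acts as a
"pore anchor" defining one 6TM repeat. S1-S3 and S5-S6 are hydrophobic and are
found on a smoothed Kyte-Doolittle profile; S4 is amphipathic (arginine/lysine
at roughly three-residue spacing) and is located by charge periodicity instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KD_SCALE

from chanarch.types import ChannelSequence, RepeatAnnotation, TMSegment, TopologyModel

# Strict amino-acid alphabet for the motif wildcard position: X never matches,
# so sequences with unknown residues at a motif position are flagged for review
# downstream rather than silently classified.
_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Consensus selectivity-filter pattern (T/S/C, any residue, G, Y/F, G).
FILTER_PATTERN_5 = re.compile(rf"(?=[TSC][{_AA}]G[YF]G)")
#: Degenerate 4-residue fallback for filters of the TIGE kind.
FILTER_PATTERN_4 = re.compile(rf"(?=[TSC][{_AA}]G[ED])")


@dataclass
class TopologyParams:
    """Tunable thresholds for TM detection (standard single-sequence heuristics)."""

    window: int = 19          # hydropathy smoothing window (odd)
    threshold: float = 1.6    # smoothed-score cutoff for TM candidacy
    min_tm_len: int = 15
    max_tm_len: int = 30
    merge_gap: int = 3        # runs separated by < merge_gap sub-threshold positions merge
    refine_cutoff: float = 1.0  # raw per-residue KD cutoff for boundary refinement
    s4_length: int = 21       # canonical TM-like length used to extend the S4 window
    max_anchor_gap: int = 60  # max distance between pore anchor and flanking S5/S6


DEFAULT_PARAMS = TopologyParams()


def hydropathy_profile(seq: ChannelSequence | str, window: int = 19) -> np.ndarray:
    """Mean Kyte-Doolittle hydropathy over a centred window.

    Positions within ``window // 2`` of either terminus use the truncated
    window. ``X`` contributes 0. Raises ``ValueError`` for sequences shorter
    than the window or even/too-small windows.
    """
    residues = seq.residues if isinstance(seq, ChannelSequence) else seq
    if window < 5 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 5, got {window}")
    n = len(residues)
    if n < window:
        raise ValueError(f"sequence length {n} shorter than window {window}")
    raw = np.array([KD_SCALE.get(a, 0.0) for a in residues])
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def detect_tm_segments(
    scores: np.ndarray,
    threshold: float = 1.6,
    min_len: int = 15,
    max_len: int = 30,
    merge_gap: int = 3,
) -> list[tuple[int, int]]:
    """Candidate TM spans: maximal supra-threshold runs, merged across short dips.

    Runs separated by fewer than ``merge_gap`` sub-threshold positions are
    merged. Because window smoothing erodes run edges by up to half the
    window, short supra-threshold cores (at least ``core_min`` positions) are
    expanded to the best-scoring ``min_len`` window around them; cores shorter
    than ``core_min`` are dropped as noise, and runs longer than ``max_len``
    are trimmed to their best-scoring ``max_len`` window. Returned sorted by
    start. An empty list is a valid result.
    """
    core_min = 5
    above = scores >= threshold
    runs: list[list[int]] = []
    i = 0
    n = len(scores)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    csum_all = np.concatenate([[0.0], np.cumsum(scores)])
    out: list[tuple[int, int]] = []
    for start, end in merged:
        if end - start < core_min:
            continue
        if end - start < min_len:
            # best min_len window containing the core
            lo = max(0, end - min_len)
            hi = min(n - min_len, start)
            if lo > hi:
                continue
            sums = csum_all[lo + min_len : hi + min_len + 1] - csum_all[lo : hi + 1]
            best = lo + int(np.argmax(sums))
            start, end = best, best + min_len
        if end - start > max_len:
            # keep the max_len sub-window with the highest summed score
            csum = np.concatenate([[0.0], np.cumsum(scores[start:end])])
            sums = csum[max_len:] - csum[:-max_len]
            best = int(np.argmax(sums))
            start, end = start + best, start + best + max_len
        out.append((start, end))
    return sorted(out)


def find_filter_motifs(seq: ChannelSequence | str) -> list[tuple[int, str]]:
    """All selectivity-filter motif matches, sorted by start.

    Reports 5-residue consensus-family hits (TVGY/FG pattern) and 4-residue
    degenerate hits (TIGE-like); overlapping matches are all reported. When
    both patterns fire at the same position the 5-residue motif is kept.
    """
    residues = seq.residues if isinstance(seq, ChannelSequence) else seq
    hits: dict[int, str] = {}
    for m in FILTER_PATTERN_4.finditer(residues):
        hits[m.start()] = residues[m.start() : m.start() + 4]
    for m in FILTER_PATTERN_5.finditer(residues):
        hits[m.start()] = residues[m.start() : m.start() + 5]
    return sorted(hits.items())


def _refine_span(raw: np.ndarray, start: int, end: int, cutoff: float,
                 max_len: int) -> tuple[int, int]:
    """Snap a smoothed-profile span to raw per-residue hydropathy boundaries.

    Window smoothing pulls run edges inward by up to half the crossing width;
    extending while flanking residues stay above ``cutoff`` (and shrinking
    while edge residues fall below it) recovers residue-level boundaries.
    """
    n = len(raw)
    while start > 0 and raw[start - 1] >= cutoff and end - start < max_len:
        start -= 1
    while end < n and raw[end] >= cutoff and end - start < max_len:
        end += 1
    while start < end - 1 and raw[start] < cutoff:
        start += 1
    while end > start + 1 and raw[end - 1] < cutoff:
        end -= 1
    return start, end


def locate_s4(residues: str, region_start: int, region_end: int,
              s4_length: int = 21,
              clip_end: int | None = None) -> tuple[int, int] | None:
    """Charge-periodic S4 window within [region_start, region_end).

    Finds the densest chain of R/K positions at (multiples of) three-residue
    spacing and extends it to a TM-like length, starting one residue before
    the first charge of the chain. Returns None when the region carries no
    basic residues. ``clip_end`` bounds the window's right edge independently
    of the charge-scan region (the window may extend past ``region_end`` up
    to ``clip_end`` when the downstream hydropathy boundary is unreliable).
    """
    pos = [i for i in range(region_start, region_end) if residues[i] in "RK"]
    if not pos:
        return None
    # best chain under spacing {3, 6} (6 tolerates one skipped register slot)
    best_chain: list[int] = []
    for k, p in enumerate(pos):
        chain = [p]
        last = p
        for q in pos[k + 1 :]:
            if q - last in (3, 6):
                chain.append(q)
                last = q
        if len(chain) > len(best_chain):
            best_chain = chain
    first = min(best_chain[0], pos[0])
    start = max(region_start, first - 1)
    end = min(clip_end if clip_end is not None else region_end,
              start + s4_length)
    if end - start < 4:
        return None
    return start, end


def assign_6tm(
    seq: ChannelSequence,
    params: TopologyParams = DEFAULT_PARAMS,
) -> TopologyModel:
    """Annotate all 6TM repeats of a candidate sequence.

    One repeat is emitted per valid pore anchor (a filter motif flanked by a TM
    span ending before it and one starting after it, with at least three
    further TM spans upstream). Sequences with no anchor, or anchors without
    enough flanking structure, are flagged rather than silently dropped.
    """
    model = TopologyModel(sequence_id=seq.id)
    raw = np.array([KD_SCALE.get(a, 0.0) for a in seq.residues])
    try:
        scores = hydropathy_profile(seq, params.window)
    except ValueError:
        model.flags.append("sequence_too_short")
        return model
    spans = detect_tm_segments(
        scores, params.threshold, params.min_tm_len, params.max_tm_len,
        params.merge_gap,
    )
    spans = [
        _refine_span(raw, s, e, params.refine_cutoff, params.max_tm_len)
        for s, e in spans
    ]
    motifs = find_filter_motifs(seq)

    if not motifs and not spans:
        model.flags.append("not_a_channel")
        return model
    if not motifs:
        model.flags.append("no_pore_anchor")
        return model

    # group motifs by the inter-span region they fall in; leftmost wins
    boundaries = [e for _, e in spans]
    anchors: list[tuple[int, str]] = []
    seen_regions: set[int] = set()
    for start, motif in motifs:
        region = sum(1 for b in boundaries if b <= start)
        if region in seen_regions:
            model.flags.append("ambiguous_tandem")
            continue
        seen_regions.add(region)
        anchors.append((start, motif))

    consumed = [False] * len(spans)
    cursor = 0
    for a_start, motif in anchors:
        a_end = a_start + len(motif)
        s5_i = s6_i = None
        for i, (s, e) in enumerate(spans):
            if consumed[i] or s < cursor:
                continue
            if e <= a_start and a_start - e <= params.max_anchor_gap:
                s5_i = i  # keep latest qualifying span: nearest before the motif
            if s >= a_end and s6_i is None and s - a_end <= params.max_anchor_gap:
                s6_i = i
        if s5_i is None or s6_i is None:
            model.flags.append(f"incomplete_repeat_at_{a_start}")
            continue
        # S4 first: it is amphipathic, so it is found by charge periodicity in
        # the region before S5 and masked out of the S1-S3 hydropathy pool
        # (its hydrophobic face can otherwise masquerade as a TM span).
        s4 = locate_s4(seq.residues, cursor, spans[s5_i][0], params.s4_length,
                       clip_end=a_start)
        if s4 is not None and s4[1] > spans[s5_i][0]:
            # merged S4/S5 hydropathy run (short linker, uncharged S4 tail):
            # the charge-anchored S4 window is the reliable boundary, so move
            # S5's start past it and past the polar linker residues
            new_start = s4[1]
            limit = spans[s5_i][1] - params.min_tm_len
            while new_start < limit and raw[new_start] < params.refine_cutoff:
                new_start += 1
            spans[s5_i] = (new_start, spans[s5_i][1])
        preceding = [
            i for i, (s, e) in enumerate(spans)
            if not consumed[i] and s >= cursor and e <= spans[s5_i][0]
            and i != s5_i
            and (s4 is None or e <= s4[0] or s >= s4[1])
        ]
        if len(preceding) < 3:
            model.flags.append(f"incomplete_repeat_at_{a_start}")
            continue
        span_score = lambda i: float(np.mean(scores[spans[i][0] : spans[i][1]]))
        s123 = sorted(sorted(preceding, key=span_score, reverse=True)[:3])

        segments: dict[str, TMSegment] = {}
        for label, i in zip(("S1", "S2", "S3"), s123):
            s, e = spans[i]
            segments[label] = TMSegment(label, s, e, span_score(i))
        s, e = spans[s5_i]
        segments["S5"] = TMSegment("S5", s, e, span_score(s5_i))
        s, e = spans[s6_i]
        segments["S6"] = TMSegment("S6", s, e, span_score(s6_i))

        rep = RepeatAnnotation(
            index=len(model.repeats) + 1,
            segments=segments,
            ploop=(segments["S5"].end, segments["S6"].start),
            filter_start=a_start,
            filter_motif=motif,
        )
        if s4 is not None and s4[0] < segments["S3"].end:
            # charge chain strayed before S3 (charges in an upstream loop):
            # re-locate strictly between S3 and S5
            s4 = locate_s4(
                seq.residues, segments["S3"].end, segments["S5"].start,
                params.s4_length,
            )
        if s4 is not None:
            segments["S4"] = TMSegment(
                "S4", s4[0], s4[1], float(np.mean(raw[s4[0] : s4[1]]))
            )
        else:
            rep.flags.append("no_s4")
        model.repeats.append(rep)
        for i in range(len(spans)):
            if spans[i][0] >= cursor and spans[i][1] <= spans[s6_i][1]:
                consumed[i] = True
        cursor = spans[s6_i][1]

    if not model.repeats:
        model.flags.append("no_valid_repeat")
    return model


def annotate_fasta(records: list[ChannelSequence],
                   params: TopologyParams = DEFAULT_PARAMS) -> list[TopologyModel]:
    """Annotate a list of sequences; convenience wrapper for the CLI/pipeline."""
    return [assign_6tm(r, params) for r in records]


def model_to_rows(model: TopologyModel) -> list[dict]:
    """Flatten a model to TSV-ready rows (id, repeat, label, start, end)."""
    rows = []
    for rep in model.repeats:
        for label in ("S1", "S2", "S3", "S4", "S5", "S6"):
            if label in rep.segments:
                seg = rep.segments[label]
                rows.append(
                    dict(id=model.sequence_id, repeat=rep.index, label=label,
                         start=seg.start, end=seg.end)
                )
        if rep.ploop:
            rows.append(dict(id=model.sequence_id, repeat=rep.index, label="Ploop",
                             start=rep.ploop[0], end=rep.ploop[1]))
    return rows
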