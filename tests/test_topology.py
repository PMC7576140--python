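import numpy as np
import pytest
from Bio.SeqUtils.ProtParamData import kd

from chanarch import topology as topo
from chanarch.types import ChannelSequence


def _manual_profile(residues: str, window: int) -> np.ndarray:
    """Independent oracle: mean KD over the window centred on each position."""
    n = len(residues)
    half = window // 2
    vals = [kd.get(a, 0.0) for a in residues]
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = float(np.mean(vals[lo:hi]))
    return out


def test_hydropathy_profile_matches_windowed_mean_oracle():
    seq = "MKTIILVVFFAAGGLLNNQQDDEEPPHHSSTTIILLVVFF"
    got = topo.hydropathy_profile(seq, window=19)
    want = _manual_profile(seq, 19)
    assert got.shape == want.shape
    np.testing.assert_allclose(got, want, atol=1e-9)


def test_hydropathy_profile_accepts_channel_sequence():
    cs = ChannelSequence("a", "ILVFILVFILVFILVFILVFILVF")
    np.testing.assert_allclose(topo.hydropathy_profile(cs),
                               topo.hydropathy_profile(cs.residues))
    with pytest.raises(ValueError):
        topo.hydropathy_profile("ILVF")  # shorter than the window
    with pytest.raises(ValueError):
        topo.hydropathy_profile(cs, window=18)  # even window


def test_detect_tm_segments_on_synthetic_block():
    # one clean hydrophobic block inside polar flanks
    seq = "N" * 30 + "I" * 21 + "N" * 30
    scores = topo.hydropathy_profile(seq)
    spans = topo.detect_tm_segments(scores)
    assert len(spans) == 1
    s, e = spans[0]
    assert 15 <= e - s <= 30
    # span centred on the hydrophobic block
    assert s >= 20 and e <= 62


def test_detect_tm_segments_none_on_polar_sequence():
    scores = topo.hydropathy_profile("N" * 80)
    assert topo.detect_tm_segments(scores) == []


def test_find_filter_motifs_five_and_four_letter():
    hits = topo.find_filter_motifs("AAATVGYGAAA")
    assert hits == [(3, "TVGYG")]
    # four-letter fallback (TIGE-style)
    hits4 = topo.find_filter_motifs("AAATIGEAAA")
    assert hits4 == [(3, "TIGE")]


def test_find_filter_motifs_x_never_matches():
    assert topo.find_filter_motifs("AAATXGYGAAA") == []
    assert topo.find_filter_motifs("AAAXVGYGAAA") == []


def test_assign_6tm_recovers_default_channel(default_channel):
    _, seq, truth = default_channel
    model = topo.assign_6tm(seq)
    assert model.n_repeats == 1
    assert not model.flags
    rep = model.repeats[0]
    for label in ("S1", "S2", "S3", "S4", "S5", "S6"):
        t = truth.segment(1, label)
        got = rep.segments[label]
        assert abs(got.start - t.start) <= 2, label
        assert abs(got.end - t.end) <= 2, label
    assert rep.filter_motif == "TVGYG"


def test_assign_6tm_tandem_two_repeats(tandem_channel):
    _, seq, truth = tandem_channel
    model = topo.assign_6tm(seq)
    assert model.n_repeats == 2
    for r, t_rep in ((model.repeats[0], 1), (model.repeats[1], 2)):
        for label in ("S1", "S2", "S3", "S4", "S5", "S6"):
            t = truth.segment(t_rep, label)
            got = r.segments[label]
            assert abs(got.start - t.start) <= 2
            assert abs(got.end - t.end) <= 2


def test_assign_6tm_segments_ordered_nonoverlapping(small_cohort):
    for _, _, _, model in small_cohort.values():
        for rep in model.repeats:
            spans = sorted(
                (s.start, s.end) for s in rep.segments.values()
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2
            if rep.ploop and "S5" in rep.segments and "S6" in rep.segments:
                assert rep.segments["S5"].end <= rep.ploop[0]
                assert rep.ploop[1] <= rep.segments["S6"].start


def test_assign_6tm_flags_non_channel():
    model = topo.assign_6tm(ChannelSequence("junk", "NQDEPHST" * 20))
    assert model.n_repeats == 0
    assert "not_a_channel" in model.flags or "no_pore_anchor" in model.flags


def test_model_to_rows_roundtrip(default_channel):
    _, seq, _ = default_channel
    model = topo.assign_6tm(seq)
    rows = topo.model_to_rows(model)
    labels = {r["label"] for r in rows}
    assert {"S1", "S2", "S3", "S4", "S5", "S6"} <= labels
    for r in rows:
        assert r["id"] == seq.id
        assert 0 <= r["start"] < r["end"] <= len(seq.residues)
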