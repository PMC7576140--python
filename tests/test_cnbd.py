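import random

import pytest

from chanarch import cnbd as cnbd_mod
from chanarch import determinants as det
from chanarch import synthetic as syn
from chanarch import topology as topo
from chanarch.types import ChannelSequence, ELEMENT_ORDER


def test_reference_carries_all_17_elements_in_order():
    ref = cnbd_mod.load_reference()
    # element column blocks appear in the canonical order
    firsts = [min(ref.element_cols[e]) for e in ELEMENT_ORDER]
    assert firsts == sorted(firsts)
    for e in ELEMENT_ORDER:
        assert ref.element_cols[e]
    # C-linker block precedes the CNBD block
    assert ref.clinker_cols[0] < ref.cnbd_cols[0]


def test_intact_channel_all_elements_present(cnbd_channel):
    _, seq, _ = cnbd_channel
    model = topo.assign_6tm(seq)
    cm = cnbd_mod.detect_cnbd(seq, model)
    assert cm.has_cnbd
    assert cm.absent_elements() == []
    assert cm.clinker_span is not None and cm.cnbd_span is not None
    assert cm.clinker_span[0] >= model.repeats[0].segments["S6"].end


def test_kv_channel_has_no_cnbd(default_channel):
    _, seq, _ = default_channel
    model = topo.assign_6tm(seq)
    cm = cnbd_mod.detect_cnbd(seq, model)
    assert not cm.has_cnbd
    assert all(v == "absent" for v in cm.elements.values())


def test_single_element_deletion_recovered():
    spec = syn.SynthChannelSpec(id="d1", has_cnbd=[True],
                                deleted_elements=[["b7"]], seed=31)
    seq, _ = syn.generate_channel(spec)
    model = topo.assign_6tm(seq)
    cm = cnbd_mod.detect_cnbd(seq, model)
    assert cm.has_cnbd
    assert cm.absent_elements() == ["b7"]


def test_heavy_deletion_recovered():
    deleted = ["C'", "D'", "E'", "F'", "b5", "b6", "b7", "b8", "PBC", "B"]
    spec = syn.SynthChannelSpec(id="d10", has_cnbd=[True],
                                deleted_elements=[deleted], seed=37)
    seq, _ = syn.generate_channel(spec)
    model = topo.assign_6tm(seq)
    cm = cnbd_mod.detect_cnbd(seq, model)
    assert cm.has_cnbd  # reduced, not absent
    assert set(cm.absent_elements()) == set(deleted)


def test_shuffled_region_rejected():
    spec = syn.SynthChannelSpec(id="s", has_cnbd=[True], seed=41)
    seq, _ = syn.generate_channel(spec)
    model = topo.assign_6tm(seq)
    rs = model.repeats[0].segments["S6"].end
    rng = random.Random(0)
    rejected = 0
    for _ in range(20):
        tail = list(seq.residues[rs:])
        rng.shuffle(tail)
        shuffled = ChannelSequence(seq.id, seq.residues[:rs] + "".join(tail))
        if not cnbd_mod.detect_cnbd(shuffled, model).has_cnbd:
            rejected += 1
    assert rejected >= 19


def test_short_region_has_no_cnbd(default_channel):
    # Kv-like channel truncated right after S6
    _, seq, _ = default_channel
    model = topo.assign_6tm(seq)
    end = model.repeats[0].segments["S6"].end
    trunc = ChannelSequence(seq.id, seq.residues[: end + 3])
    cm = cnbd_mod.detect_cnbd(trunc, model)
    assert not cm.has_cnbd


def test_detect_cnbd_requires_s6():
    from chanarch.types import TopologyModel
    with pytest.raises(ValueError):
        cnbd_mod.detect_cnbd(ChannelSequence("x", "ACDEF" * 20),
                             TopologyModel("x"))


def _profile(seq, model, repeat=1):
    cm = cnbd_mod.detect_cnbd(seq, model, repeat)
    return det.build_profile(seq, model, repeat, cm)


def test_classify_group_kv_vs_cnbd(default_channel, cnbd_channel):
    _, kv_seq, _ = default_channel
    _, cn_seq, _ = cnbd_channel
    kv_model = topo.assign_6tm(kv_seq)
    cn_model = topo.assign_6tm(cn_seq)
    assert cnbd_mod.classify_group(_profile(kv_seq, kv_model))[0] == "Kv-like"
    assert cnbd_mod.classify_group(_profile(cn_seq, cn_model))[0] == "CNBD-channel"


def test_classify_group_reduced_flag():
    spec = syn.SynthChannelSpec(id="r", has_cnbd=[True],
                                deleted_elements=[["b7"]], seed=31)
    seq, _ = syn.generate_channel(spec)
    model = topo.assign_6tm(seq)
    group, flags = cnbd_mod.classify_group(_profile(seq, model))
    assert group == "CNBD-channel"
    assert "reduced CNBD" in flags
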