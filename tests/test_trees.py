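import itertools

import pytest

from chanarch import synthetic as syn
from chanarch import trees as tr


NWK = "((A:1,B:1)95/0.97:1,(C:1,D:1)80/0.9:1,E:1);"


def test_parse_newick_tips_and_dual_supports():
    t = tr.parse_newick(NWK)
    assert sorted(t.tips) == ["A", "B", "C", "D", "E"]
    assert t.supports[frozenset({"A", "B"})] == (95.0, 0.97)
    assert t.supports[frozenset({"C", "D"})] == (80.0, 0.9)
    assert t.support_scale == "mixed"


def test_support_scale_detection():
    assert tr.parse_newick("((A:1,B:1)98:1,(C:1,D:1)77:1);").support_scale \
        == "bootstrap"
    assert tr.parse_newick("((A:1,B:1)0.98:1,(C:1,D:1)0.77:1);").support_scale \
        == "posterior"
    assert tr.parse_newick("((A:1,B:1):1,(C:1,D:1):1);").support_scale == "none"


def test_parse_newick_rejects_malformed_and_duplicates():
    with pytest.raises(ValueError):
        tr.parse_newick("((A,B)")
    with pytest.raises(ValueError):
        tr.parse_newick("((A:1,A:1):1,B:1);")


def test_write_newick_roundtrip():
    t = tr.parse_newick(NWK)
    again = tr.parse_newick(tr.write_newick(t))
    assert tr.rf_distance(t, again) == (0, 0.0)


def test_monophyly_unrooted_side_and_complement():
    t = tr.parse_newick(NWK)
    assert tr.is_monophyletic(t, {"A", "B"}).is_monophyletic
    # complement of a bipartition side is monophyletic under unrooted semantics
    assert tr.is_monophyletic(t, {"C", "D", "E"}).is_monophyletic
    rep = tr.is_monophyletic(t, {"A", "C"})
    assert not rep.is_monophyletic
    assert rep.intruders


def test_monophyly_support_lookup():
    t = tr.parse_newick(NWK)
    assert tr.is_monophyletic(t, {"A", "B"}).support == (95.0, 0.97)


def test_monophyly_validation():
    t = tr.parse_newick(NWK)
    with pytest.raises(ValueError):
        tr.is_monophyletic(t, {"A", "Z"})
    with pytest.raises(ValueError):
        tr.is_monophyletic(t, {"A"})


def _brute_force_mono(ptree, tipset):
    """Oracle: a tip set is monophyletic iff it is a side of some bipartition
    or a side of the trivial splits implied by the tree's branches."""
    tipset = frozenset(tipset)
    all_tips = frozenset(ptree.tips)
    sides = set()
    for bp in tr.bipartitions(ptree):
        sides.update(bp)
    # trivial splits (single tip vs rest) can't make a >=2 tipset monophyletic
    # except the complement of one tip
    for tip in ptree.tips:
        sides.add(all_tips - {tip})
    sides.add(all_tips)
    return tipset in sides


def test_monophyly_matches_bipartition_enumeration():
    trees = [
        NWK,
        "(((A:1,B:1):1,C:1):1,(D:1,E:1):1,F:1);",
        "((A:1,(B:1,(C:1,D:1):1):1):1,(E:1,F:1):1,(G:1,H:1):1);",
    ]
    for nwk in trees:
        t = tr.parse_newick(nwk)
        for k in (2, 3):
            for combo in itertools.combinations(sorted(t.tips), k):
                got = tr.is_monophyletic(t, set(combo)).is_monophyletic
                assert got == _brute_force_mono(t, combo), (nwk, combo)


def test_rf_distance_identity_and_symmetry():
    t1 = tr.parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
    t2 = tr.parse_newick("((A:1,C:1):1,(B:1,D:1):1,E:1);")
    assert tr.rf_distance(t1, t1) == (0, 0.0)
    assert tr.rf_distance(t1, t2) == tr.rf_distance(t2, t1)
    rf, norm = tr.rf_distance(t1, t2)
    assert rf == 4 and norm == 1.0


def test_rf_distance_requires_same_tips():
    t1 = tr.parse_newick("((A:1,B:1):1,C:1,D:1);")
    t2 = tr.parse_newick("((A:1,B:1):1,C:1,E:1);")
    with pytest.raises(ValueError):
        tr.rf_distance(t1, t2)


def test_rf_matches_scikit_bio_oracle():
    from skbio import TreeNode
    import io
    import random
    rnd = random.Random(7)
    for n in (4, 5, 6, 7, 8):
        tips = [f"t{i}" for i in range(n)]
        for _ in range(10):
            a = _random_newick(tips, rnd)
            b = _random_newick(tips, rnd)
            ta, tb = tr.parse_newick(a), tr.parse_newick(b)
            rf, _ = tr.rf_distance(ta, tb)
            sa = TreeNode.read(io.StringIO(a))
            sb = TreeNode.read(io.StringIO(b))
            assert rf == int(sa.compare_rfd(sb)), (a, b)


def _random_newick(tips, rnd):
    nodes = [f"{t}:1" for t in tips]
    while len(nodes) > 3:
        i, j = sorted(rnd.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(f"({a},{b}):1")
    return f"({','.join(nodes)});"


def test_prune_does_not_mutate_input_tree():
    nwk, _ = syn.generate_repeat_tree(4, 2, congruent=True, seed=3)
    t = tr.parse_newick(nwk)
    before = sorted(l.taxon.label for l in t.tree.leaf_node_iter())
    tr.repeat_congruence_rf(t)
    after = sorted(l.taxon.label for l in t.tree.leaf_node_iter())
    assert before == after


def test_repeat_congruence_rf_on_generated_trees():
    cong, _ = syn.generate_repeat_tree(5, 3, congruent=True, seed=3)
    inc, _ = syn.generate_repeat_tree(5, 3, congruent=False, seed=3)
    assert tr.repeat_congruence_rf(tr.parse_newick(cong)) == (0, 0.0)
    rf, norm = tr.repeat_congruence_rf(tr.parse_newick(inc))
    assert rf > 0 and norm > 0


def test_repeat_congruence_requires_three_families():
    t = tr.parse_newick("((1xa:1,2xa:1):1,(1xb:1,2xb:1):1,c:1);")
    with pytest.raises(ValueError):
        tr.repeat_congruence_rf(t)


def test_repeat_separation_verdicts():
    sep = tr.parse_newick(
        "(((1xa:1,1xb:1):1,(2xa:1,2xb:1):1):1,s1:1,s2:1);")
    mix = tr.parse_newick(
        "(((1xa:1,2xb:1):1,(2xa:1,1xb:1):1):1,s1:1,s2:1);")
    assert tr.repeat_separation(sep)["separated"]
    assert not tr.repeat_separation(mix)["separated"]
    with pytest.raises(ValueError):
        tr.repeat_separation(tr.parse_newick("((a:1,b:1):1,c:1,d:1);"))


def test_map_trait_composition():
    from chanarch.types import DeterminantProfile

    def prof(sid, count):
        return DeterminantProfile(
            sequence_id=sid, repeat=1, filter_motif="TVGYG",
            filter_class="canonical", s4_rk_count=count,
            s4_middle_residue="L", hcn_signature=False,
            rk_rich=count >= 7, linker_length=4, linker_class="short")

    t = tr.parse_newick(NWK)
    profiles = [prof("A", 8), prof("B", 7), prof("C", 4), prof("D", 8),
                prof("E", 3)]
    reports = tr.map_trait(t, profiles, [{"A", "B"}, {"C", "D"}, {"C", "E"}])
    assert reports[0].trait_class == "rich"
    assert reports[1].trait_class == "mixed"
    assert reports[2].trait_class == "poor"
    with pytest.raises(ValueError):
        tr.map_trait(t, profiles[:2], [{"A", "C"}])
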