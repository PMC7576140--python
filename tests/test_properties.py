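"""Property-based tests (hypothesis, derandomised via the 'ci' profile)."""

import random

import pytest
from hypothesis import given, strategies as st

from chanarch import align, msa
from chanarch import synthetic as syn
from chanarch import tandem
from chanarch import topology as topo
from chanarch import trees as tr

AA = "ACDEFGHIKLMNPQRSTVWY"


# --- msa -------------------------------------------------------------------

aligned_rows = st.integers(2, 6).flatmap(
    lambda ncols: st.lists(
        st.text(alphabet=AA + "-", min_size=ncols, max_size=ncols),
        min_size=2, max_size=5,
    )
)


@given(aligned_rows, st.floats(0, 1), st.floats(0, 1))
def test_column_filter_idempotent_property(rows, gap_frac, min_ident):
    aln = msa.Alignment([f"r{i}" for i in range(len(rows))], rows)
    try:
        once, kept1 = msa.remove_nonconservative_columns(aln, gap_frac,
                                                         min_ident)
    except ValueError:
        return  # filter may empty the alignment; nothing further to check
    if once.n_cols == 0:
        return
    twice, kept2 = msa.remove_nonconservative_columns(once, gap_frac,
                                                      min_ident)
    assert twice.rows == once.rows
    assert kept2 == list(range(once.n_cols))
    # retained index map is strictly increasing and within bounds
    assert kept1 == sorted(set(kept1))
    assert all(0 <= c < aln.n_cols for c in kept1)


@given(aligned_rows)
def test_column_filter_noop_at_permissive_thresholds(rows):
    aln = msa.Alignment([f"r{i}" for i in range(len(rows))], rows)
    all_gap_cols = [c for c in range(aln.n_cols)
                    if all(r[c] == "-" for r in rows)]
    out, kept = msa.remove_nonconservative_columns(aln, 1.0, 0.0)
    # only all-gap columns may be dropped at the permissive bounds
    assert kept == [c for c in range(aln.n_cols) if c not in all_gap_cols]


# --- alignment -------------------------------------------------------------

protein = st.text(alphabet=AA, min_size=1, max_size=40)


@given(protein, protein)
def test_percent_identity_symmetric_property(a, b):
    assert align.percent_identity(a, b) == pytest.approx(
        align.percent_identity(b, a))


@given(protein)
def test_self_identity_is_100(a):
    assert align.percent_identity(a, a) == pytest.approx(100.0)


@given(protein, protein)
def test_identity_bounds(a, b):
    ident = align.percent_identity(a, b)
    assert 0.0 <= ident <= 100.0


# --- synthetic / topology --------------------------------------------------

@given(st.integers(0, 2**31 - 1))
def test_generator_deterministic_property(seed):
    sp = syn.SynthChannelSpec(id="p", seed=seed)
    assert syn.generate_channel(sp)[0].residues == \
        syn.generate_channel(sp)[0].residues


@given(st.integers(1, 500), st.integers(3, 8), st.booleans())
def test_generated_channel_recovers_s4_charges(seed, k, polar):
    sp = syn.SynthChannelSpec(id="p", seed=seed, s4_rk_counts=[k],
                              s4_middle_polar=[polar])
    seq, truth = syn.generate_channel(sp)
    model = topo.assign_6tm(seq)
    assert model.n_repeats == 1
    s4 = model.repeats[0].segments["S4"]
    got = sum(1 for a in seq.residues[s4.start:s4.end] if a in "RK")
    assert got == k


@given(st.integers(1, 200))
def test_topology_robust_to_terminal_padding(seed):
    sp = syn.SynthChannelSpec(id="p", seed=seed)
    seq, _ = syn.generate_channel(sp)
    rng = random.Random(seed)
    pad_n = "".join(rng.choice("NQDEPHST") for _ in range(15))
    pad_c = "".join(rng.choice("NQDEPHST") for _ in range(15))
    padded = type(seq)(seq.id, pad_n + seq.residues + pad_c)
    m1 = topo.assign_6tm(seq)
    m2 = topo.assign_6tm(padded)
    assert m2.n_repeats == m1.n_repeats == 1
    s4a = m1.repeats[0].segments["S4"]
    s4b = m2.repeats[0].segments["S4"]
    assert s4b.start - s4a.start == len(pad_n)
    assert s4b.end - s4a.end == len(pad_n)


# --- tandem ----------------------------------------------------------------

@given(st.integers(1, 100))
def test_split_tandem_partition_property(seed):
    sp = syn.SynthChannelSpec(
        id="t", n_repeats=2, s4_rk_counts=[6, 6],
        s4_middle_polar=[False, False], filter_motifs=["TVGYG", "TVGYG"],
        has_cnbd=[False, False], deleted_elements=[[], []], seed=seed)
    seq, _ = syn.generate_channel(sp)
    model = topo.assign_6tm(seq)
    if tandem.detect_repeats(model) != 2:
        return
    u1, u2 = tandem.split_tandem(seq, model)
    assert u1.sequence + u2.sequence == seq.residues
    assert u1.span[1] == u2.span[0]


# --- trees -----------------------------------------------------------------

def _random_newick(tips, rnd):
    nodes = [f"{t}:1" for t in tips]
    while len(nodes) > 3:
        i, j = sorted(rnd.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(f"({a},{b}):1")
    return f"({','.join(nodes)});"


@given(st.integers(4, 8), st.integers(0, 10**6))
def test_rf_symmetry_and_identity_property(n, seed):
    rnd = random.Random(seed)
    tips = [f"t{i}" for i in range(n)]
    a = tr.parse_newick(_random_newick(tips, rnd))
    b = tr.parse_newick(_random_newick(tips, rnd))
    assert tr.rf_distance(a, a) == (0, 0.0)
    assert tr.rf_distance(a, b) == tr.rf_distance(b, a)
    rf, norm = tr.rf_distance(a, b)
    assert rf % 2 == 0  # symmetric difference of two binary trees is even
    assert 0.0 <= norm <= 1.0
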