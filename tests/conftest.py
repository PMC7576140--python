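"""Shared fixtures: small deterministic cohorts and annotated channels."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from chanarch import synthetic as syn
from chanarch import topology as topo

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_channel():
    """One default single-repeat channel plus its ground truth."""
    spec = syn.SynthChannelSpec(id="base", seed=11)
    seq, truth = syn.generate_channel(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def cnbd_channel():
    """A CNBD-carrying single-repeat channel plus its ground truth."""
    spec = syn.SynthChannelSpec(
        id="cnbd", has_cnbd=[True], s4_rk_counts=[8],
        loop_lengths={"s4_s5": 4}, seed=13,
    )
    seq, truth = syn.generate_channel(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def tandem_channel():
    """A two-repeat tandem channel plus its ground truth."""
    spec = syn.SynthChannelSpec(
        id="tand", n_repeats=2, s4_rk_counts=[8, 5],
        s4_middle_polar=[False, False], filter_motifs=["TVGYG", "TVGFG"],
        has_cnbd=[False, False], deleted_elements=[[], []],
        loop_lengths={"s4_s5": 4}, seed=17,
    )
    seq, truth = syn.generate_channel(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def small_cohort():
    """12-channel mixed cohort with topology models, keyed by id."""
    specs = syn.study_cohort(seed=5, n_cnbd_single=4, n_kv_single=4,
                             n_cnbd_tandem=2, n_kv_tandem=2)
    seqs, truths = syn.generate_dataset(specs, seed=5)
    models = topo.annotate_fasta(seqs)
    return {
        s.id: (sp, s, t, m)
        for sp, s, t, m in zip(specs, seqs, truths, models)
    }
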