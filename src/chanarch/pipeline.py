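"""End-to-end orchestration: annotate -> determinants -> cnbd -> split-tandem
-> curate-msa -> tree-stats, with a machine-readable run report.

Every stage writes its table under the configured output directory; the run
report JSON carries per-stage record counts and an echo of the configuration
(plus its hash) so that re-runs with an unchanged config reproduce all numeric
outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from chanarch import cnbd as cnbd_mod
from chanarch import determinants as det_mod
from chanarch import msa as msa_mod
from chanarch import tandem as tandem_mod
from chanarch import trees as trees_mod
from chanarch.topology import TopologyParams, annotate_fasta, model_to_rows
from chanarch.types import ChannelSequence


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    fasta: str = ""
    alignment: str | None = None
    tree: str | None = None
    outdir: str = "results/run"
    seed: int = 0
    # topology thresholds
    window: int = 19
    hydropathy_threshold: float = 1.6
    min_tm_len: int = 15
    max_tm_len: int = 30
    # determinant thresholds (fixed by the analysed dichotomies)
    rk_rich_threshold: int = 7
    short_linker_max: int = 10
    # msa curation
    max_gap_frac: float = 0.75
    min_identity: float = 0.0
    mixed_dataset: bool = False
    # cnbd
    presence_threshold: float = 0.5
    identity_floor: float = 0.24
    groups: dict = field(default_factory=dict)  # id -> taxon/channel group

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def read_fasta(path, groups: dict | None = None) -> list[ChannelSequence]:
    """Read candidate sequences; ``group=...`` tokens in descriptions are honoured."""
    groups = groups or {}
    records: list[ChannelSequence] = []
    rid, desc, chunks = None, "", []
    def flush():
        if rid is None:
            return
        group = groups.get(rid)
        for tok in desc.split():
            if tok.startswith("group=") and tok != "group=NA":
                group = tok[6:]
        records.append(ChannelSequence(rid, "".join(chunks), group=group))
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                flush()
                head = line[1:].split(None, 1)
                rid = head[0]
                desc = head[1] if len(head) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line)
    flush()
    return records


def _log(stage: str, msg: str) -> None:
    print(f"[chanarch:{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages applicable to the provided inputs; return the report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "config_hash": config.hash(),
                    "stages": {}}
    params = TopologyParams(
        window=config.window, threshold=config.hydropathy_threshold,
        min_tm_len=config.min_tm_len, max_tm_len=config.max_tm_len,
    )

    # --- annotate ---------------------------------------------------------
    seqs = read_fasta(config.fasta, config.groups)
    if not seqs:
        raise RuntimeError(f"annotate: no sequences in {config.fasta}")
    models = annotate_fasta(seqs, params)
    rows = [r for m in models for r in model_to_rows(m)]
    pd.DataFrame(rows).to_csv(out / "annotations.tsv", sep="\t", index=False)
    report["stages"]["annotate"] = {
        "n_sequences": len(seqs),
        "n_repeats": sum(m.n_repeats for m in models),
        "flagged": sum(1 for m in models if m.flags),
    }
    _log("annotate", f"{len(seqs)} sequences, "
         f"{report['stages']['annotate']['n_repeats']} repeats")

    # --- cnbd -------------------------------------------------------------
    by_id = {s.id: s for s in seqs}
    maps = []
    for m in models:
        for rep in m.repeats:
            cm = cnbd_mod.detect_cnbd(
                by_id[m.sequence_id], m, rep.index,
                presence_threshold=config.presence_threshold,
                identity_floor=config.identity_floor,
            )
            rep.clinker, rep.cnbd = cm.clinker_span, cm.cnbd_span
            maps.append(cm)
    pd.DataFrame(cnbd_mod.element_report(maps)).to_csv(
        out / "cnbd_elements.tsv", sep="\t", index=False)
    report["stages"]["cnbd"] = {
        "n_maps": len(maps),
        "n_with_cnbd": sum(1 for c in maps if c.has_cnbd),
    }
    _log("cnbd", f"{report['stages']['cnbd']['n_with_cnbd']}/{len(maps)} "
         "repeats carry a CNBD")

    # --- determinants -----------------------------------------------------
    cmap_by = {(c.sequence_id, c.repeat): c for c in maps}
    profiles = []
    for m in models:
        for rep in m.repeats:
            if "S4" not in rep.segments:
                continue
            profiles.append(det_mod.build_profile(
                by_id[m.sequence_id], m, rep.index,
                cmap_by.get((m.sequence_id, rep.index)),
            ))
    det_mod.profiles_to_frame(profiles).to_csv(
        out / "profiles.tsv", sep="\t", index=False)
    groups = {}
    for m in models:
        ps = [p for p in profiles if p.sequence_id == m.sequence_id]
        if ps:
            groups[m.sequence_id] = cnbd_mod.classify_group(ps)
    report["stages"]["determinants"] = {
        "n_profiles": len(profiles),
        "n_cnbd_channels": sum(1 for g, _ in groups.values()
                               if g == "CNBD-channel"),
        "n_kv_like": sum(1 for g, _ in groups.values() if g == "Kv-like"),
    }
    _log("determinants", f"{len(profiles)} repeat profiles")

    # --- split-tandem -----------------------------------------------------
    units = []
    for m in models:
        if tandem_mod.detect_repeats(m) == 2:
            units.extend(tandem_mod.split_tandem(by_id[m.sequence_id], m))
    if units:
        tandem_mod.units_to_fasta(units, out / "repeat_units.fasta")
    report["stages"]["split_tandem"] = {
        "n_tandem": len(units) // 2, "n_units": len(units),
    }
    _log("split-tandem", f"{len(units) // 2} tandem channels split")

    # --- curate-msa (only with an alignment input) ------------------------
    if config.alignment:
        aln = msa_mod.read_alignment(config.alignment)
        report["stages"]["msa_input"] = {"n_rows": aln.n_rows,
                                         "n_cols": aln.n_cols}
        curated, kept = msa_mod.remove_nonconservative_columns(
            aln, config.max_gap_frac, config.min_identity)
        if config.mixed_dataset:
            ann = {m.sequence_id: m for m in models}
            if all(r in ann for r in curated.ids):
                curated = msa_mod.strip_terminal_domains(curated, ann, mixed=True)
        msa_mod.write_alignment(
            curated, out / "curated_alignment.fasta",
            header=f"config_hash={config.hash()}")
        report["stages"]["curate_msa"] = {"n_rows": curated.n_rows,
                                          "n_cols": curated.n_cols}
        _log("curate-msa", f"{aln.n_cols} -> {curated.n_cols} columns")

    # --- tree-stats (only with a tree input) ------------------------------
    if config.tree:
        with open(config.tree) as fh:
            ptree = trees_mod.parse_newick(fh.read())
        stats: dict = {"n_tips": len(ptree.tips),
                       "support_scale": ptree.support_scale}
        try:
            sep = trees_mod.repeat_separation(ptree)
            stats["repeats_separated"] = bool(sep["separated"])
        except ValueError:
            stats["repeats_separated"] = None
        try:
            rf, nrf = trees_mod.repeat_congruence_rf(ptree)
            stats["repeat_rf"] = rf
            stats["repeat_rf_normalised"] = nrf
        except ValueError:
            pass
        report["stages"]["tree_stats"] = stats
        _log("tree-stats", json.dumps(stats))

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
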