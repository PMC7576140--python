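#!/usr/bin/env python
"""Annotate the cohort's 6TM topology and score recovery against the truth."""

import argparse
from pathlib import Path

import pandas as pd

from chanarch import topology as topo
from chanarch.pipeline import read_fasta


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fasta", type=Path, default=Path("results/cohort.fasta"))
    ap.add_argument("--truth", type=Path,
                    default=Path("results/cohort_truth.tsv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--tolerance", type=int, default=2,
                    help="residues of slack per recovered boundary")
    args = ap.parse_args()

    seqs = read_fasta(args.fasta)
    models = topo.annotate_fasta(seqs)
    rows = [r for m in models for r in topo.model_to_rows(m)]
    pd.DataFrame(rows).to_csv(args.outdir / "annotations.tsv",
                              sep="\t", index=False)

    truth = pd.read_csv(args.truth, sep="\t")
    pred = {(r["id"], r["repeat"], r["label"]): (r["start"], r["end"])
            for r in rows}
    scored = []
    for (sid, rep), grp in truth.groupby(["id", "repeat"]):
        core = grp[grp["label"].isin(["S1", "S2", "S3", "S4", "S5", "S6"])]
        ok = all(
            (sid, rep, r.label) in pred
            and abs(pred[(sid, rep, r.label)][0] - r.start) <= args.tolerance
            and abs(pred[(sid, rep, r.label)][1] - r.end) <= args.tolerance
            for r in core.itertuples()
        )
        scored.append({"id": sid, "repeat": rep, "recovered": ok})
    df = pd.DataFrame(scored)
    df.to_csv(args.outdir / "topology_recovery.tsv", sep="\t", index=False)
    print(f"recovered {int(df.recovered.sum())}/{len(df)} repeats "
          f"within +/-{args.tolerance} residues")


if __name__ == "__main__":
    main()
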