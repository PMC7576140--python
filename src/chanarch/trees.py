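"""Tree-level statistics: monophyly, repeat separation, repeat-clade congruence.

Trees are interpreted with unrooted semantics by default (a tip set is
monophyletic iff it is exactly one side of some bipartition), since channel
phylogenies are typically drawn unrooted; a rooted interpretation is available
behind a flag for outgroup-rooted runs. Internal-node labels of the form
``95`` or ``100/0.97`` are parsed as supports; values at most 1 are taken as
posterior probabilities, larger values as bootstrap percentages.

Newick parsing and pruning are delegated to dendropy; the bipartition-based
verdicts (monophyly, Robinson-Foulds counts) are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from chanarch.types import DeterminantProfile


@dataclass
class PhyloTree:
    """A parsed tree plus per-clade support annotations.

    ``supports`` maps the frozenset of tip names under an internal node to a
    ``(support1, support2)`` tuple (second entry None for single labels).
    """

    tree: dendropy.Tree
    tips: list[str]
    supports: dict[frozenset, tuple[float | None, float | None]]
    support_scale: str  # "bootstrap" | "posterior" | "mixed" | "none"
    rooted: bool = False


@dataclass
class CladeReport:
    """Monophyly / trait verdict for one query tip set."""

    tipset: frozenset
    is_monophyletic: bool
    intruders: frozenset = frozenset()
    support: tuple[float | None, float | None] = (None, None)
    n_rich: int = 0
    n_poor: int = 0
    trait_class: str = ""

    def __post_init__(self) -> None:
        if self.is_monophyletic != (len(self.intruders) == 0):
            raise ValueError("monophyly verdict inconsistent with intruder set")


def _parse_support(label: str | None) -> tuple[float | None, float | None]:
    if not label:
        return (None, None)
    parts = label.split("/")
    vals: list[float | None] = []
    for p in parts[:2]:
        try:
            vals.append(float(p))
        except ValueError:
            vals.append(None)
    while len(vals) < 2:
        vals.append(None)
    return (vals[0], vals[1])


def parse_newick(text: str, rooted: bool = False) -> PhyloTree:
    """Parse a Newick string with optional support / dual-support node labels."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed newick: {exc}") from exc
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate tip names")
    supports: dict[frozenset, tuple[float | None, float | None]] = {}
    values: list[float] = []
    for node in tree.preorder_internal_node_iter():
        s = _parse_support(node.label)
        if s != (None, None):
            under = frozenset(
                l.taxon.label for l in node.leaf_iter()
            )
            supports[under] = s
            values.extend(v for v in s if v is not None)
    if not values:
        scale = "none"
    elif all(v <= 1 for v in values):
        scale = "posterior"
    elif all(v > 1 for v in values):
        scale = "bootstrap"
    else:
        scale = "mixed"
    return PhyloTree(tree, tips, supports, scale, rooted)


def write_newick(ptree: PhyloTree) -> str:
    """Serialise back to Newick (topology, lengths and node labels preserved)."""
    return ptree.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _clade_sets(ptree: PhyloTree) -> list[frozenset]:
    """Tip sets under each internal node of the (arbitrarily rooted) tree."""
    out = []
    for node in ptree.tree.preorder_internal_node_iter():
        out.append(frozenset(l.taxon.label for l in node.leaf_iter()))
    return out


def bipartitions(ptree: PhyloTree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the two sides.

    Each bipartition is represented canonically as
    ``frozenset({side, complement})`` so comparisons are rooting-invariant.
    """
    all_tips = frozenset(ptree.tips)
    out: set[frozenset] = set()
    for clade in _clade_sets(ptree):
        comp = all_tips - clade
        if len(clade) >= 2 and len(comp) >= 2:
            out.add(frozenset({clade, comp}))
    return out


def is_monophyletic(ptree: PhyloTree, tipset) -> CladeReport:
    """Bipartition-membership monophyly test with intruder reporting.

    Unrooted semantics: the query is monophyletic iff it is exactly one side
    of some branch. Intruders are the extra tips under the minimal clade (or
    bipartition side) spanning the query.
    """
    tipset = frozenset(tipset)
    all_tips = frozenset(ptree.tips)
    unknown = tipset - all_tips
    if unknown:
        raise ValueError(f"unknown tips: {sorted(unknown)}")
    if len(tipset) < 2:
        raise ValueError("tipset must contain at least 2 tips")
    clades = _clade_sets(ptree)
    candidates = list(clades)
    if not ptree.rooted:
        candidates += [all_tips - c for c in clades]
        # pendant edges: every all-but-one-tip set is one side of a branch
        candidates += [all_tips - {t} for t in ptree.tips]
    candidates.append(all_tips)
    spanning = min(
        (c for c in candidates if tipset <= c), key=len
    )
    mono = spanning == tipset
    support = ptree.supports.get(tipset, (None, None))
    if not mono and not ptree.rooted:
        comp = all_tips - tipset
        support = ptree.supports.get(comp, support)
    return CladeReport(
        tipset=tipset,
        is_monophyletic=mono,
        intruders=spanning - tipset,
        support=support,
    )


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> tuple[int, float]:
    """Unweighted Robinson-Foulds distance and its normalised form.

    RF counts the bipartitions present in exactly one of the two trees; the
    normalisation divides by 2(n-3), the maximum for two unrooted binary
    trees on n shared tips (0 when n <= 3).
    """
    if set(t1.tips) != set(t2.tips):
        raise ValueError("trees must share an identical tip set")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    rf = len(b1 ^ b2)
    n = len(t1.tips)
    denom = 2 * (n - 3)
    return rf, (rf / denom if denom > 0 else 0.0)


def _prune_and_strip(ptree: PhyloTree, prefix: str) -> PhyloTree:
    keep = [t for t in ptree.tips if t.startswith(prefix)]
    sub = ptree.tree.extract_tree_with_taxa_labels(keep)
    # the extracted tree shares taxon objects with the source tree, so re-parse
    # into a fresh namespace before relabelling to leave the input untouched
    fresh = parse_newick(
        sub.as_string(schema="newick", suppress_rooting=True),
        rooted=ptree.rooted,
    )
    for leaf in fresh.tree.leaf_node_iter():
        leaf.taxon.label = leaf.taxon.label[len(prefix):]
    fresh.tips = [t[len(prefix):] for t in fresh.tips]
    fresh.supports = {
        frozenset(t[len(prefix):] for t in k): v
        for k, v in fresh.supports.items()
    }
    return fresh


def repeat_congruence_rf(ptree: PhyloTree) -> tuple[int, float]:
    """Congruence of the first- and second-repeat clades of tandem channels.

    The tree is pruned to the ``1x*`` tips and, separately, the ``2x*`` tips;
    both induced trees are relabelled with the parent identifiers and compared
    by Robinson-Foulds distance. Requires at least three tandem families
    present as both repeats.
    """
    fam1 = {t[2:] for t in ptree.tips if t.startswith("1x")}
    fam2 = {t[2:] for t in ptree.tips if t.startswith("2x")}
    shared = fam1 & fam2
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 tandem families present as both repeats, got {len(shared)}"
        )
    sub1 = _prune_and_strip(ptree, "1x")
    sub2 = _prune_and_strip(ptree, "2x")
    return rf_distance(sub1, sub2)


def repeat_separation(
    ptree: PhyloTree, families: dict[str, str] | None = None
) -> dict:
    """Do first and second repeats of tandem channels form separate clades?

    Tips named ``1x*`` / ``2x*`` are grouped into families (all tandem tips
    form one family by default, or per a tip->family mapping); for each family
    the monophyly of its 1x set and its 2x set is tested. The overall verdict
    is ``separated`` iff every tested set is monophyletic.
    """
    tand1 = [t for t in ptree.tips if t.startswith("1x")]
    tand2 = [t for t in ptree.tips if t.startswith("2x")]
    if not tand1 or not tand2:
        raise ValueError("no tandem (1x/2x) tips in tree")
    groups: dict[str, tuple[list[str], list[str]]] = {}
    if families is None:
        groups["all"] = (tand1, tand2)
    else:
        for t in tand1 + tand2:
            fam = families[t]
            groups.setdefault(fam, ([], []))[0 if t.startswith("1x") else 1].append(t)
    reports = {}
    separated = True
    for fam, (ones, twos) in groups.items():
        for side, tips in (("1x", ones), ("2x", twos)):
            if len(tips) < 2:
                continue
            rep = is_monophyletic(ptree, tips)
            reports[f"{fam}:{side}"] = rep
            separated &= rep.is_monophyletic
    return {"separated": separated, "reports": reports}


def map_trait(
    ptree: PhyloTree,
    profiles: list[DeterminantProfile],
    clades: list,
) -> list[CladeReport]:
    """R/K-richness composition per clade: rich / poor / mixed.

    Every clade tip must have a matching profile (tandem tips match the
    profile of the corresponding repeat via the 1x/2x prefix).
    """
    by_tip: dict[str, DeterminantProfile] = {}
    for p in profiles:
        by_tip[p.sequence_id] = p
        by_tip[f"{p.repeat}x{p.sequence_id}"] = p
    out = []
    for clade in clades:
        clade = frozenset(clade)
        missing = [t for t in clade if t not in by_tip]
        if missing:
            raise ValueError(f"missing profile for tips: {sorted(missing)}")
        rep = is_monophyletic(ptree, clade) if len(clade) >= 2 else CladeReport(
            tipset=clade, is_monophyletic=True
        )
        rep.n_rich = sum(1 for t in clade if by_tip[t].rk_rich)
        rep.n_poor = len(clade) - rep.n_rich
        if rep.n_poor == 0:
            rep.trait_class = "rich"
        elif rep.n_rich == 0:
            rep.trait_class = "poor"
        else:
            rep.trait_class = "mixed"
        out.append(rep)
    return out
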