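"""Uniparental haplogroup calling.

A haplogroup hierarchy is a rooted tree whose branches carry defining
variants (position, ancestral base, derived base). mtDNA haplogroups are
scored from an observed set of derived variants with a Kulczynski-style
two-way overlap score; Y-chromosome (and low-coverage mtDNA) samples are
placed on the tree by parsimony, maximizing derived support minus conflicts
along root-to-node paths. Basal (internal-node) placements are allowed,
which is how rare deep subclades present at low coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

ANCESTRAL, DERIVED, MISSING, CONFLICT = "ancestral", "derived", "missing", "conflict"

_TRANSITIONS = {frozenset(("C", "T")), frozenset(("G", "A"))}


@dataclass(frozen=True)
class Variant:
    pos: int
    anc: str
    der: str

    @property
    def is_transition(self) -> bool:
        return frozenset((self.anc, self.der)) in _TRANSITIONS


@dataclass
class HaploDefs:
    """Rooted haplogroup tree with per-branch defining variants.

    ``parent`` maps node name to its parent (root maps to None);
    ``variants`` maps node name to the variants on the branch *above* it.
    """

    parent: dict
    variants: dict
    contig: str = "chrMT"

    def __post_init__(self):
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        self.root = roots[0]
        self.children: dict = {n: [] for n in self.parent}
        for n, p in self.parent.items():
            if p is not None:
                if p not in self.parent:
                    raise ValueError(f"node {n!r} has unknown parent {p!r}")
                self.children[p].append(n)
        # cycle check: every node must reach the root
        for n in self.parent:
            self.path(n)
        for n, vs in self.variants.items():
            pos = [v.pos for v in vs]
            if len(pos) != len(set(pos)):
                raise ValueError(f"branch {n!r} repeats a variant position")

    def nodes(self) -> list:
        return list(self.parent)

    def path(self, node: str) -> list:
        """Nodes from root to ``node`` inclusive."""
        out = []
        seen = set()
        cur = node
        while cur is not None:
            if cur in seen:
                raise ValueError(f"cycle detected at node {cur!r}")
            seen.add(cur)
            out.append(cur)
            cur = self.parent[cur]
        return out[::-1]

    def depth(self, node: str) -> int:
        return len(self.path(node)) - 1

    def path_variants(self, node: str) -> list:
        out = []
        for n in self.path(node):
            out.extend(self.variants.get(n, []))
        return out

    def all_variants(self) -> list:
        out = []
        for n in self.parent:
            out.extend(self.variants.get(n, []))
        return out


@dataclass
class HaploCall:
    haplogroup: str
    score: Optional[float]
    n_derived_support: int
    n_conflicts: int
    n_missing: int
    margin: Optional[float] = None


def snp_status(rs, variants: Sequence[Variant], min_bq: int = 30,
               damage_mask: bool = True) -> dict:
    """Classify each defining variant as ancestral/derived/missing/conflict.

    Bases with quality below ``min_bq`` are ignored. With ``damage_mask``,
    C<->T and G<->A defined variants are excluded entirely (status missing):
    in unrepaired libraries deamination can mimic either allele state.
    Status is derived/ancestral when all passing reads agree, conflict when
    both states are seen, missing when no passing read covers the site.
    """
    pm: dict = {}
    for i, v in enumerate(variants):
        pm.setdefault(v.pos, []).append(i)
    obs: dict = {i: set() for i in range(len(variants))}
    masked = {i for i, v in enumerate(variants) if damage_mask and v.is_transition}
    for r in rs.reads:
        for off in range(len(r.seq)):
            idxs = pm.get(r.start + off)
            if not idxs or r.quals[off] < min_bq:
                continue
            for i in idxs:
                if i in masked:
                    continue
                obs[i].add(r.seq[off])
    out = {}
    for i, v in enumerate(variants):
        seen = obs[i]
        has_anc = v.anc in seen
        has_der = v.der in seen
        if has_anc and has_der:
            out[v] = CONFLICT
        elif has_der:
            out[v] = DERIVED
        elif has_anc:
            out[v] = ANCESTRAL
        else:
            out[v] = MISSING
    return out


def assign_mt_haplogroup(observed_derived: set, defs: HaploDefs,
                         covered_positions: Optional[set] = None) -> list:
    """Rank haplogroups by a Kulczynski-style two-way overlap score.

    ``observed_derived`` is a set of (position, derived base) pairs from the
    sample (typically from its mtDNA consensus); ``covered_positions``
    restricts the expected set to positions the sample actually covers (all
    positions when None). Score for candidate h with expected path set E:
    0.5 * (|E∩O| / |E∩covered| + |E∩O| / |O|). Ties break on shallower tree
    depth, then name. An empty observed set returns the root with a missing
    score.
    """
    O = set(observed_derived)
    if not O:
        return [HaploCall(defs.root, None, 0, 0, 0)]
    calls = []
    for node in defs.nodes():
        path = defs.path_variants(node)
        E = {(v.pos, v.der) for v in path}
        if covered_positions is not None:
            Ecov = {e for e in E if e[0] in covered_positions}
        else:
            Ecov = E
        hit = len(Ecov & O)
        if Ecov or O:
            prec = hit / len(O)
            rec = hit / len(Ecov) if Ecov else (1.0 if node == defs.root else 0.0)
            score = 0.5 * (rec + prec)
        else:
            score = 0.0
        calls.append(HaploCall(node, score, hit, len(Ecov) - hit,
                               len(E) - len(Ecov)))
    calls.sort(key=lambda c: (-c.score, defs.depth(c.haplogroup), c.haplogroup))
    if len(calls) > 1:
        calls[0].margin = calls[0].score - calls[1].score
    return calls


def place_on_tree(statuses: Mapping[Variant, str], defs: HaploDefs) -> HaploCall:
    """Parsimony placement: maximize derived support minus conflicts.

    For node h with root-to-h path variants P, support = derived statuses in
    P, conflicts = ancestral statuses in P; the best node maximizes
    support - conflicts. Ties prefer the shallower node (then name), so
    support confined to a shared internal branch yields a basal, internal
    placement rather than an arbitrary leaf.
    """
    informative = {v: s for v, s in statuses.items() if s in (DERIVED, ANCESTRAL)}
    if not informative:
        raise ValueError("no informative sites")
    n_missing_total = sum(1 for s in statuses.values() if s in (MISSING, CONFLICT))
    scored = []
    for node in defs.nodes():
        path = set(defs.path_variants(node))
        sup = sum(1 for v, s in informative.items() if v in path and s == DERIVED)
        conf = sum(1 for v, s in informative.items() if v in path and s == ANCESTRAL)
        scored.append((sup - conf, sup, conf, node))
    scored.sort(key=lambda t: (-t[0], defs.depth(t[3]), t[3]))
    best = scored[0]
    margin = float(best[0] - scored[1][0]) if len(scored) > 1 else None
    return HaploCall(best[3], None, best[1], best[2], n_missing_total, margin)


def consensus_derived_variants(consensus: str, defs: HaploDefs) -> tuple[set, set]:
    """Observed derived set and covered positions from an mtDNA consensus.

    Positions are 1-based; consensus 'N' counts as uncovered.
    """
    observed = set()
    covered = set()
    for v in defs.all_variants():
        if v.pos > len(consensus):
            continue
        base = consensus[v.pos - 1]
        if base == "N":
            continue
        covered.add(v.pos)
        if base == v.der:
            observed.add((v.pos, v.der))
    return observed, covered
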