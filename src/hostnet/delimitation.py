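"""DNA-based species delimitation by genealogical concordance.

Clades recovered in at least two of three independent gene trees, and
contradicted by none, are treated as evolutionarily independent lineages.
Provisional species are the most inclusive such lineages that contain at
least three specimens and no nested qualifying lineage. Specimens outside
every provisional species are rescued by a divergence threshold: the
minimum divergence observed between provisional species. Any specimen
farther than that threshold from every other specimen becomes its own
species; the rest are attached by single linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .alignment import DistanceMatrix
from .datamodel import SpeciesAssignment, ValidationError

PRESENT = "present"
CONTRADICTED = "contradicted"
UNINFORMATIVE = "uninformative"


@dataclass
class CladeSet:
    """Candidate specimen sets with their status in each gene tree."""

    clades: list[frozenset]
    statuses: list[tuple[str, ...]]

    def __iter__(self):
        return iter(self.clades)

    def __len__(self):
        return len(self.clades)

    def n_present(self, clade: frozenset) -> int:
        i = self.clades.index(clade)
        return self.statuses[i].count(PRESENT)


def _tree_clades(tree: dendropy.Tree) -> set[frozenset]:
    """Leaf sets of every internal node (size >= 2), including the root."""
    clades = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(c._leafset for c in node.child_nodes()))
            node._leafset = s
            if len(s) >= 2:
                clades.add(s)
    return clades


def clade_status(clade: frozenset, tree: dendropy.Tree) -> str:
    """Status of a candidate clade in one gene tree.

    The clade is restricted to the tree's leaf set; restrictions of size
    <= 1, or equal to the whole tree, are uninformative. Otherwise the
    clade is present if the restriction is monophyletic and contradicted
    if not.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    s = frozenset(clade) & leaves
    if len(s) <= 1 or s == leaves:
        return UNINFORMATIVE
    return PRESENT if s in _tree_clades(tree) else CONTRADICTED


def independent_lineages(gene_trees: list[dendropy.Tree]) -> CladeSet:
    """All specimen sets present in >= 2 gene trees and contradicted in none.

    Candidates are the union of the clades of all trees; each is scored in
    every tree on the shared-leaf restriction.
    """
    if len(gene_trees) < 2:
        raise ValidationError("need at least two gene trees")
    per_tree = [_tree_clades(t) for t in gene_trees]
    leafsets = [{lf.taxon.label for lf in t.leaf_node_iter()} for t in gene_trees]
    candidates = sorted(set().union(*per_tree), key=lambda c: (len(c), sorted(c)))
    kept, statuses = [], []
    for cand in candidates:
        st = []
        for clades, leaves in zip(per_tree, leafsets):
            s = cand & leaves
            if len(s) <= 1 or s == leaves:
                st.append(UNINFORMATIVE)
            elif s in clades:
                st.append(PRESENT)
            else:
                st.append(CONTRADICTED)
        if st.count(PRESENT) >= 2 and CONTRADICTED not in st:
            kept.append(cand)
            statuses.append(tuple(st))
    return CladeSet(kept, statuses)


def _resolve_conflicts(lineages: CladeSet) -> list[frozenset]:
    """Drop overlapping non-nested lineages deterministically.

    With partial leaf overlap between gene trees, two independent lineages
    can overlap without nesting. Preference order: present in more trees,
    then larger, then lexicographically smallest id set.
    """
    order = sorted(
        range(len(lineages.clades)),
        key=lambda i: (
            -lineages.statuses[i].count(PRESENT),
            -len(lineages.clades[i]),
            sorted(lineages.clades[i]),
        ),
    )
    kept: list[frozenset] = []
    for i in order:
        c = lineages.clades[i]
        if all(c <= k or k <= c or not (c & k) for k in kept):
            kept.append(c)
    return kept


def provisional_species(lineages: CladeSet) -> list[frozenset]:
    """Most inclusive qualifying lineages.

    A lineage qualifies when it has >= 3 members; it is a provisional
    species when no qualifying lineage is a proper subset of it. Nested
    lineages with < 3 members do not disqualify their parent.
    """
    laminar = _resolve_conflicts(lineages)
    qualifying = [c for c in laminar if len(c) >= 3]
    species = [
        c for c in qualifying
        if not any(q < c for q in qualifying)
    ]
    for a in species:
        for b in species:
            if a is not b and a & b:
                raise ValidationError("provisional species overlap after conflict resolution")
    return sorted(species, key=lambda c: sorted(c))


def divergence_threshold(
    species: list[frozenset], D: DistanceMatrix
) -> float | None:
    """Minimum pairwise divergence between members of different provisional
    species; None when fewer than two species exist."""
    if len(species) < 2:
        return None
    best = np.inf
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            for x in species[i]:
                for y in species[j]:
                    d = D.get(x, y)
                    if not np.isnan(d):
                        best = min(best, d)
    return float(best) if np.isfinite(best) else None


def assign_remaining(
    specimens: list[str],
    species: list[frozenset],
    threshold: float | None,
    D: DistanceMatrix,
) -> SpeciesAssignment:
    """Complete the partition over ``specimens``.

    Specimens not in any provisional species and farther than the threshold
    from every other specimen become singleton species (strict '>' per the
    rescue rule). The rest join the nearest cluster by single linkage; two
    nearby unplaced specimens seed a new cluster rather than joining a
    provisional species they are not close to.

    When no threshold exists (fewer than two provisional species), the
    fallback is the maximum within-species divergence of the provisional
    species, or infinity when none exists (everything then forms one
    single-linkage cluster per connected component at zero threshold —
    degenerate, but total).
    """
    specimens = list(specimens)
    placed = set().union(*species) if species else set()
    unknown = [s for s in specimens if s not in D._index]
    if unknown:
        raise ValidationError(f"specimens missing from distance matrix: {unknown}")

    if threshold is None:
        within = [
            D.get(x, y)
            for sp in species
            for x in sp
            for y in sp
            if x < y and not np.isnan(D.get(x, y))
        ]
        threshold = max(within) if within else np.inf

    clusters: list[set] = [set(sp) for sp in species]
    origins = {s: "provisional" for s in placed}
    n_provisional = len(clusters)
    unplaced = [s for s in specimens if s not in placed]

    for x in unplaced:
        others = [y for y in specimens if y != x]
        dists = [D.get(x, y) for y in others]
        if any(np.isnan(d) for d in dists):
            missing = [y for y, d in zip(others, dists) if np.isnan(d)]
            raise ValidationError(
                f"missing divergences for unplaced specimen {x!r} vs {missing}"
            )

    remaining = set(unplaced)
    singletons: list[str] = []
    for x in sorted(remaining):
        if all(D.get(x, y) > threshold for y in specimens if y != x):
            singletons.append(x)
    remaining -= set(singletons)

    # greedy single linkage among remaining unplaced and existing clusters
    def link_dist(x: str, group) -> float:
        return min(D.get(x, y) for y in group)

    while remaining:
        best = None  # (distance, specimen, target) target: cluster idx or specimen
        for x in sorted(remaining):
            for ci, cl in enumerate(clusters):
                d = link_dist(x, cl)
                cand = (d, x, ("cluster", ci))
                if best is None or cand[:2] < best[:2]:
                    best = cand
            for y in sorted(remaining):
                if y <= x:
                    continue
                d = D.get(x, y)
                cand = (d, x, ("pair", y))
                if best is None or cand[:2] < best[:2]:
                    best = cand
        d, x, target = best
        if d > threshold:
            # nothing within reach: everything left becomes singletons
            singletons.extend(sorted(remaining))
            remaining = set()
            break
        if target[0] == "cluster":
            clusters[target[1]].add(x)
            origins[x] = "linked"
            remaining.discard(x)
        else:
            y = target[1]
            clusters.append({x, y})
            origins[x] = origins[y] = "linked"
            remaining.discard(x)
            remaining.discard(y)

    outliers = [frozenset([s]) for s in singletons]
    for s in singletons:
        clusters.append({s})
        origins[s] = "threshold_singleton"

    assignment = {}
    for ci, cl in enumerate(sorted(clusters, key=lambda c: sorted(c))):
        sp_id = f"sp{ci + 1:03d}"
        for s in cl:
            assignment[s] = sp_id
    return SpeciesAssignment(
        assignment=assignment,
        provisional_species=list(species),
        threshold=None if np.isinf(threshold) else float(threshold),
        outlier_species=outliers,
        origin=origins,
    )


def _midpoint_root_if_unrooted(tree: dendropy.Tree) -> dendropy.Tree:
    if tree.is_rooted:
        return tree
    has_lengths = all(
        e.length is not None
        for e in tree.preorder_edge_iter()
        if e.head_node is not tree.seed_node
    )
    if not has_lengths:
        return tree
    t = tree.clone(depth=1)
    t.reroot_at_midpoint(update_bipartitions=False)
    t.is_rooted = True
    return t


def delimit(
    gene_trees: list[dendropy.Tree],
    D: DistanceMatrix,
    reroot_midpoint: bool = True,
) -> SpeciesAssignment:
    """Full delimitation: concordant lineages -> provisional species ->
    divergence threshold -> rescue of remaining specimens.

    Trees parsed without an explicit rooted flag are midpoint-rooted first
    when they carry branch lengths (disable with ``reroot_midpoint=False``).
    Deterministic given inputs.
    """
    trees = [_midpoint_root_if_unrooted(t) if reroot_midpoint else t for t in gene_trees]
    lineages = independent_lineages(trees)
    species = provisional_species(lineages)
    thr = divergence_threshold(species, D)
    specimens = sorted(set().union(*[
        {lf.taxon.label for lf in t.leaf_node_iter()} for t in trees
    ]))
    return assign_remaining(specimens, species, thr, D)
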