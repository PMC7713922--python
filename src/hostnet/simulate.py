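"""Synthetic survey generator with known ground truth.

Emulates a canopy-crane survey of sessile herbivores: individual host
trees nested in a species/genus/family taxonomy, insect species with
heterogeneous diet breadths, binary host use with tunable phylogenetic
signal (Brownian liabilities crossing a threshold), per-tree abundance
counts with a tunable diet-breadth effect, and three gene trees with
tunable concordance around a known species partition.

Default parameter values mirror the scale and effect directions of a
single tropical survey site: ~50 insect species on ~90 trees spanning ~50
host species in ~27 families, intermediate phylogenetic signal, no
diet-breadth effect on abundance, and a modest positive effect on patch
occupancy.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .alignment import concatenate_supermatrix
from .datamodel import Alignment, LinkTable
from .signal import HostUseMatrix, phylo_vcv

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic survey, with single-site defaults."""

    seed: int = 0
    site: str = "SiteA"
    n_insect_species: int = 50
    n_trees: int = 90
    n_host_species: int = 53
    species_per_genus: int = 1
    genera_per_family: int = 2
    h2: float = 0.5
    regime: str = "mixed"  # random | specialist | mixed
    prevalence: float = 0.15
    lam: float = 3.0  # mean abundance per colonized tree
    beta_abund: float = 0.0
    beta_occ: float = 0.2
    occupancy_base: float = 0.5  # colonization probability at mean breadth
    concordance: float = 1.0
    specimens_per_species: int = 4
    locus_dropout: float = 0.2
    seq_length: int = 600

    def __post_init__(self) -> None:
        if min(self.n_insect_species, self.n_trees, self.n_host_species,
               self.species_per_genus, self.genera_per_family,
               self.specimens_per_species) < 1:
            raise ValueError("all counts must be >= 1")
        for p in (self.h2, self.prevalence, self.concordance,
                  self.locus_dropout, self.occupancy_base):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.regime not in ("random", "specialist", "mixed"):
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every generated dataset."""

    partition: list[frozenset] | None = None
    host_use: HostUseMatrix | None = None
    h2: float | None = None
    beta_abund: float | None = None
    beta_occ: float | None = None
    config: GeneratorConfig | None = None


def simulate_insect_tree(
    n: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    max_retries: int = 100,
) -> dendropy.Tree:
    """Ultrametric birth-death tree over ``n`` extant tips, depth 1.

    Tip labels are t1..tn. Complete extinction during simulation triggers
    a retry (the attempt count is recorded on the tree as
    ``tree.n_retries``).
    """
    from dendropy.model import birthdeath

    if n < 2:
        raise ValueError("need n >= 2 tips")
    rng = np.random.default_rng(rng)
    if n == 2:
        tree = dendropy.Tree.get(data="(t1:1,t2:1);", schema="newick")
        tree.is_rooted = True
        tree.n_retries = 0
        return tree
    pyrng = _pyrandom.Random(int(rng.integers(0, 2**31 - 1)))
    retries = 0
    tree = None
    for _ in range(max_retries):
        try:
            tree = birthdeath.birth_death_tree(
                birth_rate,
                death_rate,
                num_extant_tips=n,
                rng=pyrng,
                repeat_until_success=False,
            )
            break
        except Exception:
            retries += 1
    if tree is None:
        raise RuntimeError(f"birth-death simulation failed after {max_retries} tries")
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
    tree.seed_node.edge.length = None  # drop pre-split waiting time
    # normalize depth to 1
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    scale = max(depths)
    if scale > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= scale
    tree.is_rooted = True
    tree.n_retries = retries
    return tree


def make_host_taxonomy(
    n_host_species: int, species_per_genus: int = 1, genera_per_family: int = 2
) -> pd.DataFrame:
    """Nested host taxonomy: host species hs001... grouped into genera and
    families by the given shape."""
    rows = []
    for i in range(n_host_species):
        g = i // species_per_genus
        f = g // genera_per_family
        rows.append(
            {
                "host_species": f"hs{i + 1:03d}",
                "host_genus": f"hg{g + 1:03d}",
                "host_family": f"hf{f + 1:03d}",
            }
        )
    return pd.DataFrame(rows)


def make_census(
    taxonomy: pd.DataFrame,
    n_trees: int,
    rng: np.random.Generator,
    site: str = "SiteA",
) -> pd.DataFrame:
    """Assign ``n_trees`` individual trees to host species.

    Every host species gets one tree (as in a first sampling round over
    one individual per species); remaining trees go to randomly chosen
    species, so common species carry several individuals.
    """
    n_sp = len(taxonomy)
    counts = np.ones(n_sp, dtype=int)
    extra = n_trees - n_sp
    if extra < 0:
        keep = rng.choice(n_sp, size=n_trees, replace=False)
        counts = np.zeros(n_sp, dtype=int)
        counts[keep] = 1
    elif extra > 0:
        for i in rng.integers(0, n_sp, size=extra):
            counts[i] += 1
    rows = []
    t = 0
    for i, c in enumerate(counts):
        for _ in range(c):
            t += 1
            rows.append({"site": site, "tree_id": f"T{t:04d}",
                         **taxonomy.iloc[i].to_dict()})
    return pd.DataFrame(rows)


def simulate_liability_trait(
    tree: dendropy.Tree,
    h2: float,
    rng: np.random.Generator | None = None,
    prevalence: float = 0.3,
    threshold_mode: str = "rank",
) -> tuple[list[str], np.ndarray]:
    """One binary trait from a thresholded Brownian liability.

    Returns (tip ids, 0/1 vector): liability = sqrt(h2) * correlated +
    sqrt(1-h2) * iid normal. ``threshold_mode='rank'`` marks the top
    ``prevalence`` fraction of species as users (exact prevalence);
    ``'quantile'`` thresholds each tip independently at the standard-normal
    (1 - prevalence) quantile, so tip states follow the bivariate-normal
    orthant probabilities exactly. Used for parameter-recovery studies of
    the signal model; unlike :func:`simulate_host_use` no zero-row repair
    applies.
    """
    from scipy.special import ndtri

    rng = np.random.default_rng(rng)
    ids, V = phylo_vcv(tree)
    n = len(ids)
    Vn = V / V.diagonal().mean()
    lam, Q = np.linalg.eigh((Vn + Vn.T) / 2.0)
    root = Q * np.sqrt(np.clip(lam, 0, None))
    liab = np.sqrt(h2) * (root @ rng.standard_normal(n)) + np.sqrt(
        1.0 - h2
    ) * rng.standard_normal(n)
    if threshold_mode == "quantile":
        scale = np.sqrt(h2 * Vn.diagonal() + (1.0 - h2))
        y = (liab > ndtri(1.0 - prevalence) * scale).astype(np.int8)
    else:
        k = max(1, int(round(prevalence * n)))
        y = np.zeros(n, dtype=np.int8)
        y[np.argsort(-liab)[:k]] = 1
    return ids, y


def simulate_host_use(
    tree: dendropy.Tree,
    taxa: list[str],
    h2: float = 0.5,
    regime: str = "random",
    rng: np.random.Generator | None = None,
    prevalence: float = 0.15,
    taxon_groups: dict[str, str] | None = None,
) -> tuple[HostUseMatrix, SyntheticTruth]:
    """Binary host use from thresholded Brownian liabilities.

    Per host taxon, liabilities are sqrt(h2) * (phylogenetically
    correlated normal) + sqrt(1-h2) * (iid normal); the top
    ``prevalence`` fraction of species (at least one) use the taxon.
    ``regime='specialist'`` then confines each species to the single
    taxon group (family, via ``taxon_groups``) where its liability is
    highest; ``'mixed'`` applies that to half of the species. All-zero
    rows are repaired by granting the species its maximum-liability taxon.
    """
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must be in [0, 1]")
    rng = np.random.default_rng(rng)
    ids, V = phylo_vcv(tree)
    n = len(ids)
    Vn = V / V.diagonal().mean()
    # sample correlated deviates through the eigendecomposition
    lam, Q = np.linalg.eigh((Vn + Vn.T) / 2.0)
    root = Q * np.sqrt(np.clip(lam, 0, None))
    k = len(taxa)
    L = np.sqrt(h2) * (root @ rng.standard_normal((n, k))) + np.sqrt(
        1.0 - h2
    ) * rng.standard_normal((n, k))

    n_users = max(1, int(round(prevalence * n)))
    M = np.zeros((n, k), dtype=np.int8)
    for j in range(k):
        top = np.argsort(-L[:, j])[:n_users]
        M[top, j] = 1

    groups = taxon_groups or {t: t for t in taxa}
    group_labels = sorted(set(groups.values()))
    group_cols = {
        g: [j for j, t in enumerate(taxa) if groups[t] == g] for g in group_labels
    }
    if regime in ("specialist", "mixed"):
        if regime == "mixed":
            special = rng.permutation(n)[: n // 2]
        else:
            special = np.arange(n)
        for i in special:
            sums = {g: L[i, cols].max() for g, cols in group_cols.items()}
            g_best = max(sums, key=lambda g: (sums[g], g))
            keep = set(group_cols[g_best])
            for j in range(k):
                if j not in keep:
                    M[i, j] = 0
            if M[i, list(keep)].sum() == 0:
                M[i, max(keep, key=lambda j: L[i, j])] = 1

    for i in range(n):
        if M[i].sum() == 0:
            M[i, int(np.argmax(L[i]))] = 1

    hum = HostUseMatrix(list(ids), list(taxa), M)
    return hum, SyntheticTruth(host_use=hum, h2=h2)


def simulate_link_table(
    M: HostUseMatrix,
    census: pd.DataFrame,
    lam: float = 3.0,
    beta_abund: float = 0.0,
    beta_occ: float = 0.0,
    occupancy_base: float = 0.5,
    rng: np.random.Generator | None = None,
) -> LinkTable:
    """Colonization and abundance draws over the surveyed trees.

    For each (insect species, usable tree) pair (host species in the
    species' true range), the tree is colonized with probability
    logistic(logit(occupancy_base) + beta_occ * (breadth - mean breadth));
    colonized trees receive 1 + Poisson(max(lam * exp(beta_abund *
    centered breadth) - 1, 0)) adult females, guaranteeing a count >= 1.
    A species whose draws all fail is granted one colonized tree so every
    true species is observed.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    rng = np.random.default_rng(rng)
    breadth = M.values.sum(axis=1).astype(float)
    b_c = breadth - breadth.mean()
    alpha = np.log(occupancy_base / (1.0 - occupancy_base))
    taxon_idx = {t: j for j, t in enumerate(M.taxa)}

    rows = []
    census = census.reset_index(drop=True)
    tree_info = census.to_dict("records")
    for i, sp in enumerate(M.species):
        p_col = 1.0 / (1.0 + np.exp(-(alpha + beta_occ * b_c[i])))
        mu_extra = max(lam * np.exp(beta_abund * b_c[i]) - 1.0, 0.0)
        colonized = []
        for tr in tree_info:
            j = taxon_idx.get(tr["host_species"])
            if j is None or M.values[i, j] == 0:
                continue
            if rng.random() < p_col:
                colonized.append(tr)
        if not colonized:
            usable = [tr for tr in tree_info
                      if taxon_idx.get(tr["host_species"]) is not None
                      and M.values[i, taxon_idx[tr["host_species"]]] == 1]
            if usable:
                colonized = [usable[rng.integers(0, len(usable))]]
        for tr in colonized:
            count = 1 + int(rng.poisson(mu_extra))
            rows.append(
                {
                    "site": tr["site"],
                    "tree_id": tr["tree_id"],
                    "host_species": tr["host_species"],
                    "host_genus": tr["host_genus"],
                    "host_family": tr["host_family"],
                    "insect_species": sp,
                    "life_stage": "adult_female",
                    "count": count,
                }
            )
    return LinkTable(pd.DataFrame(rows))


# -- gene trees and sequences -------------------------------------------


def _random_binary_subtree(
    labels: list[str], rng: np.random.Generator, namespace: dendropy.TaxonNamespace,
    depth_scale: float = 0.004,
) -> dendropy.Node:
    """Random shallow binary subtree over specimen labels (tiny branches)."""
    nodes = []
    for lab in labels:
        taxon = namespace.require_taxon(label=lab)
        nd = dendropy.Node(taxon=taxon)
        nd.edge.length = float(rng.uniform(0.2, 1.0)) * depth_scale
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.2, 1.0)) * depth_scale
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def _nni(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    """One random nearest-neighbour interchange on an internal edge."""
    internal = [
        nd
        for nd in tree.preorder_node_iter()
        if not nd.is_leaf()
        and nd.parent_node is not None
        and nd.parent_node.parent_node is not None
    ]
    if not internal:
        return
    nd = internal[rng.integers(0, len(internal))]
    parent = nd.parent_node
    siblings = [c for c in parent.child_nodes() if c is not nd]
    if not siblings:
        return
    sib = siblings[rng.integers(0, len(siblings))]
    child = nd.child_nodes()[rng.integers(0, len(nd.child_nodes()))]
    nd.remove_child(child)
    parent.remove_child(sib)
    nd.add_child(sib)
    parent.add_child(child)


def _evolve_sequences(
    tree: dendropy.Tree, length: int, rng: np.random.Generator
) -> dict[str, str]:
    """Jukes-Cantor-style sequence sampling along the tree."""
    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.integers(0, 4, size=length)
    out = {}
    for node in tree.preorder_node_iter():
        if node is root:
            parent_seq = seqs[id(root)]
        else:
            parent_seq = seqs[id(node.parent_node)]
            d = node.edge.length or 0.0
            p_sub = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            seq = parent_seq.copy()
            hit = rng.random(length) < p_sub
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()))
                seq[hit] = (seq[hit] + shift) % 4
            seqs[id(node)] = seq
        if node.is_leaf():
            arr = _BASES[seqs[id(node)]]
            out[node.taxon.label] = arr.tobytes().decode()
    return out


def simulate_gene_trees(
    partition: list[frozenset] | list[set],
    concordance: float = 1.0,
    rng: np.random.Generator | None = None,
    locus_dropout: float = 0.0,
    seq_length: int = 600,
    species_tree_depth: float = 0.1,
    min_species_branch: float = 0.03,
    small_species_extra_depth: float = 0.5,
) -> tuple[list[dendropy.Tree], Alignment, SyntheticTruth]:
    """Three gene trees and a supermatrix around a known species partition.

    A species tree is simulated, scaled to ``species_tree_depth``, and
    every species-level terminal branch raised to ``min_species_branch``
    (species with fewer than three specimens get
    ``small_species_extra_depth`` more, so they are rescuable by the
    divergence threshold). The depths are kept shallow so substitution
    saturation cannot compress between-cluster p-distances past the
    singletons' extra divergence. Each gene tree clones the species tree,
    applies one species-level NNI with probability (1 - concordance), and
    replaces each species tip with a shallow specimen subtree (shared
    topology across loci, tip divergence <= 0.01). Sequences evolve along
    each gene tree; specimens are dropped from a locus with probability
    ``locus_dropout`` but always remain in >= 2 loci. The supermatrix
    concatenates the per-locus alignments.
    """
    rng = np.random.default_rng(rng)
    parts = [sorted(p) for p in partition]
    n_sp = len(parts)
    if n_sp < 2:
        raise ValueError("need at least two species in the partition")
    species_tree = simulate_insect_tree(n_sp, rng=rng)
    # rescale, then enforce separation on terminal branches
    for edge in species_tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= species_tree_depth
    for i, leaf in enumerate(species_tree.leaf_node_iter()):
        leaf.taxon.label = f"SP{i + 1}"
        leaf.edge.length = max(leaf.edge.length or 0.0, min_species_branch)
        if len(parts[i]) < 3:
            leaf.edge.length += small_species_extra_depth

    within_topologies = {i: None for i in range(n_sp)}  # shared across loci
    sub_rngs = [np.random.default_rng(rng.integers(0, 2**31 - 1)) for _ in range(n_sp)]

    # locus presence: each specimen in >= 2 of 3 loci
    all_specimens = [s for p in parts for s in p]
    presence = {s: [True, True, True] for s in all_specimens}
    for s in all_specimens:
        if rng.random() < locus_dropout:
            presence[s][int(rng.integers(0, 3))] = False

    gene_trees: list[dendropy.Tree] = []
    alignments: list[Alignment] = []
    for locus in range(3):
        gt = species_tree.clone(depth=1)
        if rng.random() > concordance:
            _nni(gt, rng)
        ns = gt.taxon_namespace
        for leaf in list(gt.leaf_node_iter()):
            i = int(leaf.taxon.label[2:]) - 1
            members = [s for s in parts[i] if presence[s][locus]]
            if not members:
                members = [parts[i][0]]
            sub_rng = np.random.default_rng(sub_rngs[i].integers(0, 2**31 - 1))
            if len(members) == 1:
                leaf.taxon = ns.require_taxon(label=members[0])
            else:
                sub = _random_binary_subtree(members, sub_rng, ns)
                stem = leaf.edge.length
                parent = leaf.parent_node
                parent.remove_child(leaf)
                sub.edge.length = stem
                parent.add_child(sub)
        gt.is_rooted = True
        seqs = _evolve_sequences(gt, seq_length, rng)
        labels = sorted(seqs)
        alignments.append(Alignment(ids=labels, seqs=[seqs[l] for l in labels]))
        gene_trees.append(gt)

    supermatrix, _ = concatenate_supermatrix(alignments)
    truth = SyntheticTruth(partition=[frozenset(p) for p in parts])
    return gene_trees, supermatrix, truth


@dataclass
class SyntheticDataset:
    """Everything one generated survey provides to the pipeline."""

    config: GeneratorConfig
    link_table: LinkTable
    census: pd.DataFrame
    insect_tree: dendropy.Tree
    host_use: HostUseMatrix
    truth: SyntheticTruth
    gene_trees: list[dendropy.Tree] = field(default_factory=list)
    supermatrix: Alignment | None = None


def generate_dataset(
    config: GeneratorConfig | None = None,
    with_gene_trees: bool = False,
) -> SyntheticDataset:
    """Run the full generator from one config (deterministic given seed)."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    taxonomy = make_host_taxonomy(
        cfg.n_host_species, cfg.species_per_genus, cfg.genera_per_family
    )
    census = make_census(taxonomy, cfg.n_trees, rng, site=cfg.site)
    tree = simulate_insect_tree(cfg.n_insect_species, rng=rng)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"i{i + 1:03d}"
    groups = dict(zip(taxonomy["host_species"], taxonomy["host_family"]))
    host_use, truth = simulate_host_use(
        tree,
        list(taxonomy["host_species"]),
        h2=cfg.h2,
        regime=cfg.regime,
        rng=rng,
        prevalence=cfg.prevalence,
        taxon_groups=groups,
    )
    lt = simulate_link_table(
        host_use,
        census,
        lam=cfg.lam,
        beta_abund=cfg.beta_abund,
        beta_occ=cfg.beta_occ,
        occupancy_base=cfg.occupancy_base,
        rng=rng,
    )
    truth.beta_abund = cfg.beta_abund
    truth.beta_occ = cfg.beta_occ
    truth.config = cfg
    ds = SyntheticDataset(
        config=cfg,
        link_table=lt,
        census=census,
        insect_tree=tree,
        host_use=host_use,
        truth=truth,
    )
    if with_gene_trees:
        observed = sorted(set(lt.establishment_view["insect_species"]))
        partition = [
            frozenset(f"{sp}_s{k + 1}" for k in range(cfg.specimens_per_species))
            for sp in observed
        ]
        gts, sm, gtruth = simulate_gene_trees(
            partition,
            concordance=cfg.concordance,
            rng=rng,
            locus_dropout=cfg.locus_dropout,
            seq_length=cfg.seq_length,
        )
        ds.gene_trees = gts
        ds.supermatrix = sm
        truth.partition = gtruth.partition
    return ds
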