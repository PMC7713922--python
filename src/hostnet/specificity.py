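"""Diet-specificity test: Simpson's Reciprocal Diversity Index of hosts
per insect species versus a permutation null.

For each insect species the hosts it colonizes are tallied as individual
trees per host taxon (at a chosen taxonomic level); Simpson's RDI
1 / sum(p_i^2) is the effective number of host taxa used. The community
statistic is the mean RDI over insect species. The null model randomly
permutes the associations between insect species and individual trees:
the species-by-tree colonization incidence is shuffled by checkerboard
swaps, conserving per-tree link counts and every species' number of
colonized trees while keeping the table a valid incidence (a species is
never placed on the same tree twice, so null tables are exchangeable with
the observed one under random host use). A Z test against the permuted
mean RDIs gives the significance of specialization (negative Z: species
use less diverse hosts than expected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import LinkTable
from .signal import swap_null
from .stats import z_test


@dataclass
class SpecificityResult:
    site: str
    level: str
    empirical_mean_rdi: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_permutations: int
    degenerate: bool = False

    def as_row(self) -> dict:
        return {
            "site": self.site,
            "level": self.level,
            "empirical_1_over_D": self.empirical_mean_rdi,
            "null_1_over_D": self.null_mean,
            "Z": self.z,
            "p": self.p,
        }


def simpson_rdi(counts) -> float:
    """Simpson's Reciprocal Diversity Index, 1 / sum(p_i^2).

    ``counts`` maps taxa to positive counts (a dict, Series or array).
    Equals the effective number of equally used taxa: 1 for a single
    taxon, k for k equally used taxa.
    """
    c = np.asarray(
        list(counts.values()) if isinstance(counts, dict) else counts, dtype=float
    )
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("simpson_rdi needs at least one positive count")
    p = c / c.sum()
    return float(1.0 / np.sum(p * p))


def host_rdi_per_insect(lt: LinkTable, level: str) -> dict[str, float]:
    """RDI of colonized trees per host taxon, for each insect species."""
    links = lt.colonization_links(level)
    out = {}
    for sp, grp in links.groupby("insect_species"):
        counts = grp.groupby("host_taxon")["tree_id"].nunique()
        out[sp] = simpson_rdi(counts.to_numpy())
    return out


def _incidence(lt: LinkTable):
    """Species x tree binary colonization incidence plus index arrays."""
    links = lt.colonization_links()
    species = sorted(links["insect_species"].unique())
    trees = sorted(links["tree_id"].unique())
    si = {s: i for i, s in enumerate(species)}
    ti = {t: i for i, t in enumerate(trees)}
    A = np.zeros((len(species), len(trees)), dtype=np.int8)
    for s, t in zip(links["insect_species"], links["tree_id"]):
        A[si[s], ti[t]] = 1
    return A, species, trees, links


def _mean_rdi_incidence(A: np.ndarray, taxon_indicator: np.ndarray) -> float:
    """Mean RDI over species rows; taxon_indicator is trees x taxa 0/1."""
    C = A @ taxon_indicator
    tot = C.sum(axis=1, keepdims=True)
    frac = np.divide(C, tot, out=np.zeros_like(C, dtype=float), where=tot > 0)
    p2 = (frac**2).sum(axis=1)
    return float(np.mean(1.0 / p2))


def permute_associations(lt: LinkTable, rng: np.random.Generator) -> LinkTable:
    """Randomly permute the species-by-tree colonization associations.

    Checkerboard swaps on the binary incidence (10x the number of links)
    conserve per-tree link counts and the multiset of species labels
    exactly, and never place a species twice on one tree. Tree taxonomy
    travels with the tree. Counts are reset to 1 in the permuted table
    (association structure, not abundance, is what the null randomizes).
    Deterministic given the generator state.
    """
    A, species, trees, links = _incidence(lt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        B = swap_null(A, rng=rng, warn=False)
    tt = lt.tree_taxonomy().set_index("tree_id")
    rows = []
    for i, j in zip(*np.nonzero(B)):
        t = trees[j]
        info = tt.loc[t]
        rows.append(
            {
                "site": info["site"],
                "tree_id": t,
                "host_species": info["host_species"],
                "host_genus": info["host_genus"],
                "host_family": info["host_family"],
                "insect_species": species[i],
                "life_stage": "adult_female",
                "count": 1,
            }
        )
    return LinkTable(pd.DataFrame(rows))


def specificity_test(
    lt: LinkTable,
    level: str,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
    site: str = "",
) -> SpecificityResult:
    """Mean host RDI versus the association-permutation null, two-sided Z.

    A negative Z means insect species use less diverse hosts than expected
    under random colonization, i.e. diet specialization.
    """
    rng = np.random.default_rng(rng)
    A, species, trees, links = _incidence(lt)
    if len(species) < 2:
        raise ValueError("specificity test needs at least two insect species")
    taxon_of = lt.taxon_of(level)
    taxa = sorted({taxon_of[t] for t in trees})
    ti = {t: i for i, t in enumerate(taxa)}
    indicator = np.zeros((len(trees), len(taxa)))
    for j, t in enumerate(trees):
        indicator[j, ti[taxon_of[t]]] = 1.0

    empirical = _mean_rdi_incidence(A, indicator)
    nulls = np.empty(n_permutations)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_permutations):
            nulls[i] = _mean_rdi_incidence(
                swap_null(A, rng=rng, warn=False), indicator
            )
    m, s, z, p = z_test(empirical, nulls)
    degenerate = s == 0.0
    if degenerate:
        warnings.warn("degenerate permutation null (sd = 0) in specificity test")
    if not site:
        site = ",".join(sorted(links["site"].unique()))
    return SpecificityResult(
        site=site,
        level=level,
        empirical_mean_rdi=empirical,
        null_mean=m,
        null_sd=s,
        z=z,
        p=p,
        n_permutations=n_permutations,
        degenerate=degenerate,
    )
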