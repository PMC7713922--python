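"""Alignment post-processing and pairwise divergences.

Gap-threshold trimming keeps only columns with non-missing sequence for at
least a given fraction of specimens; per-locus alignments concatenate into
a supermatrix over the union of specimens, with gaps filling missing loci.
Divergence between specimens is measured either as uncorrected p-distance
on the (trimmed) supermatrix or as patristic distance on a supplied tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .datamodel import Alignment, ValidationError

# characters counted as informative; gaps, N and ambiguity codes are missing
_CERTAIN = (b"A", b"C", b"G", b"T")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise divergence matrix with possibly-missing entries.

    Missing comparisons (no comparable sites) are NaN; the diagonal is zero.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        self.values = v
        self._index = {s: i for i, s in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def missing_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.values[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _certain_mask(arr: np.ndarray) -> np.ndarray:
    m = np.zeros(arr.shape, dtype=bool)
    for c in _CERTAIN:
        m |= arr == c
    return m


def trim_alignment(aln: Alignment, min_nongap_fraction: float = 0.8) -> Alignment:
    """Keep only columns with non-missing characters in at least
    ``min_nongap_fraction`` of specimens (boundary inclusive).

    Gaps, N and ambiguity codes all count as missing. Column order is
    preserved; trimming is idempotent.
    """
    if not 0 < min_nongap_fraction <= 1:
        raise ValueError("min_nongap_fraction must be in (0, 1]")
    if len(aln) == 0:
        raise ValidationError("cannot trim an empty alignment")
    arr = aln.as_array()
    frac = _certain_mask(arr).mean(axis=0)
    keep = frac >= min_nongap_fraction - 1e-12
    kept = arr[:, keep]
    seqs = [row.tobytes().decode() for row in kept]
    return Alignment(ids=list(aln.ids), seqs=seqs)


def concatenate_supermatrix(alns: list[Alignment]) -> tuple[Alignment, pd.DataFrame]:
    """Concatenate per-locus alignments over the union of specimens.

    Specimens absent from a locus get an all-gap segment. Returns the
    supermatrix and a partition table of 1-based inclusive column ranges,
    one row per locus.
    """
    if not alns:
        raise ValidationError("need at least one alignment")
    ids: list[str] = []
    for aln in alns:
        for i in aln.ids:
            if i not in ids:
                ids.append(i)
    parts = []
    start = 1
    segments = {i: [] for i in ids}
    for k, aln in enumerate(alns):
        L = aln.n_sites
        lookup = dict(zip(aln.ids, aln.seqs))
        for i in ids:
            segments[i].append(lookup.get(i, "-" * L))
        parts.append({"locus": k + 1, "start": start, "end": start + L - 1})
        start += L
    seqs = ["".join(segments[i]) for i in ids]
    return Alignment(ids=ids, seqs=seqs), pd.DataFrame(parts)


def p_distance(aln: Alignment) -> DistanceMatrix:
    """Uncorrected pairwise divergence: mismatches / comparable sites.

    A site is comparable for a pair when both rows carry an unambiguous
    nucleotide there. Pairs with zero comparable sites (including any
    all-gap specimen) are NaN rather than silently zero.
    """
    arr = aln.as_array()
    n = len(aln)
    cert = _certain_mask(arr)
    vals = np.zeros((n, n), dtype=float)
    for i in range(n):
        both = cert[i] & cert[i + 1:]
        comp = both.sum(axis=1).astype(float)
        mism = ((arr[i] != arr[i + 1:]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(comp > 0, mism / np.maximum(comp, 1), np.nan)
        vals[i, i + 1:] = d
        vals[i + 1:, i] = d
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(aln.ids), vals)


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Sum of branch lengths along the path between every leaf pair."""
    leaves = list(tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if edge.length is None and head is not tree.seed_node:
            raise ValidationError("tree has a branch without a length")
    pdm = tree.phylogenetic_distance_matrix()
    ids = [lf.taxon.label for lf in leaves]
    n = len(ids)
    vals = np.zeros((n, n), dtype=float)
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
        vals[i, j] = vals[j, i] = d
    return DistanceMatrix(ids, vals)
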