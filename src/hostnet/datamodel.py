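"""Core domain types for bipartite host-use survey data.

The central object is the :class:`LinkTable`, a long-format record of
herbivore occurrences on individual, taxonomically labelled host trees.
Sessile herbivores such as armored scale insects settle permanently after
their first-instar dispersal stage, so only later life stages (second
instars and adult females) evidence successful establishment on a host;
every downstream statistic therefore operates on the establishment view of
the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LIFE_STAGES = ("first_instar", "second_instar", "adult_female", "other")
ESTABLISHMENT_STAGES = ("second_instar", "adult_female")
LEVELS = ("species", "genus", "family")

LINK_COLUMNS = (
    "site",
    "tree_id",
    "host_species",
    "host_genus",
    "host_family",
    "insect_species",
    "life_stage",
    "count",
)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def level_column(level: str) -> str:
    if level not in LEVELS:
        raise ValueError(f"unknown host-taxonomy level {level!r}; expected one of {LEVELS}")
    return f"host_{level}"


@dataclass(frozen=True)
class OccurrenceRecord:
    """One observation of an insect species on an individual host tree."""

    site: str
    tree_id: str
    host_species: str
    host_genus: str
    host_family: str
    insect_species: str
    life_stage: str
    count: int

    def __post_init__(self) -> None:
        if self.life_stage not in LIFE_STAGES:
            raise ValidationError(
                f"life_stage {self.life_stage!r} not in {LIFE_STAGES} (tree {self.tree_id})"
            )
        if self.count < 0:
            raise ValidationError(f"negative count on tree {self.tree_id}")


class LinkTable:
    """Long-format table of (site, tree, host taxonomy, insect, stage, count).

    Duplicate (site, tree, insect, stage) rows are aggregated by summing
    counts on construction. The ``establishment_view`` property exposes the
    sub-table restricted to second instars and adult females, which is the
    only part downstream statistics consume.
    """

    def __init__(self, df: pd.DataFrame):
        self._df = _validate_links(df)

    @classmethod
    def from_records(cls, records: Iterable[OccurrenceRecord]) -> "LinkTable":
        rows = [vars(r) for r in records]
        return cls(pd.DataFrame(rows, columns=list(LINK_COLUMNS)))

    @property
    def records(self) -> pd.DataFrame:
        """All records, including non-establishment life stages."""
        return self._df.copy()

    @property
    def establishment_view(self) -> pd.DataFrame:
        return self._df[self._df["life_stage"].isin(ESTABLISHMENT_STAGES)].reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinkTable):
            return NotImplemented
        a = self._df.sort_values(list(LINK_COLUMNS)).reset_index(drop=True)
        b = other._df.sort_values(list(LINK_COLUMNS)).reset_index(drop=True)
        return a.equals(b)

    # -- derived views ----------------------------------------------------

    def tree_taxonomy(self) -> pd.DataFrame:
        """One row per tree: site, tree_id and the host taxonomy triple."""
        cols = ["site", "tree_id", "host_species", "host_genus", "host_family"]
        return self._df[cols].drop_duplicates().reset_index(drop=True)

    def taxon_of(self, level: str) -> Mapping[str, str]:
        """tree_id -> host taxon label at ``level``."""
        tt = self.tree_taxonomy()
        return dict(zip(tt["tree_id"], tt[level_column(level)]))

    def colonization_links(self, level: str | None = None) -> pd.DataFrame:
        """One row per (insect species, colonized tree) establishment link.

        Colonization is defined tree-wise: a species colonizes a tree if it
        has at least one establishment-stage record there, regardless of
        count. When ``level`` is given, a ``host_taxon`` column carries the
        tree's taxon at that level.
        """
        ev = self.establishment_view
        links = (
            ev.groupby(["site", "tree_id", "insect_species"], as_index=False)["count"]
            .sum()
            .rename(columns={"count": "abundance"})
        )
        tt = self.tree_taxonomy()
        links = links.merge(tt, on=["site", "tree_id"], how="left")
        if level is not None:
            links["host_taxon"] = links[level_column(level)]
        return links

    def to_tsv(self, path) -> None:
        self._df.to_csv(path, sep="\t", index=False)


def _validate_links(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LINK_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"link table missing column(s): {missing}")
    df = df[list(LINK_COLUMNS)].copy()
    for col in LINK_COLUMNS[:-1]:
        df[col] = df[col].astype(str)

    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 0) | (counts != counts.round())]
    if len(bad):
        raise ValidationError(
            f"count must be a nonnegative integer; offending row index {bad[0]} "
            f"(tree {df.loc[bad[0], 'tree_id']})"
        )
    df["count"] = counts.astype(int)

    bad_stage = df.index[~df["life_stage"].isin(LIFE_STAGES)]
    if len(bad_stage):
        i = bad_stage[0]
        raise ValidationError(
            f"life_stage {df.loc[i, 'life_stage']!r} at row {i} not one of {LIFE_STAGES}"
        )

    # each tree maps to exactly one taxonomy triple
    tax = df[["tree_id", "host_species", "host_genus", "host_family"]].drop_duplicates()
    dup = tax["tree_id"].duplicated()
    if dup.any():
        t = tax.loc[dup, "tree_id"].iloc[0]
        raise ValidationError(f"tree {t!r} appears with conflicting host taxonomy")

    # taxonomy is hierarchical: species -> one genus, genus -> one family
    sp = tax[["host_species", "host_genus"]].drop_duplicates()
    if sp["host_species"].duplicated().any():
        s = sp.loc[sp["host_species"].duplicated(), "host_species"].iloc[0]
        raise ValidationError(f"host species {s!r} maps to multiple genera")
    ge = tax[["host_genus", "host_family"]].drop_duplicates()
    if ge["host_genus"].duplicated().any():
        g = ge.loc[ge["host_genus"].duplicated(), "host_genus"].iloc[0]
        raise ValidationError(f"host genus {g!r} maps to multiple families")

    # aggregate duplicate (site, tree, insect, stage) rows
    key = ["site", "tree_id", "host_species", "host_genus", "host_family",
           "insect_species", "life_stage"]
    df = df.groupby(key, as_index=False, sort=False)["count"].sum()
    return df[list(LINK_COLUMNS)].reset_index(drop=True)


@dataclass
class Alignment:
    """A multiple sequence alignment: unique ids, equal-length rows.

    Characters are uppercase nucleotides, gaps ('-') and IUPAC ambiguity
    codes; 'U' is normalized to 'T' on construction.
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValidationError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            dups = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate sequence id(s): {dups}")
        self.seqs = [s.upper().replace("U", "T") for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValidationError(f"unequal sequence lengths: {sorted(lengths)}")

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def __len__(self) -> int:
        return len(self.ids)

    def as_array(self) -> np.ndarray:
        """(n_seqs, n_sites) array of single-byte characters."""
        if not self.seqs:
            return np.empty((0, 0), dtype="S1")
        return np.frombuffer("".join(self.seqs).encode(), dtype="S1").reshape(
            len(self.seqs), self.n_sites
        )


@dataclass
class TestReport:
    """A permutation-test result: empirical value vs. a simulated null.

    ``z`` is (empirical - null_mean) / null_sd and ``p`` the two-sided
    normal tail probability; ``significant_fdr`` is filled only where a
    multiple-testing correction applies.
    """

    context: dict
    empirical: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    significant_fdr: bool | None = None
    n_null: int = 0
    degenerate: bool = False

    def as_row(self) -> dict:
        row = dict(self.context)
        row.update(
            empirical=self.empirical,
            null_mean=self.null_mean,
            null_sd=self.null_sd,
            Z=self.z,
            p=self.p,
        )
        if self.significant_fdr is not None:
            row["significant_fdr"] = self.significant_fdr
        return row


@dataclass
class SpeciesAssignment:
    """Specimen -> delimited species partition with its provenance.

    ``origin`` records, per specimen, whether it came from a provisional
    concordance species, was rescued as a divergent singleton, or was linked
    to a cluster by the divergence threshold.
    """

    assignment: dict[str, str]
    provisional_species: list[frozenset]
    threshold: float | None
    outlier_species: list[frozenset] = field(default_factory=list)
    origin: dict[str, str] = field(default_factory=dict)

    def species(self) -> dict[str, frozenset]:
        out: dict[str, set] = {}
        for spec, sp in self.assignment.items():
            out.setdefault(sp, set()).add(spec)
        return {k: frozenset(v) for k, v in out.items()}

    def partition(self) -> set[frozenset]:
        return set(self.species().values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "specimen_id": spec,
                "species_id": sp,
                "origin": self.origin.get(spec, "provisional"),
            }
            for spec, sp in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows)
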