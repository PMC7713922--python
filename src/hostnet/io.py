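"""Readers and writers for the formats the pipeline touches: tab-separated
link tables, FASTA alignments, and Newick trees."""

from __future__ import annotations

import dendropy
import pandas as pd
from Bio import SeqIO

from .datamodel import Alignment, LinkTable, ValidationError


def read_link_table(path) -> LinkTable:
    """Read and validate a tab-separated occurrence table.

    Expects a header row with columns site, tree_id, host_species,
    host_genus, host_family, insect_species, life_stage, count. Duplicate
    rows are aggregated; structural violations raise ValidationError naming
    the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return LinkTable(df)


def write_link_table(lt: LinkTable, path) -> None:
    lt.to_tsv(path)


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Sequences are case-folded to uppercase and U is normalized to T.
    Duplicate ids or unequal lengths raise ValidationError.
    """
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise ValidationError(f"no sequences found in {path}")
    return Alignment(ids=ids, seqs=seqs)


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for i, s in zip(aln.ids, aln.seqs):
            fh.write(f">{i}\n{s}\n")


def read_newick(path_or_string) -> dendropy.Tree:
    """Read a Newick tree, checking for duplicate leaf labels.

    Accepts a file path or a raw Newick string. Underscores in labels are
    preserved verbatim.
    """
    from dendropy.dataio.newickreader import NewickReader

    s = str(path_or_string)
    try:
        if s.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=s, schema="newick", preserve_underscores=True)
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"duplicate leaf label(s): {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"duplicate leaf label(s): {dups}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValidationError("negative branch length")
    return tree


def newick_string(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths to 10 significant digits."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=False,
            unquoted_underscores=True,
            real_value_format_specifier=".10g",
        ).strip()
    )


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}
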