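"""File-format helpers: FASTA alignments, Newick trees, peak lists, TSV tables."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylo.tree import Tree


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_tree(path) -> Tree:
    return Tree.from_newick(Path(path).read_text())


def write_tree(tree: Tree, path, include_support: bool = False) -> None:
    Path(path).write_text(tree.to_newick(include_support=include_support) + "\n")
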