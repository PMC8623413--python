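"""File-format helpers: FASTA/FASTQ via Biopython, trees via dendropy, tables
via pandas."""

from __future__ import annotations

from typing import Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = (
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    )
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")}


def write_fastq(reads: Mapping[str, str], path, quality: int = 40) -> None:
    def records():
        for name, seq in reads.items():
            rec = SeqRecord(Seq(seq), id=name, description="")
            rec.letter_annotations["phred_quality"] = [quality] * len(seq)
            yield rec

    SeqIO.write(records(), str(path), "fastq")


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(str(path), sep="\t", index=False)


def read_depth_tsv(path) -> dict[str, "pd.Series"]:
    """Per-base depth table (scaffold, pos, depth) to per-scaffold arrays."""
    import numpy as np

    df = pd.read_csv(str(path), sep="\t", names=["scaffold", "pos", "depth"], header=None,
                     comment="#")
    if df.iloc[0]["scaffold"] == "scaffold":  # header present
        df = df.iloc[1:].reset_index(drop=True)
        df["pos"] = df["pos"].astype(int)
        df["depth"] = df["depth"].astype(float)
    out = {}
    for name, grp in df.groupby("scaffold"):
        length = int(grp["pos"].max()) + 1
        arr = np.zeros(length, dtype=float)
        arr[grp["pos"].to_numpy(dtype=int)] = grp["depth"].to_numpy(dtype=float)
        out[name] = arr
    return out
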