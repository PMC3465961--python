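"""Readers and writers for the formats the pipeline touches.

FASTA goes through Biopython; edge lists accept both bare two-column pairs
and three-column SIF ("geneA interacts geneB"); chemotaxis and ortholog-pool
tables are plain tab-delimited text handled by pandas.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import split_codons

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class CodonSequencePair:
    """A gap-free, in-frame pair of aligned coding sequences.

    Frame starts at position 1. Construction validates equal lengths,
    length divisible by 3, no gaps and no internal stop codons.
    """
    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"unequal sequence lengths: {len(self.seq_a)} vs {len(self.seq_b)}")
        for name, seq in ((self.id_a, self.seq_a), (self.id_b, self.seq_b)):
            if GAP_CHARS & set(seq):
                raise ValueError(f"gap characters in {name}; strip gaps first")
            split_codons(seq)  # raises on frame/stop/alphabet problems

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def reversed(self) -> "CodonSequencePair":
        return CodonSequencePair(self.id_b, self.id_a, self.seq_b, self.seq_a)


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into an order-preserving list of (id, sequence).

    Sequences are upper-cased and RNA U is mapped to T.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"empty FASTA file: {path}")
    if not text.lstrip().startswith(">"):
        raise ValueError(f"malformed FASTA (no '>' header) in {path}")
    records = [(rec.id, _normalize(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no records parsed from {path}")
    return records


def write_fasta(path, records: list[tuple[str, str]], width: int = 60) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def strip_gaps(aligned_a: str, aligned_b: str, mode: str = "codon") -> tuple[str, str]:
    """Remove gapped columns from a pairwise alignment.

    mode="nucleotide" drops every column where either sequence has a gap;
    mode="codon" drops whole codon columns (frame from position 1)
    containing any gap, preserving the reading frame.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences have unequal lengths")
    if mode == "nucleotide":
        keep = [i for i in range(len(aligned_a))
                if aligned_a[i] not in GAP_CHARS and aligned_b[i] not in GAP_CHARS]
        return ("".join(aligned_a[i] for i in keep),
                "".join(aligned_b[i] for i in keep))
    if mode == "codon":
        out_a, out_b = [], []
        # trailing partial codon columns are dropped with a warning
        if len(aligned_a) % 3:
            logger.warning("alignment length %d not divisible by 3; "
                           "trailing %d columns ignored", len(aligned_a), len(aligned_a) % 3)
        for i in range(0, len(aligned_a) - len(aligned_a) % 3, 3):
            ca, cb = aligned_a[i:i + 3], aligned_b[i:i + 3]
            if GAP_CHARS & set(ca + cb):
                continue
            out_a.append(ca)
            out_b.append(cb)
        return "".join(out_a), "".join(out_b)
    raise ValueError(f"unknown strip mode {mode!r}")


def read_edge_list(path) -> nx.Graph:
    """Read an undirected edge list (two-column, or three-column SIF with the
    interaction type in the middle). Duplicate and reversed-duplicate edges
    collapse to one undirected edge with a logged warning; self-loops are
    rejected."""
    G = nx.Graph()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                a, b = parts
            elif len(parts) == 3:
                a, _, b = parts
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop on {a}")
            if G.has_edge(a, b):
                n_dup += 1
                continue
            G.add_edge(a, b)
    if n_dup:
        logger.warning("%d duplicate edge(s) collapsed while reading %s", n_dup, path)
    return G


def write_edge_list(path, G: nx.Graph, sif: bool = True) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in G.edges()):
            fh.write(f"{a}\tinteracts\t{b}\n" if sif else f"{a}\t{b}\n")


CHEMOTAXIS_COLUMNS = ["gene", "neuron", "assay", "ci_wt", "ci_mut", "ci_diff", "n_odors"]


def read_chemotaxis_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(CHEMOTAXIS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"chemotaxis table missing columns: {sorted(missing)}")
    return df


def write_chemotaxis_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pool_table(path) -> pd.DataFrame:
    """Ortholog-pool table: pair_id, omega, tags (comma-separated, may be empty)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"pair_id": str}, keep_default_na=False)
    if not {"pair_id", "omega"} <= set(df.columns):
        raise ValueError("pool table needs columns pair_id, omega")
    df["omega"] = df["omega"].astype(float)
    if "tags" not in df.columns:
        df["tags"] = ""
    return df


def write_pool_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_config(path) -> dict[str, str]:
    """Flat key=value config file; '#' comments and blank lines ignored."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
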