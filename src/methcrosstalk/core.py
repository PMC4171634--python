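"""Core containers shared across the pipeline.

Coordinates are 0-based, half-open throughout (BED convention).  A tag is
recorded by its 5' position: for a plus-strand read this is the leftmost
aligned base, for a minus-strand read the rightmost aligned base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_NT_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_NT_CHARS = np.array(list("ACGTN"))


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGTN string as a uint8 array (A=0 C=1 G=2 T=3 N=4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.uint8)
    for base, code in _NT_CODES.items():
        out[arr == ord(base)] = code
    return out


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(_NT_CHARS[codes])


@dataclass
class TagLibrary:
    """A condition-labelled set of mapped sequencing tags.

    ``tags`` holds one row per tag with columns ``chrom`` (str), ``pos``
    (int, 5' position) and ``strand`` ('+'/'-').  ``size`` is the tag count.
    """

    condition: str
    tags: pd.DataFrame
    read_length: int = 50

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "strand"}
        if not required.issubset(self.tags.columns):
            raise ValueError(f"tag table must have columns {sorted(required)}")
        self.tags = self.tags.reset_index(drop=True)

    @property
    def size(self) -> int:
        return len(self.tags)

    def sorted(self) -> "TagLibrary":
        df = self.tags.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        return TagLibrary(self.condition, df.reset_index(drop=True), self.read_length)

    @classmethod
    def from_bed(cls, path, condition: str, read_length: int = 50) -> "TagLibrary":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=[0, 1, 2, 3, 4, 5],
            dtype={0: str, 1: np.int64, 2: np.int64},
        )
        pos = np.where(df["strand"].to_numpy() == "-", df["end"].to_numpy() - 1,
                       df["start"].to_numpy())
        tags = pd.DataFrame({"chrom": df["chrom"], "pos": pos, "strand": df["strand"]})
        return cls(condition, tags, read_length)

    def to_bed(self, path) -> None:
        t = self.tags
        minus = t["strand"].to_numpy() == "-"
        pos = t["pos"].to_numpy()
        start = np.where(minus, pos - self.read_length + 1, pos)
        start = np.maximum(start, 0)
        end = start + self.read_length
        out = pd.DataFrame({
            "chrom": t["chrom"], "start": start, "end": end,
            "name": "tag", "score": 0, "strand": t["strand"],
        })
        out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class GenomeAnnotation:
    """Coordinate frame for all classification steps.

    ``genes``: DataFrame with columns name, chrom, strand, tx_start, tx_end.
    ``cgis``: DataFrame with columns chrom, start, end, name.
    ``promoter_seqs``: gene name -> promoter-window sequence (TSS +/- 1 kb,
    forward strand).
    ``genome_seq``: optional chrom -> uint8-encoded sequence.
    """

    chrom_lengths: dict[str, int]
    genes: pd.DataFrame
    cgis: pd.DataFrame
    promoter_seqs: dict[str, str] = field(default_factory=dict)
    genome_seq: dict[str, np.ndarray] | None = None

    def sequence(self, chrom: str, start: int, end: int) -> str:
        if self.genome_seq is None:
            raise ValueError("annotation carries no genome sequence")
        start = max(0, start)
        end = min(self.chrom_lengths[chrom], end)
        return decode_sequence(self.genome_seq[chrom][start:end])


def read_bed(path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    """Read a BED-like tab-delimited file (first len(names) columns kept)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = list(names)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_refflat(path) -> pd.DataFrame:
    """Read a refFlat-style gene table (name, chrom, strand, txStart, txEnd)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["name", "chrom", "strand", "tx_start", "tx_end"],
        usecols=[0, 1, 2, 3, 4],
    )
    df["tx_start"] = df["tx_start"].astype(np.int64)
    df["tx_end"] = df["tx_end"].astype(np.int64)
    return df


def write_refflat(genes: pd.DataFrame, path) -> None:
    genes[["name", "chrom", "strand", "tx_start", "tx_end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
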