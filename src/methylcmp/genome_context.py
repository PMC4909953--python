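"""Reference genome handling and cytosine sequence-context classification.

In plants, DNA methylation is maintained in three sequence contexts defined
by the two bases immediately 3' of a cytosine on its own strand: CG, CHG and
CHH (H = A, T or C). Each context is serviced by a distinct methyltransferase
pathway (MET1, CMT3, CMT2/DRM2 respectively), so every downstream analysis
here is context-resolved. This module reads a reference genome and classifies
every cytosine on both strands.

Coordinates are 0-based throughout; intervals are half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

CONTEXTS = ("CG", "CHG", "CHH")

#: columns of a cytosine-site table
SITE_COLUMNS = ["chrom", "pos", "strand", "context"]

_VALID_BASES = frozenset(b"ACGTN")


@dataclass
class Genome:
    """An ordered collection of named chromosome sequences over {A,C,G,T,N}."""

    chromosomes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.chromosomes) == 0:
            return
        for name, seq in self.chromosomes.items():
            if not name:
                raise ValueError("chromosome names must be nonempty")
            if len(seq) == 0:
                raise ValueError(f"chromosome {name!r} has an empty sequence")

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}


def _sanitize(seq: str, name: str) -> str:
    """Uppercase and map any non-ACGTN character (IUPAC ambiguity etc.) to N."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if bad.any():
        warnings.warn(
            f"{name}: {int(bad.sum())} non-ACGTN characters mapped to N",
            stacklevel=3,
        )
        arr[bad] = ord("N")
    return arr.tobytes().decode("ascii")


def read_fasta(path: str | Path) -> Genome:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Sequences are uppercased; characters outside {A,C,G,T,N} are mapped to N
    with a warning. Duplicate record names and empty records are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate FASTA record name: {rec.id!r}")
        seq = str(rec.seq)
        if len(seq) == 0:
            raise ValueError(f"empty FASTA record: {rec.id!r}")
        chroms[rec.id] = _sanitize(seq, rec.id)
    if not chroms:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(chroms)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def classify_context(
    genome: Genome, chrom: str, pos: int, strand: str
) -> str | None:
    """Classify the cytosine at (chrom, pos, strand) as CG, CHG or CHH.

    The two context bases are read 5'->3' on the cytosine's own strand; for
    a minus-strand cytosine (a G on the forward sequence) they are the
    complements of the two preceding forward-strand bases. Returns None
    (undefined) when fewer than two downstream bases exist or any of them
    is N.

    Raises if pos is out of range or the base at the site is not a cytosine
    on the requested strand.
    """
    seq = genome[chrom]
    if not 0 <= pos < len(seq):
        raise IndexError(f"position {pos} out of range for {chrom}")
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {seq[pos]}, not C")
        if pos + 2 >= len(seq):
            return None
        b1, b2 = seq[pos + 1], seq[pos + 2]
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"{chrom}:{pos}(-) is {seq[pos]}, not G (C on -)")
        if pos - 2 < 0:
            return None
        # complement of forward base: C<->G, A<->T
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        b1, b2 = comp[seq[pos - 1]], comp[seq[pos - 2]]
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if b1 == "N" or b2 == "N":
        return None
    if b1 == "G":
        return "CG"
    if b2 == "G":
        return "CHG"
    return "CHH"


def _enumerate_chrom(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized context classification of one chromosome.

    Returns (pos, strand, context) arrays; strand is '+'/'-' and context one
    of CONTEXTS. Sites with undefined context are omitted.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = len(arr)
    C, G, N = ord("C"), ord("G"), ord("N")

    out_pos, out_strand, out_ctx = [], [], []

    # forward-strand cytosines: context bases at pos+1, pos+2
    fwd = np.flatnonzero(arr == C)
    fwd = fwd[fwd + 2 < n]
    if fwd.size:
        b1, b2 = arr[fwd + 1], arr[fwd + 2]
        ok = (b1 != N) & (b2 != N)
        fwd, b1, b2 = fwd[ok], b1[ok], b2[ok]
        ctx = np.where(b1 == G, 0, np.where(b2 == G, 1, 2))
        out_pos.append(fwd)
        out_strand.append(np.zeros(fwd.size, dtype=np.uint8))
        out_ctx.append(ctx)

    # minus-strand cytosines are forward Gs; context bases are complements of
    # the forward bases at pos-1, pos-2, so CG <=> seq[pos-1]==C etc.
    rev = np.flatnonzero(arr == G)
    rev = rev[rev - 2 >= 0]
    if rev.size:
        b1, b2 = arr[rev - 1], arr[rev - 2]
        ok = (b1 != N) & (b2 != N)
        rev, b1, b2 = rev[ok], b1[ok], b2[ok]
        ctx = np.where(b1 == C, 0, np.where(b2 == C, 1, 2))
        out_pos.append(rev)
        out_strand.append(np.ones(rev.size, dtype=np.uint8))
        out_ctx.append(ctx)

    if not out_pos:
        z = np.array([], dtype=np.int64)
        return z, z.astype(np.uint8), z.astype(np.uint8)

    pos = np.concatenate(out_pos)
    strand = np.concatenate(out_strand)
    ctx = np.concatenate(out_ctx).astype(np.uint8)
    order = np.lexsort((strand, pos))
    return pos[order], strand[order], ctx[order]


def enumerate_cytosines(genome: Genome) -> pd.DataFrame:
    """Enumerate every context-classified cytosine on both strands.

    Returns a DataFrame with columns chrom, pos (0-based forward coordinate
    of the C/G base), strand and context, sorted by chrom order, position,
    strand. Cytosines whose two downstream context bases run off the
    chromosome or contain N are excluded (their context is unknowable).
    """
    frames = []
    ctx_codes = pd.CategoricalDtype(categories=list(CONTEXTS))
    for name, seq in genome.chromosomes.items():
        pos, strand, ctx = _enumerate_chrom(seq)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": pos,
                    "strand": np.where(strand == 0, "+", "-"),
                    "context": pd.Categorical.from_codes(ctx, dtype=ctx_codes),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=SITE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_context_table(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a cytosine-site table as TSV (chrom, pos, strand, context)."""
    sites[SITE_COLUMNS].to_csv(path, sep="\t", index=False)
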