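"""Shared data model and readers/writers for the formats the pipeline touches.

Sequences travel as :class:`PromoterRecord` (FASTA), motifs as
:class:`MotifModel` (MEME minimal format), and every tabular input/output is
tab-separated with a mandatory header, read and written through pandas with an
explicit column schema.

Coordinate convention: 0-based, half-open everywhere in memory and in BED-like
output; 1-based coordinates appear only in human-readable report text.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_LETTERS = "ACGT"
DNA_ALPHABET = frozenset("ACGTN")
#: row order of every 4 x w probability / score matrix in the package
LETTER_INDEX = {c: i for i, c in enumerate(DNA_LETTERS)}

__all__ = [
    "PromoterRecord",
    "MotifModel",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_meme_motifs",
    "write_meme_motifs",
    "read_table",
    "write_table",
    "reverse_complement",
    "encode_sequence",
]


class FormatError(ValueError):
    """A malformed input file; the message locates the offending entry."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A,C,G,T,N as 0..4 (N = 4). Input must be uppercase ACGTN."""
    table = np.full(128, -1, dtype=np.int8)
    for c, i in LETTER_INDEX.items():
        table[ord(c)] = i
    table[ord("N")] = 4
    codes = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        pos = int(np.argmax(codes < 0))
        raise FormatError(f"non-IUPAC character {seq[pos]!r} at position {pos}")
    return codes.astype(np.int64)


@dataclass
class PromoterRecord:
    """One gene's promoter sequence.

    The sequence is stored uppercase over {A,C,G,T,N}; ``strand`` records the
    orientation of the extracted genomic window relative to the gene.
    """

    gene_id: str
    sequence: str
    strand: str = "+"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence) if c in bad
            )
            raise FormatError(
                f"record {self.gene_id!r}: non-IUPAC character "
                f"{self.sequence[pos]!r} at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MotifModel:
    """A position probability matrix over A,C,G,T.

    ``probs`` is 4 x width (rows in A,C,G,T order, columns sum to 1);
    ``background`` is the 4-vector of letter frequencies used for scoring.
    ``nsites`` and ``evalue`` are carried from the source file when present so
    downstream E-value filters can be applied.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    nsites: int | None = None
    evalue: float | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("probs must be a 4 x width matrix")
        if self.width < 2:
            raise ValueError("motif width must be >= 2")
        if (self.probs < 0).any():
            raise FormatError(f"motif {self.motif_id!r}: negative probability")
        colsums = self.probs.sum(axis=0)
        if np.abs(colsums - 1.0).max() > 1e-3:
            col = int(np.argmax(np.abs(colsums - 1.0)))
            raise FormatError(
                f"motif {self.motif_id!r}: column {col} sums to "
                f"{colsums[col]:.6f}, expected 1"
            )
        # renormalize away sub-1e-3 rounding so invariants hold exactly
        self.probs = self.probs / colsums
        if abs(float(self.background.sum()) - 1.0) > 1e-3:
            raise FormatError(
                f"motif {self.motif_id!r}: background sums to "
                f"{self.background.sum():.6f}"
            )
        self.background = self.background / self.background.sum()

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        return "".join(DNA_LETTERS[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(
            motif_id=self.motif_id,
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background.copy(),
            nsites=self.nsites,
            evalue=self.evalue,
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[PromoterRecord]:
    """Read a FASTA file into :class:`PromoterRecord` objects, order preserved.

    Raises :class:`FormatError` on an empty file, a duplicate id, or a
    non-IUPAC character (located by record and position).
    """
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(PromoterRecord(gene_id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[PromoterRecord], path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme_motifs(path) -> list[MotifModel]:
    """Parse a MEME *minimal* format motif file.

    Supports the version line, optional ``ALPHABET``/``strands`` lines, an
    optional ``Background letter frequencies`` block, and ``MOTIF`` blocks
    with a ``letter-probability matrix`` header carrying ``w=``, optional
    ``nsites=`` and ``E=``. Background defaults to uniform when absent.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    background = np.full(4, 0.25)
    motifs: list[MotifModel] = []
    i = 0
    saw_version = False
    while i < len(lines):
        line = lines[i].strip()
        if line.lower().startswith("meme version"):
            saw_version = True
            i += 1
        elif line.startswith("Background letter frequencies"):
            i += 1
            toks: list[str] = []
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                toks.extend(lines[i].split())
                i += 1
            freqs = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freqs.get(c, 0.0) for c in DNA_LETTERS])
        elif line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: MOTIF line without an id: {line!r}")
            motif_id = parts[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(
                        f"{path}: motif {motif_id!r} has no probability matrix"
                    )
                i += 1
            if i >= len(lines):
                raise FormatError(
                    f"{path}: motif {motif_id!r} has no probability matrix"
                )
            header = lines[i].strip()
            kv = {}
            toks = header.replace(":", " ").split()
            for j, t in enumerate(toks):
                if t.endswith("=") and j + 1 < len(toks):
                    kv[t[:-1]] = toks[j + 1]
            width = int(kv.get("w", 0)) or None
            nsites = int(kv["nsites"]) if "nsites" in kv else None
            evalue = float(kv["E"]) if "E" in kv else None
            i += 1
            rows: list[list[float]] = []
            while i < len(lines):
                s = lines[i].strip()
                if not s or s.startswith("MOTIF") or s.startswith("URL"):
                    break
                rows.append([float(x) for x in s.split()])
                i += 1
            if not rows:
                raise FormatError(f"{path}: motif {motif_id!r} matrix is empty")
            mat = np.array(rows)  # rows = positions, cols = A C G T
            if mat.shape[1] != 4:
                raise FormatError(
                    f"{path}: motif {motif_id!r} matrix has {mat.shape[1]} "
                    "columns, expected 4 (A C G T)"
                )
            if width is not None and mat.shape[0] != width:
                raise FormatError(
                    f"{path}: motif {motif_id!r} declares w= {width} but has "
                    f"{mat.shape[0]} matrix rows"
                )
            motifs.append(
                MotifModel(
                    motif_id=motif_id,
                    probs=mat.T,
                    background=background.copy(),
                    nsites=nsites,
                    evalue=evalue,
                )
            )
        else:
            i += 1
    if not motifs:
        raise FormatError(f"{path}: no MOTIF blocks found")
    if not saw_version:
        raise FormatError(f"{path}: missing 'MEME version' line")
    return motifs


def write_meme_motifs(motifs: list[MotifModel], path) -> None:
    """Write motifs in MEME minimal format (round-trips with the reader)."""
    if not motifs:
        raise ValueError("no motifs to write")
    bg = motifs[0].background
    buf = io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    buf.write("Background letter frequencies\n")
    buf.write(
        " ".join(f"{c} {bg[i]:.6f}" for i, c in enumerate(DNA_LETTERS)) + "\n\n"
    )
    for m in motifs:
        buf.write(f"MOTIF {m.motif_id}\n")
        header = f"letter-probability matrix: alength= 4 w= {m.width}"
        if m.nsites is not None:
            header += f" nsites= {m.nsites}"
        if m.evalue is not None:
            header += f" E= {m.evalue:.6g}"
        buf.write(header + "\n")
        for col in range(m.width):
            buf.write(
                " ".join(f"{m.probs[r, col]:.9f}" for r in range(4)) + "\n"
            )
        buf.write("\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# TSV tables


def read_table(path, schema: dict[str, type] | None = None) -> pd.DataFrame:
    """Read a tab-separated table with a header; ``#`` lines are comments.

    ``schema`` maps required column names to types; a missing column raises
    :class:`FormatError` naming it, and columns are cast to the declared type.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if schema:
        for col, typ in schema.items():
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column {col!r}")
            if typ is bool:
                df[col] = df[col].map(
                    {"True": True, "False": False, "1": True, "0": False,
                     "true": True, "false": False}
                )
                if df[col].isna().any():
                    raise FormatError(f"{path}: non-boolean value in {col!r}")
            else:
                df[col] = df[col].astype(typ)
    return df


def write_table(df: pd.DataFrame, path, columns: list[str] | None = None,
                header_comments: list[str] | None = None) -> None:
    """Write a TSV with deterministic column order and optional # comments."""
    out = df[columns] if columns else df
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False)
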