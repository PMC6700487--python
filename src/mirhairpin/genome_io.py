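"""FASTA ingestion and genome windowing with exact coordinate bookkeeping.

Genomes are stored as DNA (``A/C/G/T/N``); windows are emitted in the RNA
alphabet (``T`` transcribed to ``U``) because every downstream stage folds
RNA.  Coordinates are 0-based, half-open and always refer to the plus
strand of the source genome, so a window or hairpin can be located with
BED-style arithmetic regardless of the strand it was read from.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ParameterError

_VALID_RESIDUES = frozenset("ACGTN")

#: header grammar for hairpin FASTA records, e.g. ``g1:100-180(+)|positive``
HAIRPIN_HEADER_RE = re.compile(
    r"^(?P<genome_id>.+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+-])\)\|(?P<label>\w+)$"
)


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence, normalized to uppercase ``A/C/G/T/N``."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid residues {sorted(bad)} "
                "(expected A/C/G/T/N after normalization)"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Window:
    """A coordinate-tracked slice of a genome, in the RNA alphabet.

    ``start``/``end`` are plus-strand genomic offsets (0-based, half-open).
    For ``strand == "-"`` the sequence is the reverse complement of the
    plus-strand slice, transcribed to RNA.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ParameterError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ParameterError(f"bad window interval [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ParameterError("window sequence length does not match its interval")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_fraction(self) -> float:
        return self.sequence.count("N") / len(self.sequence)


def _normalize(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-)FASTA file into :class:`GenomeSequence` records.

    Lowercase letters and ``U`` are normalized; the id is the header token
    before the first whitespace.  Empty files and zero-length records are
    format errors.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = _normalize(str(rec.seq))
        if not residues:
            raise FormatError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(GenomeSequence(id=rec.id, residues=residues))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def transcribe(dna: str) -> str:
    """DNA -> RNA (``T`` to ``U``); ``N`` passes through."""
    return dna.replace("T", "U")


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def window_sequence(genome: GenomeSequence, start: int, end: int, strand: str) -> str:
    """The RNA-alphabet sequence of interval [start, end) on the given strand."""
    dna = genome.residues[start:end]
    if strand == "-":
        dna = reverse_complement(dna)
    return transcribe(dna)


def make_windows(
    genome: GenomeSequence,
    window_length: int = 500,
    step: int = 300,
    strands: Sequence[str] = ("+", "-"),
) -> list[Window]:
    """Slice a genome into overlapping windows covering every position.

    Regular windows start at 0, step, 2*step, ...; if the last regular
    window does not reach the genome end, a final window anchored at
    ``L - window_length`` is appended so the tail is fully covered.  A
    genome no longer than ``window_length`` yields the single window
    ``[0, L)``.  One window is produced per start and requested strand.
    """
    if window_length <= 0:
        raise ParameterError(f"window_length must be positive, got {window_length}")
    if step <= 0 or step > window_length:
        raise ParameterError(f"step must satisfy 1 <= step <= window_length, got {step}")
    for s in strands:
        if s not in "+-":
            raise ParameterError(f"unknown strand {s!r}")

    L = genome.length
    if L <= window_length:
        starts = [0]
        ends = [L]
    else:
        starts = list(range(0, L - window_length + 1, step))
        ends = [s + window_length for s in starts]
        if ends[-1] < L:
            starts.append(L - window_length)
            ends.append(L)

    windows = []
    for strand in strands:
        for start, end in zip(starts, ends):
            windows.append(
                Window(
                    genome_id=genome.id,
                    start=start,
                    end=end,
                    strand=strand,
                    sequence=window_sequence(genome, start, end, strand),
                )
            )
    return windows


def hairpin_header(genome_id: str, start: int, end: int, strand: str, label: str) -> str:
    return f"{genome_id}:{start}-{end}({strand})|{label}"


def parse_hairpin_header(header: str) -> dict:
    m = HAIRPIN_HEADER_RE.match(header)
    if m is None:
        raise FormatError(f"hairpin header {header!r} does not match the header grammar")
    d = m.groupdict()
    d["start"] = int(d["start"])
    d["end"] = int(d["end"])
    return d


def write_hairpin_fasta(hairpins: Iterable, path: str | Path, wrap: int = 60) -> None:
    """Write hairpins as FASTA with the documented header grammar.

    Headers look like ``genome_id:start-end(strand)|label`` and round-trip
    through :func:`read_hairpin_fasta`.  An empty list yields an empty
    (valid) file.
    """
    path = Path(path)
    records = []
    for h in hairpins:
        header = hairpin_header(h.genome_id, h.start, h.end, h.strand, h.label)
        records.append(SeqRecord(Seq(h.sequence), id=header, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_hairpin_fasta(path: str | Path) -> list:
    """Read a hairpin FASTA written by :func:`write_hairpin_fasta`.

    Structures are not serialized; returned hairpins carry
    ``structure=None`` and are re-folded on demand by downstream stages.
    """
    from .hairpin_extraction import Hairpin  # local import avoids a cycle

    path = Path(path)
    hairpins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = parse_hairpin_header(rec.id)
        hairpins.append(
            Hairpin(
                sequence=str(rec.seq).upper().replace("T", "U"),
                structure=None,
                genome_id=meta["genome_id"],
                start=meta["start"],
                end=meta["end"],
                strand=meta["strand"],
                label=meta["label"],
            )
        )
    return hairpins
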