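"""Positive / unlabeled class assignment against a known-miRNA reference.

Candidate hairpins are compared with every reference sequence by
Smith-Waterman local alignment (linear gap penalty); a hairpin is
labeled *positive* when some reference reaches both an identity and a
reference-coverage threshold.  Everything else stays *unlabeled* — such
sequences have no known function and are candidate novel precursors,
not verified negatives.

Defaults: match +2, mismatch -3, gap -5; identity and coverage 0.9.  A
precomputed match table (BLAST outfmt-6-compatible subset) can be
supplied instead of the internal aligner.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _kernels
from .errors import FormatError, InputError
from .genome_io import hairpin_header
from .hairpin_extraction import LABEL_POSITIVE, LABEL_UNLABELED, Hairpin

logger = logging.getLogger(__name__)

DEFAULT_MATCH = 2.0
DEFAULT_MISMATCH = -3.0
DEFAULT_GAP = -5.0


@dataclass(frozen=True)
class KnownMiRNASet:
    """Reference set of known pre-miRNA sequences (miRBase-style)."""

    entries: tuple[tuple[str, str], ...]
    source_tag: str = ""

    def __post_init__(self):
        ids = [i for i, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise InputError("reference ids must be unique")
        if any(not s for _, s in self.entries):
            raise InputError("reference sequences must be non-empty")

    @classmethod
    def from_fasta(cls, path: str | Path, source_tag: str = "") -> "KnownMiRNASet":
        from Bio import SeqIO

        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            entries.append((rec.id, str(rec.seq).upper().replace("T", "U")))
        return cls(entries=tuple(entries), source_tag=source_tag or str(path))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class MatchResult:
    hairpin_index: int
    reference_id: str
    identity: float
    coverage: float


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.upper().replace("T", "U").encode("ascii"), dtype=np.uint8)


def local_align(
    query: str,
    reference: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> tuple[float, float, float]:
    """Optimal local alignment: (score, identity, reference coverage).

    Identity is matches over aligned columns (gap columns included);
    coverage is the aligned reference span over the reference length.
    Traceback is deterministic: the best cell is the first maximum in
    row-major order and moves prefer diagonal, then up, then left.
    """
    if not query or not reference:
        raise InputError("local_align requires non-empty sequences")
    q = _encode(query)
    r = _encode(reference)
    H, best, bi, bj = _kernels.sw_fill(q, r, match, mismatch, gap)
    if best <= 0.0:
        return 0.0, 0.0, 0.0
    i, j = bi, bj
    matches = 0
    columns = 0
    while H[i, j] > 0.0:
        s = match if q[i - 1] == r[j - 1] else mismatch
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
            columns += 1
            if q[i - 1] == r[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    identity = matches / columns if columns else 0.0
    coverage = (bj - j) / len(reference)
    return float(best), identity, coverage


def match_hairpins(
    hairpins: Sequence[Hairpin],
    known: KnownMiRNASet,
    min_identity: float = 0.9,
    min_coverage: float = 0.9,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> list[MatchResult]:
    """Best qualifying match per hairpin (empty result entries omitted)."""
    results = []
    for idx, h in enumerate(hairpins):
        for ref_id, ref_seq in known.entries:
            _, identity, coverage = local_align(h.sequence, ref_seq, match, mismatch, gap)
            if identity >= min_identity and coverage >= min_coverage:
                results.append(
                    MatchResult(
                        hairpin_index=idx,
                        reference_id=ref_id,
                        identity=identity,
                        coverage=coverage,
                    )
                )
                break
    return results


def label_hairpins(
    hairpins: Sequence[Hairpin],
    known: KnownMiRNASet,
    min_identity: float = 0.9,
    min_coverage: float = 0.9,
    **align_kwargs,
) -> list[Hairpin]:
    """Label hairpins positive when a reference matches, else unlabeled."""
    if not 0.0 < min_identity <= 1.0 or not 0.0 < min_coverage <= 1.0:
        raise InputError("matcher thresholds must lie in (0, 1]")
    if len(known) == 0:
        logger.warning("empty reference set: every hairpin stays unlabeled")
        matched: set[int] = set()
    else:
        matched = {
            m.hairpin_index
            for m in match_hairpins(
                hairpins, known, min_identity, min_coverage, **align_kwargs
            )
        }
    out = []
    for idx, h in enumerate(hairpins):
        label = LABEL_POSITIVE if idx in matched else LABEL_UNLABELED
        out.append(
            Hairpin(
                sequence=h.sequence,
                structure=h.structure,
                genome_id=h.genome_id,
                start=h.start,
                end=h.end,
                strand=h.strand,
                label=label,
            )
        )
    logger.info(
        "labeled positives=%d unlabeled=%d",
        len(matched),
        len(out) - len(matched),
    )
    return out


def load_match_table(path: str | Path) -> list[tuple[str, str, float, int]]:
    """Read an external match table: query_id, reference_id, identity%,
    alignment_length (tab-separated, BLAST outfmt-6-compatible subset)."""
    rows = []
    with open(path) as fh:
        for ln, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 4:
                raise FormatError(f"match table line {ln}: expected >= 4 columns")
            rows.append((row[0], row[1], float(row[2]), int(row[3])))
    return rows


def label_from_table(
    hairpins: Sequence[Hairpin],
    table: Sequence[tuple[str, str, float, int]],
    known: KnownMiRNASet,
    min_identity: float = 0.9,
    min_coverage: float = 0.9,
) -> list[Hairpin]:
    """Label from a precomputed match table (e.g. external BLAST output).

    Query ids must follow the hairpin header grammar; identity arrives on
    the 0-100 scale, coverage is alignment_length / reference length.
    """
    ref_len = {rid: len(seq) for rid, seq in known.entries}
    positive_ids = set()
    for qid, rid, ident_pct, aln_len in table:
        if rid not in ref_len:
            continue
        if ident_pct / 100.0 >= min_identity and aln_len / ref_len[rid] >= min_coverage:
            positive_ids.add(qid)
    out = []
    for h in hairpins:
        hid = hairpin_header(h.genome_id, h.start, h.end, h.strand, h.label)
        bare = hid.rsplit("|", 1)[0]
        is_pos = any(p.rsplit("|", 1)[0] == bare for p in positive_ids) or hid in positive_ids
        out.append(
            Hairpin(
                sequence=h.sequence,
                structure=h.structure,
                genome_id=h.genome_id,
                start=h.start,
                end=h.end,
                strand=h.strand,
                label=LABEL_POSITIVE if is_pos else LABEL_UNLABELED,
            )
        )
    return out
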