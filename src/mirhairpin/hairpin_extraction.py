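"""Stem-loop parsing, filtering, trimming and deduplication.

A hairpin is the region reachable from a hairpin loop's closing pair by
walking outward through stacked pairs, bulges and internal loops,
stopping at a multiloop or the exterior.  Each hairpin keeps plus-strand
genome coordinates so its sequence can always be re-derived from the
genome, whichever strand it was read from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .errors import ParameterError
from .folding import (
    DEFAULT_MODEL,
    EnergyModel,
    SecondaryStructure,
    pairs_to_dotbracket,
    structure_energy,
)
from .genome_io import Window

LABEL_POSITIVE = "positive"
LABEL_UNLABELED = "unlabeled"


@dataclass
class Hairpin:
    """An extracted stem-loop with provenance coordinates and a label."""

    sequence: str
    structure: Optional[SecondaryStructure]
    genome_id: str
    start: int
    end: int
    strand: str
    label: str = LABEL_UNLABELED

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_pairs(self) -> int:
        return self.structure.n_pairs if self.structure is not None else 0


@dataclass(frozen=True)
class StemLoopStats:
    """Helix-level summary of a hairpin structure.

    A stem is a maximal run of perfectly stacked pairs (i,j), (i+1,j-1),
    ... with no intervening unpaired base on either strand; a lone pair
    is a stem of length 1, so every base pair belongs to exactly one
    stem.  Pair-class counts pool the two orientations (AU+UA, GC+CG,
    GU+UG).
    """

    stem_number: int
    avg_bp_stem: float
    longest_stem_length: int
    terminal_loop_length: int
    bp_number: int
    bp_counts: tuple[int, int, int]
    bp_counts_in_stems: tuple[int, int, int]


def _children_map(pairs: Sequence[int]) -> dict:
    """Map each pair (i, j) to its directly nested pairs; key None = exterior."""
    children: dict = {None: []}
    stack: list[tuple[int, int]] = []
    for i, j in enumerate(pairs):
        if j > i:
            parent = stack[-1] if stack else None
            children.setdefault((i, j), [])
            children.setdefault(parent, []).append((i, j))
            stack.append((i, j))
        elif 0 <= j < i:
            stack.pop()
    return children


def _parent_map(pairs: Sequence[int]) -> dict:
    parent: dict = {}
    stack: list[tuple[int, int]] = []
    for i, j in enumerate(pairs):
        if j > i:
            parent[(i, j)] = stack[-1] if stack else None
            stack.append((i, j))
        elif 0 <= j < i:
            stack.pop()
    return parent


def _substructure(window_seq: str, pairs: Sequence[int], a: int, b: int,
                  model: EnergyModel) -> SecondaryStructure:
    """Re-index the structure restricted to the closed span [a, b]."""
    sub_seq = window_seq[a : b + 1]
    sub_pairs = []
    for p in range(a, b + 1):
        q = pairs[p]
        sub_pairs.append(q - a if q >= 0 else -1)
    sub_pairs = tuple(sub_pairs)
    return SecondaryStructure(
        sequence=sub_seq,
        dotbracket=pairs_to_dotbracket(sub_pairs),
        pairs=sub_pairs,
        mfe=structure_energy(sub_seq, sub_pairs, model),
    )


def _span_to_genome(start: int, end: int, strand: str, seq_len: int,
                    a: int, b: int) -> tuple[int, int]:
    """Map local span [a, b] (inclusive) back to plus-strand coordinates."""
    if strand == "+":
        return start + a, start + b + 1
    return start + (seq_len - 1 - b), start + (seq_len - a)


def extract_stem_loops(
    window: Window,
    structure: SecondaryStructure,
    model: EnergyModel = DEFAULT_MODEL,
) -> list[Hairpin]:
    """One hairpin per hairpin loop of the folded window.

    Each hairpin spans from its loop's closing pair out to the outermost
    pair reachable through single-branch regions (stacks, bulges,
    internal loops); the walk stops below a multiloop or the exterior.
    The excised sub-structure is re-indexed to the hairpin sequence and
    its energy is the restriction of the window structure (no re-fold).
    """
    pairs = structure.pairs
    children = _children_map(pairs)
    parent = _parent_map(pairs)

    hairpins = []
    for pr in sorted(p for p in children if p is not None):
        if children.get(pr):
            continue  # not a hairpin-loop closing pair
        node = pr
        while True:
            up = parent.get(node)
            if up is None or len(children.get(up, [])) != 1:
                break
            node = up
        a, b = node
        sub = _substructure(window.sequence, pairs, a, b, model)
        g_start, g_end = _span_to_genome(
            window.start, window.end, window.strand, len(window.sequence), a, b
        )
        hairpins.append(
            Hairpin(
                sequence=sub.sequence,
                structure=sub,
                genome_id=window.genome_id,
                start=g_start,
                end=g_end,
                strand=window.strand,
            )
        )
    hairpins.sort(key=lambda h: h.start)
    return hairpins


def filter_hairpins(
    hairpins: Sequence[Hairpin], min_length: int = 60, min_pairs: int = 16
) -> list[Hairpin]:
    """Keep hairpins with length >= min_length AND base pairs >= min_pairs.

    Both boundaries are inclusive: a 60-nt hairpin with 16 pairs passes.
    """
    if min_length < 1:
        raise ParameterError(f"min_length must be >= 1, got {min_length}")
    if min_pairs < 0:
        raise ParameterError(f"min_pairs must be >= 0, got {min_pairs}")
    return [
        h for h in hairpins if h.length >= min_length and h.n_pairs >= min_pairs
    ]


def _pair_chain(pairs: Sequence[int]) -> list[tuple[int, int]]:
    """Pairs on the walk from the hairpin loop outward (innermost first).

    Assumes a single-loop hairpin structure; on a multi-loop structure the
    chain of the first hairpin loop is returned.
    """
    children = _children_map(pairs)
    parent = _parent_map(pairs)
    loops = sorted(p for p in children if p is not None and not children.get(p))
    if not loops:
        return []
    chain = [loops[0]]
    while True:
        up = parent.get(chain[-1])
        if up is None or len(children.get(up, [])) != 1:
            break
        chain.append(up)
    return chain


def trim_hairpin(hairpin: Hairpin, min_length: int = 60,
                 model: EnergyModel = DEFAULT_MODEL) -> Optional[Hairpin]:
    """Trim a hairpin at the innermost loop/bulge whose span is long enough.

    Rule 1: a hairpin shorter than ``min_length`` is discarded (returns
    ``None``).  Rule 2: walking outward from the main loop, each internal
    loop or bulge offers a candidate cut whose enclosed span keeps the
    inner closing pair intact and extends one unpaired nucleotide into
    the loop/bulge on each side where one exists; the first (closest to
    the loop) span of length >= ``min_length`` is kept.  Shorter
    sequences have higher length-normalized free energy, so the cut
    closest to the loop that still satisfies the minimum is preferred.
    If no loop/bulge qualifies the hairpin is returned whole.
    """
    if hairpin.length < min_length:
        return None
    pairs = hairpin.structure.pairs
    chain = _pair_chain(pairs)
    n = hairpin.length
    for (a, b), (c, d) in zip(chain, chain[1:]):
        gap5 = a - c - 1
        gap3 = d - b - 1
        if gap5 == 0 and gap3 == 0:
            continue  # stacked pair, not a loop/bulge
        a_cut = a - 1 if gap5 > 0 else a
        b_cut = b + 1 if gap3 > 0 else b
        if b_cut - a_cut + 1 >= min_length:
            sub = _substructure(hairpin.sequence, pairs, a_cut, b_cut, model)
            g_start, g_end = _span_to_genome(
                hairpin.start, hairpin.end, hairpin.strand, n, a_cut, b_cut
            )
            return Hairpin(
                sequence=sub.sequence,
                structure=sub,
                genome_id=hairpin.genome_id,
                start=g_start,
                end=g_end,
                strand=hairpin.strand,
                label=hairpin.label,
            )
    return hairpin


def deduplicate(hairpins: Sequence[Hairpin]) -> list[Hairpin]:
    """Drop consecutive containment duplicates (overlapping-window echoes).

    Single pass in extraction order: each sequence is compared with the
    most recently kept one; when one contains the other, the shorter is
    discarded (on equal sequences, the later).  Comparison is on sequence
    text only.
    """
    kept: list[Hairpin] = []
    for h in hairpins:
        if kept:
            last = kept[-1]
            if h.sequence == last.sequence:
                continue
            if h.sequence in last.sequence:
                continue
            if last.sequence in h.sequence:
                kept[-1] = h
                continue
        kept.append(h)
    return kept


_PAIR_CLASS = {
    frozenset("AU"): 0,
    frozenset("GC"): 1,
    frozenset("GU"): 2,
}


def compute_stem_stats(hairpin: Hairpin) -> StemLoopStats:
    """Helix statistics of a hairpin's structure (see :class:`StemLoopStats`)."""
    pairs = hairpin.structure.pairs
    seq = hairpin.sequence
    n = len(seq)

    bp_counts = [0, 0, 0]
    stems: list[int] = []  # lengths in bp
    run = 0
    for i in range(n):
        j = pairs[i]
        if j > i:
            cls = _PAIR_CLASS.get(frozenset((seq[i], seq[j])))
            if cls is not None:
                bp_counts[cls] += 1
            if i > 0 and pairs[i - 1] == j + 1:
                run += 1
            else:
                if run:
                    stems.append(run)
                run = 1
        else:
            if run:
                stems.append(run)
                run = 0
    if run:
        stems.append(run)

    bp_number = sum(1 for i in range(n) if pairs[i] > i)
    stem_number = len(stems)
    longest = max(stems) if stems else 0
    avg_bp_stem = (2.0 * bp_number / stem_number) if stem_number else 0.0

    # terminal loop: unpaired run inside the innermost closing pair
    children = _children_map(pairs)
    loops = sorted(p for p in children if p is not None and not children.get(p))
    terminal_loop = loops[0][1] - loops[0][0] - 1 if loops else 0

    return StemLoopStats(
        stem_number=stem_number,
        avg_bp_stem=avg_bp_stem,
        longest_stem_length=longest,
        terminal_loop_length=terminal_loop,
        bp_number=bp_number,
        bp_counts=tuple(bp_counts),
        bp_counts_in_stems=tuple(bp_counts),  # every pair sits in a stem
    )


def suggest_trim_min(known_lengths: Sequence[int], default: int = 60) -> int:
    """Per-genome trimming minimum: 10th percentile of known-miRNA lengths.

    Falls back to ``default`` when no reference lengths are available.
    """
    if not known_lengths:
        return default
    import numpy as np

    return int(np.percentile(np.asarray(known_lengths), 10))
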