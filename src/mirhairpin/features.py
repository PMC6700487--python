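"""The 77-dimensional hairpin feature vector and its CSV serialization.

The vector concatenates, in a fixed canonical order: nucleotide and
dinucleotide composition, GC measures, sequence length, helix-level
structure statistics, pairing densities, the 32 structure-sequence
triplet frequencies, and thermodynamic quantities (MFE, ensemble free
energy, MFE-structure frequency, ensemble diversity, and the derived
indices dQ, dG, MFEI_1, MFEI_2, MFEI_4).

Conventions that matter downstream:

* ``dQ`` is computed exactly as ``(1/L) sum_{i<j} p_ij log2 p_ij`` —
  no leading minus — so it is always <= 0, unlike the positive
  Shannon-entropy variant found elsewhere in the literature.
* ``EFE`` is the raw ensemble free energy in kcal/mol; the per-length
  normalization appears only in ``mfe_efe_difference`` (= |MFE-EFE|/L).
* ``MFEI_1`` divides MFE by %G+C on the 0-100 scale.
* ``avg_bp_stem`` counts paired *nucleotides* per stem (2 bp per stem
  position), matching its description as nucleotides per stem.
* triplet bins are nucleotide-major, pattern-minor with ``(`` and ``)``
  collapsed to a single "paired" state; see :data:`TRIPLET_PATTERNS`.

Division guards (gc_ratio with no C, MFEI_1 at 0% GC, MFEI_2 with no
stems, MFEI_4 with no pairs) produce 0 with a logged warning so every
vector stays total and finite.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .folding import EnsembleData
from .genome_io import hairpin_header
from .hairpin_extraction import Hairpin, StemLoopStats, compute_stem_stats

logger = logging.getLogger(__name__)

_NT = "ACGU"
TRIPLET_PATTERNS = ("...", "..(", ".(.", ".((", "(..", "(.(", "((.", "(((")

_SCALAR_HEAD = (
    "gc_content",
    "gc_ratio",
    "sequence_length",
    "stem_number",
    "avg_bp_stem",
    "longest_stem_length",
    "terminal_loop_length",
    "bp_number",
    "dP",
)
_PAIR_CLASSES = ("AU", "GC", "GU")
_SCALAR_TAIL = (
    "MFE",
    "EFE",
    "ensemble_frequency",
    "diversity",
    "mfe_efe_difference",
    "dQ",
    "dG",
    "MFEI_1",
    "MFEI_2",
    "MFEI_4",
)

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"nt_proportion_{b}" for b in _NT)
    + tuple(f"dinucleotide_proportion_{a}{b}" for a in _NT for b in _NT)
    + _SCALAR_HEAD
    + tuple(f"bp_proportion_{c}" for c in _PAIR_CLASSES)
    + tuple(f"bp_proportion_stem_{c}" for c in _PAIR_CLASSES)
    + tuple(f"triplets_{i}" for i in range(32))
    + _SCALAR_TAIL
)
assert len(FEATURE_NAMES) == 77

METADATA_COLUMNS = ("id", "genome_id", "start", "end", "strand", "label")


@dataclass(frozen=True)
class FeatureVector:
    """The 77 canonical feature values of one hairpin, in fixed order."""

    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.values) != 77:
            raise InputError(f"a feature vector has 77 values, got {len(self.values)}")

    def __len__(self) -> int:
        return 77

    def __getitem__(self, name: str) -> float:
        return self.values[FEATURE_NAMES.index(name)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


def sequence_features(sequence: str) -> dict[str, float]:
    """Composition features: nt/dinucleotide proportions, GC content/ratio, length."""
    if not sequence:
        raise InputError("cannot compute sequence features of an empty sequence")
    seq = sequence.upper().replace("T", "U")
    L = len(seq)
    out: dict[str, float] = {}
    for b in _NT:
        out[f"nt_proportion_{b}"] = seq.count(b) / L
    denom = max(L - 1, 1)
    counts = {f"{a}{b}": 0 for a in _NT for b in _NT}
    for i in range(L - 1):
        di = seq[i : i + 2]
        if di in counts:
            counts[di] += 1
    for di, c in counts.items():
        out[f"dinucleotide_proportion_{di}"] = c / denom
    n_g = seq.count("G")
    n_c = seq.count("C")
    out["gc_content"] = (n_g + n_c) / L
    if n_c == 0:
        if n_g:
            logger.warning("gc_ratio undefined (no C); reporting 0")
        out["gc_ratio"] = 0.0
    else:
        out["gc_ratio"] = n_g / n_c
    out["sequence_length"] = float(L)
    return out


def structure_features(hairpin: Hairpin, stats: StemLoopStats) -> dict[str, float]:
    """Helix statistics plus pairing densities (dP, bp proportions)."""
    L = hairpin.length
    out = {
        "stem_number": float(stats.stem_number),
        "avg_bp_stem": stats.avg_bp_stem,
        "longest_stem_length": float(stats.longest_stem_length),
        "terminal_loop_length": float(stats.terminal_loop_length),
        "bp_number": float(stats.bp_number),
        "dP": stats.bp_number / L,
    }
    for cls, c in zip(_PAIR_CLASSES, stats.bp_counts):
        out[f"bp_proportion_{cls}"] = c / L
    stem_total = sum(stats.bp_counts_in_stems)
    for cls, c in zip(_PAIR_CLASSES, stats.bp_counts_in_stems):
        out[f"bp_proportion_stem_{cls}"] = c / stem_total if stem_total else 0.0
    return out


def triplet_features(hairpin: Hairpin) -> dict[str, float]:
    """32 structure-sequence triplet frequencies over interior positions.

    Position i (1..L-2) is binned by its nucleotide and the
    paired/unpaired pattern of (i-1, i, i+1); bin index is
    ``8 * nt + pattern`` with nt in A,C,G,U order and pattern the binary
    number with "paired" = 1 (so pattern 0 = "...", 7 = "(((").
    Interior positions whose middle base is not A/C/G/U are skipped.
    """
    seq = hairpin.sequence
    pairs = hairpin.structure.pairs
    L = len(seq)
    counts = np.zeros(32)
    if L < 3:
        logger.warning("triplet features need length >= 3; reporting zeros")
        return {f"triplets_{i}": 0.0 for i in range(32)}
    n_windows = 0
    for i in range(1, L - 1):
        nt = _NT.find(seq[i])
        if nt < 0:
            continue
        pattern = 0
        for off, bit in ((-1, 4), (0, 2), (1, 1)):
            if pairs[i + off] >= 0:
                pattern |= bit
        counts[8 * nt + pattern] += 1
        n_windows += 1
    if n_windows:
        counts /= n_windows
    return {f"triplets_{i}": float(counts[i]) for i in range(32)}


def thermo_features(
    mfe: float,
    ensemble: EnsembleData,
    stats: StemLoopStats,
    L: int,
    gc_percent: float,
) -> dict[str, float]:
    """Thermodynamic block: MFE/EFE and the derived stability indices."""
    if L <= 0:
        raise InputError("sequence length must be positive")
    P = ensemble.pair_prob
    iu = np.triu_indices(P.shape[0], k=1)
    p = P[iu]
    p = p[p > 0.0]
    dq = float(np.sum(p * np.log2(p)) / L) if p.size else 0.0
    out = {
        "MFE": mfe,
        "EFE": ensemble.efe,
        "ensemble_frequency": ensemble.mfe_frequency,
        "diversity": ensemble.diversity,
        "mfe_efe_difference": abs(mfe - ensemble.efe) / L,
        "dQ": dq,
        "dG": mfe / L,
    }
    if gc_percent > 0:
        out["MFEI_1"] = mfe / gc_percent
    else:
        logger.warning("MFEI_1 undefined at 0%% G+C; reporting 0")
        out["MFEI_1"] = 0.0
    if stats.stem_number > 0:
        out["MFEI_2"] = out["dG"] / stats.stem_number
    else:
        logger.warning("MFEI_2 undefined with no stems; reporting 0")
        out["MFEI_2"] = 0.0
    if stats.bp_number > 0:
        out["MFEI_4"] = mfe / stats.bp_number
    else:
        logger.warning("MFEI_4 undefined with no base pairs; reporting 0")
        out["MFEI_4"] = 0.0
    return out


def compute_features(hairpin: Hairpin, ensemble: EnsembleData) -> FeatureVector:
    """Assemble the full 77-slot vector for a folded hairpin."""
    if hairpin.structure is None:
        raise InputError("hairpin must carry a structure; fold it first")
    stats = compute_stem_stats(hairpin)
    parts: dict[str, float] = {}
    parts.update(sequence_features(hairpin.sequence))
    parts.update(structure_features(hairpin, stats))
    parts.update(triplet_features(hairpin))
    parts.update(
        thermo_features(
            hairpin.structure.mfe,
            ensemble,
            stats,
            hairpin.length,
            parts["gc_content"] * 100.0,
        )
    )
    return FeatureVector(values=tuple(parts[name] for name in FEATURE_NAMES))


def feature_manifest() -> list[str]:
    """Canonical feature names as shipped in the machine-readable manifest."""
    with resources.files("mirhairpin").joinpath("feature_manifest.json").open() as fh:
        return json.load(fh)


def write_feature_csv(
    rows: Iterable[tuple[Hairpin, FeatureVector]], path: str | Path
) -> None:
    """Per-genome CSV: metadata columns then the 77 features, full precision."""
    records = []
    for h, fv in rows:
        rec = {
            "id": hairpin_header(h.genome_id, h.start, h.end, h.strand, h.label),
            "genome_id": h.genome_id,
            "start": h.start,
            "end": h.end,
            "strand": h.strand,
            "label": h.label,
        }
        rec.update(fv.as_dict())
        records.append(rec)
    df = pd.DataFrame(records, columns=list(METADATA_COLUMNS) + list(FEATURE_NAMES))
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    """Load a feature CSV, checking the canonical column set."""
    df = pd.read_csv(path)
    missing = [c for c in list(METADATA_COLUMNS) + list(FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise InputError(f"feature CSV {path} is missing columns: {missing[:5]} ...")
    return df
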