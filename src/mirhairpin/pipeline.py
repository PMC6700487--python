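"""Stage orchestration shared by the CLI and programmatic callers.

``extract_hairpins`` runs windows -> fold -> extract -> filter -> trim
-> dedup for one genome and reports per-stage counts; ``featurize``
folds (if needed) and computes the 77-feature vector per hairpin.
Deduplication is applied per (genome, strand) stream in window order,
which is where overlapping-window echoes are consecutive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .config import PipelineConfig
from .features import FeatureVector, compute_features
from .folding import FoldBackend, get_backend
from .genome_io import GenomeSequence, make_windows
from .hairpin_extraction import (
    Hairpin,
    deduplicate,
    extract_stem_loops,
    filter_hairpins,
    suggest_trim_min,
    trim_hairpin,
)
from .labeling import KnownMiRNASet, label_hairpins

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StageCounts:
    windows: int
    windows_skipped: int
    raw_hairpins: int
    post_filter: int
    post_trim: int
    post_dedup: int

    def as_kv(self) -> str:
        return (
            f"windows={self.windows} windows_skipped={self.windows_skipped} "
            f"raw_hairpins={self.raw_hairpins} post_filter={self.post_filter} "
            f"post_trim={self.post_trim} post_dedup={self.post_dedup}"
        )


def extract_hairpins(
    genome: GenomeSequence,
    config: PipelineConfig | None = None,
    backend: FoldBackend | None = None,
) -> tuple[list[Hairpin], StageCounts]:
    """Full extraction for one genome; returns hairpins and stage counts."""
    config = config or PipelineConfig()
    backend = backend or get_backend(config.backend)

    windows = make_windows(
        genome, config.window_length, config.step, config.strands
    )
    kept_windows = [w for w in windows if w.n_fraction <= config.max_n_fraction]
    skipped = len(windows) - len(kept_windows)

    raw_total = 0
    filtered_total = 0
    trimmed_all: list[list[Hairpin]] = []
    for strand in config.strands:
        stream: list[Hairpin] = []
        for window in (w for w in kept_windows if w.strand == strand):
            structure = backend.fold(window.sequence)
            raw = extract_stem_loops(window, structure)
            raw_total += len(raw)
            kept = filter_hairpins(raw, config.min_hairpin_length, config.min_pairs)
            filtered_total += len(kept)
            for h in kept:
                t = trim_hairpin(h, config.trim_min_length)
                if t is not None:
                    stream.append(t)
        trimmed_all.append(stream)

    post_trim = sum(len(s) for s in trimmed_all)
    deduped: list[Hairpin] = []
    for stream in trimmed_all:
        deduped.extend(deduplicate(stream))

    counts = StageCounts(
        windows=len(windows),
        windows_skipped=skipped,
        raw_hairpins=raw_total,
        post_filter=filtered_total,
        post_trim=post_trim,
        post_dedup=len(deduped),
    )
    logger.info("extract %s %s", genome.id, counts.as_kv())
    return deduped, counts


def label(
    hairpins: Sequence[Hairpin],
    known: KnownMiRNASet,
    config: PipelineConfig | None = None,
) -> list[Hairpin]:
    config = config or PipelineConfig()
    return label_hairpins(
        hairpins, known, config.min_identity, config.min_coverage
    )


def trim_minimum(config: PipelineConfig, known: KnownMiRNASet | None) -> int:
    """Per-genome trimming minimum, optionally from the reference set."""
    if config.trim_min_from_reference and known is not None and len(known):
        return suggest_trim_min([len(s) for _, s in known.entries], config.trim_min_length)
    return config.trim_min_length


def featurize(
    hairpins: Sequence[Hairpin],
    config: PipelineConfig | None = None,
    backend: FoldBackend | None = None,
) -> list[tuple[Hairpin, FeatureVector]]:
    """Fold (when structure is absent) and compute the 77-feature vector."""
    config = config or PipelineConfig()
    backend = backend or get_backend(config.backend)
    rows = []
    for h in hairpins:
        if h.structure is None:
            h = Hairpin(
                sequence=h.sequence,
                structure=backend.fold(h.sequence),
                genome_id=h.genome_id,
                start=h.start,
                end=h.end,
                strand=h.strand,
                label=h.label,
            )
        ensemble = backend.ensemble(h.sequence)
        rows.append((h, compute_features(h, ensemble)))
    return rows
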