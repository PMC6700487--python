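"""Synthetic genomes with implanted fold-backs and a matching truth table.

The generator emulates the one structural signal the pipeline must
recover — perfect reverse-complement palindromes (fold-backs) dropped
into i.i.d. uniform background — while the background itself supplies
the "unlabeled" class: random RNA folds promiscuously, so plenty of
chance hairpins pass the length/pairing filters, just as in a real
genome.  A configurable fraction of the implants is copied into the
returned reference set; those are the expected positives.

Every implant is validated at generation time: folded in isolation with
the bundled model it must yield a hairpin passing the default filters
(length >= 60, >= 16 pairs), so recovery failures downstream indicate a
pipeline defect, not an unlucky draw.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .folding import DEFAULT_MODEL, EnergyModel, fold_mfe
from .genome_io import GenomeSequence, Window, reverse_complement
from .hairpin_extraction import extract_stem_loops, filter_hairpins
from .labeling import KnownMiRNASet

_RNA = np.array(list("ACGU"))


@dataclass(frozen=True)
class PlantedImplant:
    genome_id: str
    start: int
    end: int
    strand: str
    sequence: str  # RNA, as transcribed from its strand
    is_known_mirna: bool


@dataclass(frozen=True)
class PlantedTruth:
    implants: tuple[PlantedImplant, ...]

    def __len__(self) -> int:
        return len(self.implants)

    def known(self) -> list[PlantedImplant]:
        return [im for im in self.implants if im.is_known_mirna]


def make_foldback(
    arm_length: int,
    loop_length: int,
    gc_fraction: float = 0.5,
    seed: int = 0,
) -> str:
    """Random arm + loop + exact reverse complement of the arm (RNA).

    The arm draws G/C with probability ``gc_fraction`` (split evenly)
    and A/U otherwise; total length is ``2 * arm_length + loop_length``.
    Deterministic per seed.
    """
    if arm_length < 1:
        raise ParameterError("arm_length must be >= 1")
    if loop_length < 3:
        raise ParameterError(
            "loop_length must be >= 3 (minimum hairpin loop of the fold model)"
        )
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            (1 - gc_fraction) / 2,
            gc_fraction / 2,
            gc_fraction / 2,
            (1 - gc_fraction) / 2,
        ]
    )
    arm = "".join(rng.choice(_RNA, size=arm_length, p=p))
    loop = "".join(rng.choice(_RNA, size=loop_length))
    rc = reverse_complement(arm.replace("U", "T")).replace("T", "U")
    return arm + loop + rc


def _implant_passes_filters(
    rna: str, min_length: int, min_pairs: int, model: EnergyModel
) -> bool:
    structure = fold_mfe(rna, model)
    window = Window(
        genome_id="implant", start=0, end=len(rna), strand="+", sequence=rna
    )
    hairpins = extract_stem_loops(window, structure, model)
    return bool(filter_hairpins(hairpins, min_length, min_pairs))


def generate_genome(
    n_implants: int = 10,
    background_length: int = 50_000,
    arm_length: int = 30,
    loop_length: int = 4,
    gc_fraction: float = 0.5,
    known_fraction: float = 0.5,
    spacing: int = 500,
    seed: int = 0,
    genome_id: str = "synth1",
    min_length: int = 60,
    min_pairs: int = 16,
    model: EnergyModel = DEFAULT_MODEL,
) -> tuple[GenomeSequence, KnownMiRNASet, PlantedTruth]:
    """A uniform-random genome with fold-backs at recorded positions.

    Implants overwrite the background (genome length stays
    ``background_length``), are separated by at least ``spacing`` nt so
    each lies wholly within one window, and land on a random strand.
    The first ``round(known_fraction * n_implants)`` implants are copied
    into the reference set.  Deterministic per seed.
    """
    implant_len = 2 * arm_length + loop_length
    need = n_implants * (implant_len + spacing)
    if need > background_length:
        raise ParameterError(
            f"{n_implants} implants of {implant_len} nt with spacing {spacing} "
            f"do not fit in {background_length} nt of background"
        )
    rng = np.random.default_rng(seed)
    background = rng.choice(np.array(list("ACGT")), size=background_length)

    # evenly spread slots, jittered, so pairwise gaps stay >= spacing
    slot = background_length // n_implants
    jitter_max = max(slot - implant_len - spacing, 0)
    starts = []
    for k in range(n_implants):
        jitter = int(rng.integers(0, jitter_max + 1))
        starts.append(k * slot + jitter)

    n_known = round(known_fraction * n_implants)
    implants = []
    known_entries = []
    for k, start in enumerate(starts):
        # re-draw until the implant provably passes the default filters
        for attempt in range(50):
            sub = int(rng.integers(0, 2**31))
            rna = make_foldback(arm_length, loop_length, gc_fraction, seed=sub)
            if _implant_passes_filters(rna, min_length, min_pairs, model):
                break
        else:  # pragma: no cover - vanishingly unlikely for sane params
            raise ParameterError("could not generate a filter-passing fold-back")
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        dna = rna.replace("U", "T")
        if strand == "-":
            dna = reverse_complement(dna)
        background[start : start + implant_len] = list(dna)
        is_known = k < n_known
        implants.append(
            PlantedImplant(
                genome_id=genome_id,
                start=start,
                end=start + implant_len,
                strand=strand,
                sequence=rna,
                is_known_mirna=is_known,
            )
        )
        if is_known:
            known_entries.append((f"mir-{k + 1}", rna))

    genome = GenomeSequence(id=genome_id, residues="".join(background))
    known = KnownMiRNASet(entries=tuple(known_entries), source_tag="synthetic")
    return genome, known, PlantedTruth(implants=tuple(implants))


def write_truth_table(truth: PlantedTruth, path: str | Path) -> None:
    """Tab-separated truth table: genome_id, start, end, strand, is_known."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["genome_id", "start", "end", "strand", "is_known"])
        for im in truth.implants:
            w.writerow(
                [im.genome_id, im.start, im.end, im.strand, int(im.is_known_mirna)]
            )


def read_truth_table(path: str | Path) -> PlantedTruth:
    implants = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            implants.append(
                PlantedImplant(
                    genome_id=row["genome_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    sequence="",
                    is_known_mirna=bool(int(row["is_known"])),
                )
            )
    return PlantedTruth(implants=tuple(implants))
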