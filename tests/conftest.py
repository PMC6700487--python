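import math

import numpy as np
import pytest

from mirhairpin.folding import (
    DEFAULT_MODEL,
    DEFAULT_TEMPERATURE,
    GAS_CONSTANT_KCAL,
    SecondaryStructure,
    dotbracket_to_pairs,
    structure_energy,
)
from mirhairpin.hairpin_extraction import Hairpin

RT = GAS_CONSTANT_KCAL * DEFAULT_TEMPERATURE


def build_hairpin(
    sequence: str,
    dotbracket: str,
    genome_id: str = "g1",
    start: int = 0,
    strand: str = "+",
    label: str = "unlabeled",
) -> Hairpin:
    """Hairpin with a hand-specified structure (energy from the pair-count model)."""
    pairs = dotbracket_to_pairs(dotbracket)
    structure = SecondaryStructure(
        sequence=sequence,
        dotbracket=dotbracket,
        pairs=pairs,
        mfe=structure_energy(sequence, pairs, DEFAULT_MODEL),
    )
    return Hairpin(
        sequence=sequence,
        structure=structure,
        genome_id=genome_id,
        start=start,
        end=start + len(sequence),
        strand=strand,
        label=label,
    )


def seq_for_dotbracket(dotbracket: str) -> str:
    """A sequence realizing a dot-bracket with G:C pairs and A elsewhere."""
    out = []
    for c in dotbracket:
        out.append({"(": "G", ")": "C", ".": "A"}[c])
    return "".join(out)


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


def ensemble_by_enumeration(structures):
    """Brute-force Z, EFE, pair probabilities and diversity from a structure set."""
    Z = sum(math.exp(-s.mfe / RT) for s in structures)
    n = len(structures[0].sequence)
    P = np.zeros((n, n))
    for s in structures:
        w = math.exp(-s.mfe / RT) / Z
        for i, j in s.pair_list():
            P[i, j] += w
            P[j, i] += w
    efe = -RT * math.log(Z)
    mfe = min(s.mfe for s in structures)
    freq = math.exp(-mfe / RT) / Z
    upper = np.triu(P, 1)
    diversity = float(np.sum(2 * upper * (1 - upper)))
    return {"Z": Z, "efe": efe, "mfe": mfe, "freq": freq, "P": P, "diversity": diversity}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
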