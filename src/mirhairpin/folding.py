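"""RNA secondary-structure prediction behind a pluggable backend contract.

Three routes to a structure live here:

* a bundled exact dynamic-programming folder over a deliberately simple,
  non-physical pair-count energy model (``E(S) = -sum e(i,j)`` with
  e(GC)=3, e(AU)=2, e(GU)=1 kcal/mol and a minimum hairpin loop of 3 nt),
  with a McCaskill-style partition function for ensemble quantities;
* an adapter for the ViennaRNA ``RNA`` python bindings (the production
  nearest-neighbour engine), selected with ``backend="vienna"``;
* an exhaustive enumeration of all nested structures, usable as an
  independent oracle on short sequences.

The toy model keeps the entire pipeline deterministic and verifiable
against enumeration while the backend contract admits the real engine.
``N`` is accepted as an unpairable residue so windows containing a small
fraction of ambiguous bases still fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _kernels
from .errors import BackendUnavailableError, InputError

GAS_CONSTANT_KCAL = 0.0019872  # kcal / (mol K)
DEFAULT_TEMPERATURE = 310.15  # kelvin (37 C, RNAfold default)

_ALPHABET = "ACGUN"
_ENCODE = {c: i for i, c in enumerate(_ALPHABET)}
_ENCODE["T"] = _ENCODE["U"]  # tolerate DNA input


@dataclass(frozen=True)
class EnergyModel:
    """Pair-count energy model: each pair releases a fixed energy.

    ``gc``/``au``/``gu`` are the energies (kcal/mol, positive = released)
    of the three admissible pair classes; ``min_loop`` is the minimum
    number of unpaired nucleotides in a hairpin loop.
    """

    gc: float = 3.0
    au: float = 2.0
    gu: float = 1.0
    min_loop: int = 3

    def table(self) -> np.ndarray:
        t = np.zeros((5, 5), dtype=np.float64)
        A, C, G, U = 0, 1, 2, 3
        t[G, C] = t[C, G] = self.gc
        t[A, U] = t[U, A] = self.au
        t[G, U] = t[U, G] = self.gu
        return t

    def pair_energy(self, a: str, b: str) -> float:
        return float(self.table()[_ENCODE[a], _ENCODE[b]])


DEFAULT_MODEL = EnergyModel()


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure with its free energy.

    ``pairs[i]`` is the partner of position i, or -1 when unpaired;
    ``dotbracket`` is the equivalent string over ``( . )``; ``mfe`` is
    the structure's free energy in kcal/mol (non-positive under the
    pair-count model).
    """

    sequence: str
    dotbracket: str
    pairs: tuple[int, ...]
    mfe: float

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pairs) if j > i)

    def pair_list(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in enumerate(self.pairs) if j > i]


@dataclass(frozen=True)
class EnsembleData:
    """Boltzmann-ensemble quantities of a sequence.

    ``efe`` is the ensemble free energy -RT ln Z; ``mfe_frequency`` the
    probability of the MFE structure; ``diversity`` the expected base-pair
    distance within the ensemble; ``pair_prob`` the symmetric matrix of
    base-pair probabilities p_ij.
    """

    efe: float
    mfe_frequency: float
    diversity: float
    pair_prob: np.ndarray


def encode(sequence: str) -> np.ndarray:
    if not sequence:
        raise InputError("empty sequence cannot be folded")
    try:
        return np.array([_ENCODE[c] for c in sequence.upper()], dtype=np.int64)
    except KeyError as exc:
        raise InputError(
            f"invalid residue {exc.args[0]!r} in sequence (alphabet A/C/G/U, N unpairable)"
        ) from None


def pairs_to_dotbracket(pairs) -> str:
    out = []
    for i, j in enumerate(pairs):
        if j < 0:
            out.append(".")
        elif j > i:
            out.append("(")
        else:
            out.append(")")
    return "".join(out)


def dotbracket_to_pairs(dotbracket: str) -> tuple[int, ...]:
    pairs = [-1] * len(dotbracket)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise InputError(f"unbalanced dot-bracket {dotbracket!r}")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
    if stack:
        raise InputError(f"unbalanced dot-bracket {dotbracket!r}")
    return tuple(pairs)


def structure_energy(sequence: str, pairs, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Free energy of a given structure under the pair-count model."""
    return -sum(
        model.pair_energy(sequence[i], sequence[j]) for i, j in enumerate(pairs) if j > i
    )


def _traceback(enc: np.ndarray, W: np.ndarray, etab: np.ndarray, min_loop: int) -> list[int]:
    """Deterministic traceback: prefer pairing i with the largest admissible j."""
    n = enc.shape[0]
    pairs = [-1] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        target = W[i, j]
        if target == 0.0:
            continue
        paired = False
        for k in range(j, i + min_loop, -1):
            e = etab[enc[i], enc[k]]
            if e > 0.0:
                v = e + W[i + 1, k - 1]
                if k + 1 <= j:
                    v += W[k + 1, j]
                if abs(v - target) < 1e-9:
                    pairs[i] = k
                    pairs[k] = i
                    stack.append((i + 1, k - 1))
                    if k + 1 <= j:
                        stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return pairs


def fold_mfe(sequence: str, model: EnergyModel = DEFAULT_MODEL) -> SecondaryStructure:
    """Minimum-free-energy structure under the pair-count model (exact DP)."""
    enc = encode(sequence)
    etab = model.table()
    W = _kernels.mfe_fill(enc, etab, model.min_loop)
    if enc.shape[0] - 1 < model.min_loop + 1:
        pairs = [-1] * enc.shape[0]
        score = 0.0
    else:
        score = W[0, enc.shape[0] - 1]
        pairs = _traceback(enc, W, etab, model.min_loop)
    return SecondaryStructure(
        sequence=sequence.upper().replace("T", "U"),
        dotbracket=pairs_to_dotbracket(pairs),
        pairs=tuple(pairs),
        mfe=-float(score),
    )


def fold_ensemble(
    sequence: str,
    model: EnergyModel = DEFAULT_MODEL,
    temperature: float = DEFAULT_TEMPERATURE,
) -> EnsembleData:
    """Partition-function quantities via a scaled inside/outside DP.

    Z sums exp(-E(S)/RT) over every nested structure (hairpin loops
    >= min_loop); base-pair probabilities come from the matching outside
    pass.  Per-nucleotide scaling by exp(mfe/(n RT)) keeps the tables in
    float range for long, strongly pairing sequences.
    """
    enc = encode(sequence)
    n = enc.shape[0]
    rt = GAS_CONSTANT_KCAL * temperature
    mfe = fold_mfe(sequence, model).mfe
    etab = model.table()
    s0 = math.exp(mfe / (n * rt))  # mfe <= 0 so s0 <= 1
    wtab = np.where(etab > 0.0, np.exp(etab / rt) * s0 * s0, 0.0)
    Z = _kernels.inside_fill(enc, wtab, model.min_loop, s0)
    O = _kernels.outside_fill(enc, wtab, model.min_loop, s0, Z)
    P = _kernels.pair_probs(enc, wtab, model.min_loop, Z, O)
    efe = -rt * (math.log(Z[0, n]) - n * math.log(s0))
    mfe_frequency = math.exp((efe - mfe) / rt)
    diversity = float(np.sum(2.0 * np.triu(P, 1) * (1.0 - np.triu(P, 1))))
    return EnsembleData(
        efe=efe, mfe_frequency=mfe_frequency, diversity=diversity, pair_prob=P
    )


_ENUM_GUARD = 30


def enumerate_structures(
    sequence: str, min_loop: int = 3, model: EnergyModel = DEFAULT_MODEL
) -> list[SecondaryStructure]:
    """Every nested structure over admissible pairs (independent oracle).

    Includes the empty structure; duplicates are impossible because the
    leftmost-base decomposition is unambiguous.  Refuses sequences longer
    than 30 nt (combinatorial guard).
    """
    if len(sequence) > _ENUM_GUARD:
        raise InputError(
            f"enumeration limited to sequences of length <= {_ENUM_GUARD} "
            f"(got {len(sequence)})"
        )
    enc = encode(sequence)
    etab = model.table()
    seq = sequence.upper().replace("T", "U")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        # all pair sets on half-open region [i, j)
        if j - i <= 0:
            return ((),)
        out = list(rec(i + 1, j))
        for k in range(i + min_loop + 1, j):
            if etab[enc[i], enc[k]] > 0.0:
                for left in rec(i + 1, k):
                    for right in rec(k + 1, j):
                        out.append(((i, k),) + left + right)
        return tuple(out)

    structures = []
    for pairset in rec(0, len(seq)):
        pairs = [-1] * len(seq)
        for a, b in pairset:
            pairs[a] = b
            pairs[b] = a
        structures.append(
            SecondaryStructure(
                sequence=seq,
                dotbracket=pairs_to_dotbracket(pairs),
                pairs=tuple(pairs),
                mfe=structure_energy(seq, pairs, model),
            )
        )
    rec.cache_clear()
    return structures


class FoldBackend:
    """Contract for folding engines: an MFE structure and ensemble data."""

    name: str = "abstract"
    capabilities: frozenset = frozenset()

    def fold(self, sequence: str) -> SecondaryStructure:
        raise NotImplementedError

    def ensemble(self, sequence: str) -> EnsembleData:
        raise NotImplementedError


class ToyBackend(FoldBackend):
    """The bundled exact pair-count folder (deterministic, offline)."""

    name = "toy"
    capabilities = frozenset({"mfe", "ensemble"})

    def __init__(
        self,
        model: EnergyModel = DEFAULT_MODEL,
        temperature: float = DEFAULT_TEMPERATURE,
    ):
        self.model = model
        self.temperature = temperature

    def fold(self, sequence: str) -> SecondaryStructure:
        return fold_mfe(sequence, self.model)

    def ensemble(self, sequence: str) -> EnsembleData:
        return fold_ensemble(sequence, self.model, self.temperature)


class ViennaRNABackend(FoldBackend):
    """Adapter for the ViennaRNA python bindings (nearest-neighbour model)."""

    name = "vienna"
    capabilities = frozenset({"mfe", "ensemble"})

    def __init__(self, temperature_celsius: float | None = None):
        try:
            import RNA  # noqa: PLC0415
        except ImportError as exc:
            raise BackendUnavailableError(
                "ViennaRNA python bindings not importable; install the "
                "'viennarna' package or select the 'toy' backend"
            ) from exc
        self._RNA = RNA
        self.temperature_celsius = temperature_celsius

    def _compound(self, sequence: str):
        RNA = self._RNA
        md = RNA.md()
        if self.temperature_celsius is not None:
            md.temperature = self.temperature_celsius
        return RNA.fold_compound(sequence, md)

    def fold(self, sequence: str) -> SecondaryStructure:
        fc = self._compound(sequence)
        db, mfe = fc.mfe()
        return SecondaryStructure(
            sequence=sequence.upper().replace("T", "U"),
            dotbracket=db,
            pairs=dotbracket_to_pairs(db),
            mfe=float(mfe),
        )

    def ensemble(self, sequence: str) -> EnsembleData:
        RNA = self._RNA
        fc = self._compound(sequence)
        db, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        _, efe = fc.pf()
        n = len(sequence)
        P = np.zeros((n, n))
        bpp = fc.bpp()  # 1-based upper-triangular
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                p = bpp[i][j]
                if p > 0.0:
                    P[i - 1, j - 1] = P[j - 1, i - 1] = p
        md = fc.params.model_details if hasattr(fc, "params") else RNA.md()
        kt = RNA.exp_param(md).kT / 1000.0 if hasattr(RNA, "exp_param") else None
        if kt is None or kt <= 0:
            kt = GAS_CONSTANT_KCAL * (273.15 + (self.temperature_celsius or 37.0))
        freq = math.exp((efe - mfe) / kt)
        diversity = float(fc.mean_bp_distance())
        return EnsembleData(
            efe=float(efe), mfe_frequency=freq, diversity=diversity, pair_prob=P
        )


def get_backend(name: str, **kwargs) -> FoldBackend:
    """Backend factory; raises :class:`BackendUnavailableError` early when
    the requested engine cannot be loaded."""
    if name == "toy":
        return ToyBackend(**kwargs)
    if name in ("vienna", "external"):
        return ViennaRNABackend(**kwargs)
    raise BackendUnavailableError(f"unknown folding backend {name!r}")
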