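"""Composition-based feature extraction.

Twelve feature models combine overlapping k-mer frequency blocks over
two alphabets — the 20 canonical amino acids and a reduced 7-group
"side chain" alphabet — with eight physicochemical "extra" features.
Block widths are fixed by the alphabets: amino-acid 2-mers (400) and
3-mers (8,000); side-chain 2-mers (49), 3-mers (343) and 4-mers
(2,401); plus the 8 extras. The full model ("all") therefore has
11,201 features and the tri + tetra-side-chain + extras model
("tetra_sc_tri_p") has 10,409.

k-mer frequencies use overlapping windows normalized by the number of
valid windows, so every k-mer block of a sequence of length >= k sums
to exactly 1. Windows containing the unknown-residue letter X are
excluded from both numerator and denominator.

The extra features (isoelectric point, instability index, length,
aromaticity, molar extinction coefficient under reduced and disulfide
assumptions, GRAVY hydropathy, molecular weight) are computed with
Biopython's ProtParam; X residues are excluded from those computations
except for the length feature, which counts all residues.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from phagenn.seqio import CANONICAL_AA, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SideChainAlphabet:
    """Total single-valued mapping of the 20 canonical amino acids onto
    7 side-chain chemical group symbols."""

    groups: Mapping[str, str]
    name: str = "side_chain_7"

    def __post_init__(self) -> None:
        missing = set(CANONICAL_AA) - set(self.groups)
        if missing:
            raise ValueError(f"unmapped amino acids: {sorted(missing)}")
        symbols = set(self.groups[a] for a in CANONICAL_AA)
        if len(symbols) != 7:
            raise ValueError(f"expected 7 group symbols, got {len(symbols)}")

    @property
    def symbols(self) -> str:
        """Group symbols in sorted (lexicographic) order."""
        return "".join(sorted(set(self.groups[a] for a in CANONICAL_AA)))


#: Default 7-group chemical partition: aliphatic (a), aromatic (r),
#: basic (b), acidic (d), polar amide/hydroxyl (p), sulfur (s),
#: conformationally special (c). Injectable, so an alternative grouping
#: can be dropped in; any total 7-group mapping preserves all block
#: dimensionalities.
DEFAULT_SIDE_CHAIN = SideChainAlphabet(
    groups={
        "A": "a", "V": "a", "L": "a", "I": "a",
        "F": "r", "W": "r", "Y": "r",
        "K": "b", "R": "b", "H": "b",
        "D": "d", "E": "d",
        "S": "p", "T": "p", "N": "p", "Q": "p",
        "C": "s", "M": "s",
        "G": "c", "P": "c",
    },
)

EXTRA_FEATURE_NAMES = (
    "isoelectric_point",
    "instability_index",
    "length",
    "aromaticity",
    "extinction_reduced",
    "extinction_cystines",
    "gravy",
    "molecular_weight",
)

BLOCK_DIMS = {
    "aa-2mer": 400,
    "aa-3mer": 8000,
    "sc-2mer": 49,
    "sc-3mer": 343,
    "sc-4mer": 2401,
    "extra": 8,
}

#: Feature blocks per model, in canonical concatenation order
#: (aa-2mer, aa-3mer, sc-2mer, sc-3mer, sc-4mer, extra).
_BLOCK_ORDER = ("aa-2mer", "aa-3mer", "sc-2mer", "sc-3mer", "sc-4mer", "extra")
_MODEL_BLOCKS = {
    "di_sc": ("sc-2mer",),
    "di_sc_p": ("sc-2mer", "extra"),
    "tri_sc": ("sc-3mer",),
    "tri_sc_p": ("sc-3mer", "extra"),
    "tetra_sc": ("sc-4mer",),
    "tetra_sc_p": ("sc-4mer", "extra"),
    "di": ("aa-2mer",),
    "di_p": ("aa-2mer", "extra"),
    "tri": ("aa-3mer",),
    "tri_p": ("aa-3mer", "extra"),
    "tetra_sc_tri_p": ("aa-3mer", "sc-4mer", "extra"),
    "all": _BLOCK_ORDER,
}

MODEL_NAMES = tuple(_MODEL_BLOCKS)


@dataclass(frozen=True)
class ExtraFeatures:
    isoelectric_point: float
    instability_index: float
    length: int
    aromaticity: float
    extinction_reduced: float
    extinction_cystines: float
    gravy: float
    molecular_weight: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in EXTRA_FEATURE_NAMES], dtype=float)


@dataclass(frozen=True)
class FeatureSchema:
    """The ordered feature layout of one model."""

    model_name: str
    blocks: tuple[tuple[str, tuple[str, ...]], ...]
    side_chain: SideChainAlphabet = DEFAULT_SIDE_CHAIN

    @property
    def total_dim(self) -> int:
        return sum(len(names) for _, names in self.blocks)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(itertools.chain.from_iterable(names for _, names in self.blocks))

    @property
    def block_kinds(self) -> tuple[str, ...]:
        return tuple(kind for kind, _ in self.blocks)

    def block_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for kind, names in self.blocks:
            out[kind] = slice(start, start + len(names))
            start += len(names)
        return out


def _kmer_names(alphabet: str, k: int) -> tuple[str, ...]:
    return tuple("".join(t) for t in itertools.product(sorted(alphabet), repeat=k))


def get_schema(model_name: str, side_chain: SideChainAlphabet = DEFAULT_SIDE_CHAIN) -> FeatureSchema:
    """Build the feature schema for one of the 12 model names."""
    if model_name not in _MODEL_BLOCKS:
        raise ValueError(
            f"unknown model {model_name!r}; valid names: {', '.join(MODEL_NAMES)}"
        )
    blocks = []
    for kind in _BLOCK_ORDER:
        if kind not in _MODEL_BLOCKS[model_name]:
            continue
        if kind == "extra":
            names: tuple[str, ...] = EXTRA_FEATURE_NAMES
        elif kind.startswith("aa"):
            k = int(kind[3])
            names = _kmer_names(CANONICAL_AA, k)
        else:
            k = int(kind[3])
            names = _kmer_names(side_chain.symbols, k)
        blocks.append((kind, names))
    return FeatureSchema(model_name=model_name, blocks=tuple(blocks), side_chain=side_chain)


def translate_side_chain(sequence: str, alphabet: SideChainAlphabet = DEFAULT_SIDE_CHAIN) -> str:
    """Replace each amino acid by its side-chain group symbol.

    X passes through unchanged (it stays "unknown" in both alphabets);
    any other unmapped letter raises, naming the position.
    """
    out = []
    for i, ch in enumerate(sequence):
        if ch == "X":
            out.append("X")
        elif ch in alphabet.groups:
            out.append(alphabet.groups[ch])
        else:
            raise ValueError(f"unmapped letter {ch!r} at position {i}")
    return "".join(out)


def kmer_frequencies(sequence: str, k: int, alphabet: str | SideChainAlphabet = CANONICAL_AA) -> np.ndarray:
    """Overlapping k-mer frequencies, lexicographically ordered.

    ``alphabet`` is either a string of letters (the canonical 20) or a
    :class:`SideChainAlphabet`, in which case the sequence is first
    translated to group symbols. Windows containing X are excluded from
    numerator and denominator. Sequences shorter than k yield an
    all-zero vector with a logged warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(alphabet, SideChainAlphabet):
        sequence = translate_side_chain(sequence, alphabet)
        letters = alphabet.symbols
    else:
        letters = "".join(sorted(alphabet))
    n_sym = len(letters)
    dim = n_sym ** k
    if len(sequence) < k:
        logger.warning("sequence shorter than k=%d; returning zeros", k)
        return np.zeros(dim)
    code = {ch: i for i, ch in enumerate(letters)}
    idx = np.array([code.get(ch, -1) for ch in sequence], dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(idx, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return np.zeros(dim)
    powers = n_sym ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = windows[valid] @ powers
    counts = np.bincount(codes, minlength=dim).astype(float)
    return counts / counts.sum()


def compute_extra_features(sequence: str) -> ExtraFeatures:
    """Physicochemical summary features via Biopython's ProtParam.

    The length feature counts every residue including X; all other
    quantities are computed on the X-free sequence.
    """
    if not sequence:
        raise ValueError("empty sequence")
    clean = sequence.replace("X", "")
    if not clean:
        raise ValueError("sequence contains only unknown residues")
    pa = ProteinAnalysis(clean)
    ext_reduced, ext_cystines = pa.molar_extinction_coefficient()
    return ExtraFeatures(
        isoelectric_point=pa.isoelectric_point(),
        instability_index=pa.instability_index(),
        length=len(sequence),
        aromaticity=pa.aromaticity(),
        extinction_reduced=float(ext_reduced),
        extinction_cystines=float(ext_cystines),
        gravy=pa.gravy(),
        molecular_weight=pa.molecular_weight(),
    )


_KIND_TO_ARGS = {
    "aa-2mer": (2, "aa"),
    "aa-3mer": (3, "aa"),
    "sc-2mer": (2, "sc"),
    "sc-3mer": (3, "sc"),
    "sc-4mer": (4, "sc"),
}


def extract(record: ProteinRecord | str, schema: FeatureSchema) -> np.ndarray:
    """Extract one feature vector (length ``schema.total_dim``) for a
    record or raw sequence. Extra features are raw here; standardization
    happens at training time, per fold."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    parts = []
    for kind, _ in schema.blocks:
        if kind == "extra":
            parts.append(compute_extra_features(seq).as_array())
        else:
            k, alph = _KIND_TO_ARGS[kind]
            alphabet = CANONICAL_AA if alph == "aa" else schema.side_chain
            parts.append(kmer_frequencies(seq, k, alphabet))
    return np.concatenate(parts)


def extract_matrix(records: Sequence[ProteinRecord | str], schema: FeatureSchema) -> np.ndarray:
    """Stack feature vectors for many records: (n_records, total_dim)."""
    if not records:
        return np.zeros((0, schema.total_dim))
    return np.vstack([extract(r, schema) for r in records])
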