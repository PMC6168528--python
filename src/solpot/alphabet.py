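"""Canonical amino-acid alphabet and unordered-pair indexing.

All tensors in the package are indexed by a fixed 20-letter alphabet and a
canonical ordering of the 210 unordered residue pairs.  Keeping the ordering
in one place guarantees that count tensors, potential tables and significance
reports derived in different runs line up slot for slot.
"""

from __future__ import annotations

import numpy as np

#: Fixed one-letter alphabet order used for all pair indexing.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

N_AA = 20
N_PAIRS = N_AA * (N_AA + 1) // 2  # 210 unordered pairs

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Selenomethionine is treated as methionine; every other modified residue is
# dropped at parse time.
RESIDUE_ALIASES = {"MSE": "MET"}

_PAIR_INDEX = np.zeros((N_AA, N_AA), dtype=np.int64)
_PAIR_LIST: list[tuple[str, str]] = []
_k = 0
for _i in range(N_AA):
    for _j in range(_i, N_AA):
        _PAIR_INDEX[_i, _j] = _k
        _PAIR_INDEX[_j, _i] = _k
        _PAIR_LIST.append((AA_ORDER[_i], AA_ORDER[_j]))
        _k += 1

#: (20, 20) symmetric lookup: type indices -> canonical pair slot in [0, 210).
PAIR_INDEX_TABLE = _PAIR_INDEX
#: Pair slot -> (aa1, aa2) with aa1 before aa2 in ``AA_ORDER``.
PAIR_LIST = tuple(_PAIR_LIST)


def aa_index(aa: str) -> int:
    """Index of a one-letter residue type in the canonical alphabet."""
    try:
        return AA_INDEX[aa]
    except KeyError:
        raise ValueError(f"unknown amino-acid type {aa!r}") from None


def pair_index(aa1: str, aa2: str) -> int:
    """Canonical slot of the unordered pair (aa1, aa2); order-insensitive."""
    return int(PAIR_INDEX_TABLE[aa_index(aa1), aa_index(aa2)])


def pair_name(slot: int) -> tuple[str, str]:
    """Inverse of :func:`pair_index`."""
    return PAIR_LIST[slot]


def validate_sequence(sequence: str) -> None:
    bad = set(sequence) - set(AA_ORDER)
    if bad:
        raise ValueError(f"sequence contains non-standard letters: {sorted(bad)}")
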