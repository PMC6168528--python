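"""Distance-binned, separation-stratified residue-pair occurrence counting.

Counts are stored in a dense tensor indexed by (unordered residue pair,
sequence-separation class, distance bin).  Distances between side-chain
centroids are binned on [3, 10) Å in 0.2 Å bins (35 core bins) with a last
overflow bin for d >= 10 Å.  Pairs at sequence separation |i-j| = 2..8 each
get their own class; all separations above 8 are pooled into a single
long-range class, where chain connectivity no longer constrains the
distance distribution.

Two statistical repair layers compensate for small datasets: a five-tap
smoothing of neighbouring distance bins with weights 1/a^2, 1/a, 1, 1/a,
1/a^2 (a = 4/3 by default), and an occurrence threshold (default 10) below
which a bin is masked and its potential later forced to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import convolve1d

from .alphabet import (
    AA_INDEX,
    N_PAIRS,
    PAIR_INDEX_TABLE,
    PAIR_LIST,
    pair_index,
)
from .config import RunConfig
from .structure_io import ProteinRecord

#: Separation-class labels in storage order.
SEP_LABELS = ("2", "3", "4", "5", "6", "7", "8", ">8")
N_SEP = len(SEP_LABELS)
LONG_RANGE = N_SEP - 1  # index of the ">8" class


class SchemeMismatchError(ValueError):
    """Two tensors/tables built under different binning schemes were mixed."""


class TensorStateError(ValueError):
    """An operation was applied to a tensor in the wrong raw/smoothed state."""


@dataclass(frozen=True)
class BinningScheme:
    """Half-open distance bins [d_min, d_max) plus an overflow bin.

    With the defaults: 35 core bins of width 0.2 Å on [3, 10) and one
    overflow bin for d >= 10 Å, i.e. 36 bins in total.  Setting
    ``separate_overflow=False`` routes d >= d_max into the last core bin
    instead (35 bins in total).
    """

    d_min: float = 3.0
    d_max: float = 10.0
    bin_width: float = 0.2
    separate_overflow: bool = True

    def __post_init__(self) -> None:
        n = (self.d_max - self.d_min) / self.bin_width
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError("bin_width must evenly divide the distance range")

    @property
    def n_core_bins(self) -> int:
        return int(round((self.d_max - self.d_min) / self.bin_width))

    @property
    def n_bins(self) -> int:
        return self.n_core_bins + (1 if self.separate_overflow else 0)

    @property
    def overflow_bin(self) -> int:
        return self.n_bins - 1

    def bin_edges(self) -> np.ndarray:
        """(n_bins, 2) array of [lo, hi) edges; the overflow hi is +inf."""
        lo = self.d_min + self.bin_width * np.arange(self.n_core_bins)
        edges = np.column_stack([lo, lo + self.bin_width])
        if self.separate_overflow:
            edges = np.vstack([edges, [self.d_max, np.inf]])
        else:
            edges[-1, 1] = np.inf
        return edges

    def bin_centers(self) -> np.ndarray:
        """Mid-bin distances; the overflow bin reports d_max + b/2."""
        centers = self.d_min + self.bin_width * (np.arange(self.n_core_bins) + 0.5)
        if self.separate_overflow:
            centers = np.append(centers, self.d_max + self.bin_width / 2)
        return centers

    @classmethod
    def from_config(cls, config: RunConfig) -> "BinningScheme":
        return cls(
            d_min=config.d_min,
            d_max=config.d_max,
            bin_width=config.bin_width,
            separate_overflow=config.separate_overflow,
        )


def bin_index(d: float, scheme: BinningScheme) -> int:
    """Bin of a single distance; d below d_min is clamped into bin 0."""
    if not np.isfinite(d) or d <= 0:
        raise ValueError(f"distance must be positive and finite, got {d}")
    idx, _ = bin_indices(np.array([d]), scheme)
    return int(idx[0])


def bin_indices(d: np.ndarray, scheme: BinningScheme) -> tuple[np.ndarray, int]:
    """Vectorized binning; returns (indices, number of clamped d < d_min)."""
    d = np.asarray(d, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("distances must be positive and finite")
    raw = np.floor((d - scheme.d_min) / scheme.bin_width).astype(np.int64)
    n_clamped = int(np.sum(raw < 0))
    idx = np.clip(raw, 0, scheme.overflow_bin if scheme.separate_overflow
                  else scheme.n_core_bins - 1)
    if scheme.separate_overflow:
        idx[d >= scheme.d_max] = scheme.overflow_bin
    return idx, n_clamped


def separation_class(sep: np.ndarray | int) -> np.ndarray | int:
    """Class index for sequence separations >= 2 (2..8 own classes, then >8)."""
    sep_arr = np.asarray(sep)
    if np.any(sep_arr < 2):
        raise ValueError("sequence separation below 2 has no class")
    out = np.minimum(sep_arr - 2, LONG_RANGE)
    return out if isinstance(sep, np.ndarray) else int(out)


@dataclass
class PairCountTensor:
    """Occurrence counts n(s, s', sep-class, d-bin) with symmetric pair slots.

    Raw tensors hold integer counts; smoothed tensors hold the weighted
    neighbour sums and are real-valued.  ``n_clamped`` tracks how many
    sub-d_min distances were clamped into bin 0.
    """

    counts: np.ndarray
    scheme: BinningScheme
    state: str = "raw"
    provenance: str = "custom"
    n_clamped: int = 0

    def __post_init__(self) -> None:
        expected = (N_PAIRS, N_SEP, self.scheme.n_bins)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.state not in ("raw", "smoothed"):
            raise ValueError(f"unknown state {self.state!r}")

    @classmethod
    def zeros(cls, scheme: BinningScheme, **kwargs) -> "PairCountTensor":
        return cls(
            counts=np.zeros((N_PAIRS, N_SEP, scheme.n_bins)), scheme=scheme, **kwargs
        )

    def get(self, aa1: str, aa2: str) -> np.ndarray:
        """(n_sep, n_bins) counts for an unordered pair; order-insensitive."""
        return self.counts[pair_index(aa1, aa2)]

    # marginals, per separation class ------------------------------------
    def pair_totals(self) -> np.ndarray:
        """n_ss' : (N_PAIRS, N_SEP) totals over distance bins."""
        return self.counts.sum(axis=2)

    def bin_totals(self) -> np.ndarray:
        """n_d : (N_SEP, n_bins) totals over residue pairs."""
        return self.counts.sum(axis=0)

    def grand_totals(self) -> np.ndarray:
        """n : (N_SEP,) totals per separation class."""
        return self.counts.sum(axis=(0, 2))

    def copy(self) -> "PairCountTensor":
        return replace(self, counts=self.counts.copy())


def count_pairs(protein: ProteinRecord, scheme: BinningScheme) -> PairCountTensor:
    """Raw pair-count tensor of one protein.

    Every same-chain residue pair (i, j) with j - i >= 2 contributes one
    count at (pair type, separation class, centroid-distance bin).
    """
    if not protein.sites:
        raise ValueError(f"{protein.protein_id}: no residue sites")
    n = protein.n_residues
    tensor = PairCountTensor.zeros(scheme, provenance=protein.protein_id)
    if n < 3:
        return tensor
    i_idx, j_idx = np.triu_indices(n, k=2)
    chain = protein.chain_ids()
    same_chain = chain[i_idx] == chain[j_idx]
    i_idx, j_idx = i_idx[same_chain], j_idx[same_chain]
    if i_idx.size == 0:
        return tensor
    cent = protein.centroids()
    d = np.linalg.norm(cent[j_idx] - cent[i_idx], axis=1)
    bins, n_clamped = bin_indices(d, scheme)
    classes = separation_class(j_idx - i_idx)
    aa_idx = np.array([AA_INDEX[a] for a in protein.sequence])
    pair_idx = PAIR_INDEX_TABLE[aa_idx[i_idx], aa_idx[j_idx]]
    np.add.at(tensor.counts, (pair_idx, classes, bins), 1.0)
    tensor.n_clamped = n_clamped
    return tensor


def stack_counts(
    records: list[ProteinRecord], scheme: BinningScheme
) -> np.ndarray:
    """(n_proteins, N_PAIRS, N_SEP, n_bins) stacked raw counts."""
    return np.stack([count_pairs(r, scheme).counts for r in records])


def aggregate(tensors: list[PairCountTensor]) -> PairCountTensor:
    """Element-wise sum of raw tensors sharing one scheme."""
    if not tensors:
        raise ValueError("nothing to aggregate")
    scheme = tensors[0].scheme
    for t in tensors:
        if t.scheme != scheme:
            raise SchemeMismatchError("aggregate over mixed binning schemes")
        if t.state != "raw":
            raise TensorStateError("aggregate only raw tensors")
    total = np.sum([t.counts for t in tensors], axis=0)
    return PairCountTensor(
        counts=total,
        scheme=scheme,
        state="raw",
        provenance="aggregate",
        n_clamped=sum(t.n_clamped for t in tensors),
    )


def subtract(total: PairCountTensor, part: PairCountTensor) -> PairCountTensor:
    """Remove one protein's raw counts from a pooled raw tensor (leave-one-out)."""
    if total.scheme != part.scheme:
        raise SchemeMismatchError("subtract over mixed binning schemes")
    if total.state != "raw" or part.state != "raw":
        raise TensorStateError("subtract operates on raw tensors")
    out = total.counts - part.counts
    if np.any(out < -1e-9):
        raise ValueError("subtraction produced negative counts")
    return PairCountTensor(
        counts=np.maximum(out, 0.0),
        scheme=total.scheme,
        state="raw",
        provenance=f"{total.provenance}-minus-{part.provenance}",
        n_clamped=max(total.n_clamped - part.n_clamped, 0),
    )


def smoothing_kernel(alpha: float) -> np.ndarray:
    return np.array([1 / alpha**2, 1 / alpha, 1.0, 1 / alpha, 1 / alpha**2])


def smooth(tensor: PairCountTensor, alpha: float = 4.0 / 3.0) -> PairCountTensor:
    """Five-tap neighbour smoothing along the distance axis (zero padding).

    The overflow bin participates as an ordinary last neighbour; bins beyond
    either edge contribute nothing.  Applied independently within each
    separation class.
    """
    if tensor.state != "raw":
        raise TensorStateError("tensor is already smoothed")
    if alpha <= 1.0:
        raise ValueError("alpha must be larger than one")
    smoothed = convolve1d(
        tensor.counts, smoothing_kernel(alpha), axis=2, mode="constant", cval=0.0
    )
    return PairCountTensor(
        counts=smoothed,
        scheme=tensor.scheme,
        state="smoothed",
        provenance=tensor.provenance,
        n_clamped=tensor.n_clamped,
    )


def apply_threshold(
    tensor: PairCountTensor, min_occurrences: float = 10.0
) -> tuple[PairCountTensor, np.ndarray]:
    """Mask bins whose occurrence count is <= min_occurrences (strict '>').

    Returns the tensor unchanged plus a boolean mask of suppressed bins;
    masked bins later contribute a potential of exactly zero.
    """
    if min_occurrences <= 0:
        raise ValueError("min_occurrences must be positive")
    mask = tensor.counts <= min_occurrences
    return tensor, mask


def prepare_counts(
    raw: PairCountTensor, config: RunConfig
) -> tuple[PairCountTensor, np.ndarray]:
    """Apply the two statistical layers in the configured order.

    Default: smooth first, then threshold on the smoothed counts.  The
    alternative order thresholds the raw counts (zeroing sub-threshold bins)
    before smoothing, with the mask taken from the raw counts.
    """
    if config.layer_order == "smooth_then_threshold":
        smoothed = smooth(raw, config.alpha)
        return apply_threshold(smoothed, config.min_occurrences)
    # threshold_then_smooth
    _, mask = apply_threshold(raw, config.min_occurrences)
    censored = raw.copy()
    censored.counts[mask] = 0.0
    smoothed = smooth(censored, config.alpha)
    return smoothed, mask


# ---------------------------------------------------------------------------
# serialization

_TSV_HEADER = "aa1\taa2\tsep_class\tbin_lo\tbin_hi\tcount\n"


def write_tensor_tsv(tensor: PairCountTensor, path: str | Path) -> None:
    """Long-format TSV dump; raw integer tensors round-trip bit-exactly."""
    edges = tensor.scheme.bin_edges()
    is_raw = tensor.state == "raw"
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for p, (a1, a2) in enumerate(PAIR_LIST):
            for s, label in enumerate(SEP_LABELS):
                for b in range(tensor.scheme.n_bins):
                    v = tensor.counts[p, s, b]
                    val = str(int(v)) if is_raw else repr(float(v))
                    fh.write(
                        f"{a1}\t{a2}\t{label}\t{edges[b, 0]:.1f}\t"
                        f"{edges[b, 1]:.1f}\t{val}\n"
                    )


def tensor_to_json(tensor: PairCountTensor) -> str:
    payload = {
        "scheme": {
            "d_min": tensor.scheme.d_min,
            "d_max": tensor.scheme.d_max,
            "bin_width": tensor.scheme.bin_width,
            "separate_overflow": tensor.scheme.separate_overflow,
        },
        "state": tensor.state,
        "provenance": tensor.provenance,
        "n_clamped": tensor.n_clamped,
        "counts": tensor.counts.tolist(),
    }
    return json.dumps(payload)


def tensor_from_json(text: str) -> PairCountTensor:
    payload = json.loads(text)
    scheme = BinningScheme(**payload["scheme"])
    return PairCountTensor(
        counts=np.asarray(payload["counts"], dtype=float),
        scheme=scheme,
        state=payload["state"],
        provenance=payload["provenance"],
        n_clamped=payload["n_clamped"],
    )


def read_tensor_tsv(
    path: str | Path, scheme: BinningScheme, state: str = "raw"
) -> PairCountTensor:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    tensor = PairCountTensor.zeros(scheme, state=state)
    sep_idx = {label: i for i, label in enumerate(SEP_LABELS)}
    lo_to_bin = {round(edge, 6): i for i, edge in enumerate(scheme.bin_edges()[:, 0])}
    p_idx = df.apply(lambda r: pair_index(r["aa1"], r["aa2"]), axis=1).to_numpy()
    s_idx = df["sep_class"].map(sep_idx).to_numpy()
    b_idx = df["bin_lo"].round(6).map(lo_to_bin).to_numpy()
    tensor.counts[p_idx, s_idx, b_idx] = df["count"].to_numpy(dtype=float)
    return tensor
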