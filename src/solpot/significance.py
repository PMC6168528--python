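"""Randomized-split significance analysis of pair-potential differences.

For every unordered residue pair the soluble and insoluble potentials are
compared through two summary statistics over the distance bins of one
separation class (the long-range ">8" class by default):

    M = (1/N_d) * sum_d [ dW_insol(s, s', d) - dW_sol(s, s', d) ]
    V = (1/N_d) * sum_d [ dW_insol(s, s', d) - dW_sol(s, s', d) ]**2

Masked bins carry a stored value of zero and enter the sums as such.  With
this orientation M > 0 marks a solubilizing pair (the interaction is more
favourable — lower energy — in soluble proteins) and M < 0 an
insolubilizing one.

The null model re-runs the entire derivation on random equal-size
bipartitions of the full dataset.  Sig M is the fraction of null |M| values
strictly below the actual |M| (ties do not count), and analogously Sig V.
The strict criterion requires Sig M >= 0.95 and Sig V >= 0.95; the relaxed
criterion requires either.  No multiple-testing correction is applied
across the 210 pairs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import N_PAIRS, PAIR_LIST, ONE_TO_THREE, pair_index
from .config import RunConfig
from .counting import LONG_RANGE, SEP_LABELS
from .potentials import PotentialTable, derive_from_stack


@dataclass(frozen=True)
class PairDifferenceStats:
    """Per-pair M (kcal/mol) and V (kcal^2/mol^2) over the distance bins."""

    pair: tuple[str, str]
    M: float
    V: float
    n_bins_used: int

    def __post_init__(self) -> None:
        if self.V < -1e-12:
            raise ValueError("V must be non-negative")


@dataclass
class SignificanceResult:
    """Classification of one residue pair against the randomization null."""

    pair: tuple[str, str]
    M: float
    V: float
    sig_m: float
    sig_v: float
    strict: bool
    relaxed: bool
    direction: str  # "solubilizing" | "insolubilizing" | "none"
    n_shuffles: int
    seed: int


def _class_index(label: str) -> int:
    try:
        return SEP_LABELS.index(label)
    except ValueError:
        raise ValueError(f"unknown separation class {label!r}") from None


def compute_mv(
    w_sol: PotentialTable,
    w_insol: PotentialTable,
    config: RunConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (M, V, n_bins_used) for all 210 pairs in one class."""
    config = config or RunConfig()
    if w_sol.scheme != w_insol.scheme:
        raise ValueError("potential tables disagree on binning scheme")
    cls = _class_index(config.mv_separation_class)
    diff = w_insol.values[:, cls, :] - w_sol.values[:, cls, :]  # (P, B)
    if config.mv_bin_mode == "all_bins":
        n_d = diff.shape[1]
        m = diff.sum(axis=1) / n_d
        v = (diff**2).sum(axis=1) / n_d
        n_used = np.full(N_PAIRS, n_d)
    else:  # shared_support
        support = ~(w_sol.mask[:, cls, :] | w_insol.mask[:, cls, :])
        n_used = support.sum(axis=1)
        safe = np.maximum(n_used, 1)
        m = np.where(n_used > 0, (diff * support).sum(axis=1) / safe, 0.0)
        v = np.where(n_used > 0, (diff**2 * support).sum(axis=1) / safe, 0.0)
    return m, v, n_used


def pair_stats(
    w_sol: PotentialTable,
    w_insol: PotentialTable,
    aa1: str,
    aa2: str,
    config: RunConfig | None = None,
) -> PairDifferenceStats:
    """M/V statistics of a single unordered residue pair."""
    m, v, n_used = compute_mv(w_sol, w_insol, config)
    p = pair_index(aa1, aa2)
    return PairDifferenceStats(
        pair=PAIR_LIST[p], M=float(m[p]), V=float(v[p]), n_bins_used=int(n_used[p])
    )


def shuffle_null(
    stack: np.ndarray,
    config: RunConfig | None = None,
    n_shuffles: int | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Null samples of (|M|, V) from random equal-size bipartitions.

    ``stack`` holds per-protein raw count tensors.  Each shuffle bipartitions
    the proteins (odd sizes give the extra protein to the first half), runs
    the full derivation with the halves playing soluble/insoluble, and
    records per-pair |M| and V.  Deterministic given the seed.

    Returns (null_abs_m, null_v), each of shape (n_shuffles, 210).
    """
    config = config or RunConfig()
    n_shuffles = config.n_shuffles if n_shuffles is None else n_shuffles
    seed = config.seed if seed is None else seed
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be at least 1")
    n = stack.shape[0]
    if n < 4:
        raise ValueError("need at least 4 proteins for a meaningful null")
    rng = np.random.default_rng(seed)
    half = (n + 1) // 2
    null_abs_m = np.empty((n_shuffles, N_PAIRS))
    null_v = np.empty((n_shuffles, N_PAIRS))
    for k in range(n_shuffles):
        perm = rng.permutation(n)
        w_a, w_b, _ = derive_from_stack(stack, perm[:half], perm[half:], config)
        m, v, _ = compute_mv(w_b, w_a, config)  # (w_sol=w_b, w_insol=w_a) arbitrary
        null_abs_m[k] = np.abs(m)
        null_v[k] = v
    return null_abs_m, null_v


def _load_category_map() -> dict[frozenset, str]:
    text = (
        importlib.resources.files("solpot")
        .joinpath("data/pair_categories.tsv")
        .read_text()
    )
    mapping: dict[frozenset, str] = {}
    for line in text.strip().splitlines()[1:]:
        a, b, cat = line.split("\t")
        mapping[frozenset((a, b))] = cat
    return mapping


def pair_category(aa1: str, aa2: str) -> str:
    return _load_category_map().get(frozenset((aa1, aa2)), "miscellaneous")


def classify(
    m: np.ndarray,
    v: np.ndarray,
    null_abs_m: np.ndarray,
    null_v: np.ndarray,
    config: RunConfig | None = None,
) -> tuple[list[SignificanceResult], pd.DataFrame]:
    """Per-pair significance flags plus the ranked report table.

    Cauchy-Schwarz (V >= M^2) is asserted for every pair on every call: it
    must hold exactly for a mean and mean-square over the same bins.
    """
    config = config or RunConfig()
    if null_abs_m.size == 0:
        raise ValueError("null sample is empty")
    if np.any(v + 1e-9 < m**2):
        raise AssertionError("V >= M^2 violated — inconsistent M/V computation")
    sig_m = (null_abs_m < np.abs(m)[None, :]).mean(axis=0)
    sig_v = (null_v < v[None, :]).mean(axis=0)
    strict = (sig_m >= 0.95) & (sig_v >= 0.95)
    relaxed = (sig_m >= 0.95) | (sig_v >= 0.95)
    categories = _load_category_map()
    results = []
    rows = []
    for p, (a1, a2) in enumerate(PAIR_LIST):
        direction = "none"
        if m[p] > 0:
            direction = "solubilizing"
        elif m[p] < 0:
            direction = "insolubilizing"
        res = SignificanceResult(
            pair=(a1, a2),
            M=float(m[p]),
            V=float(v[p]),
            sig_m=float(sig_m[p]),
            sig_v=float(sig_v[p]),
            strict=bool(strict[p]),
            relaxed=bool(relaxed[p]),
            direction=direction,
            n_shuffles=null_abs_m.shape[0],
            seed=config.seed,
        )
        results.append(res)
        rows.append(
            {
                "category": categories.get(frozenset((a1, a2)), "miscellaneous"),
                "pair": f"{ONE_TO_THREE[a1]}-{ONE_TO_THREE[a2]}",
                "M": res.M,
                "SigM": res.sig_m,
                "V": res.V,
                "SigV": res.sig_v,
                "strict": res.strict,
                "relaxed": res.relaxed,
                "direction": res.direction,
            }
        )
    table = pd.DataFrame(rows)
    table["absM"] = table["M"].abs()
    table = (
        table.sort_values(["category", "absM"], ascending=[True, False])
        .drop(columns="absM")
        .reset_index(drop=True)
    )
    return results, table


def run_significance(
    stack: np.ndarray,
    sol_indices,
    insol_indices,
    config: RunConfig | None = None,
) -> tuple[list[SignificanceResult], pd.DataFrame, tuple[np.ndarray, np.ndarray]]:
    """Full analysis: actual M/V, randomization null, classification."""
    config = config or RunConfig()
    w_sol, w_insol, _ = derive_from_stack(stack, sol_indices, insol_indices, config)
    m, v, _ = compute_mv(w_sol, w_insol, config)
    null_abs_m, null_v = shuffle_null(stack, config)
    results, table = classify(m, v, null_abs_m, null_v, config)
    return results, table, (null_abs_m, null_v)
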