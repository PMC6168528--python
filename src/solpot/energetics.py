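"""Folding free energies, the solubility score and sequence features.

The folding free energy of a protein under a potential table is the sum of
dW(s_i, s_j, |i-j|, d_ij) over all same-chain residue pairs with j >= i+2.
The solubility score is the difference

    score = W_insol - W_sol

between the energies computed with the insoluble- and soluble-derived
potentials: soluble proteins sit deeper in the soluble potential, so a
larger (more positive) score predicts higher solubility.  Scores of
dataset members are computed with strict leave-one-out: the target
protein's own pair counts are removed from every derivation set before its
potentials are rebuilt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alphabet import validate_sequence
from .config import RunConfig
from .counting import BinningScheme, PairCountTensor, count_pairs, stack_counts
from .potentials import PotentialTable, derive_from_counts
from .structure_io import ProteinRecord, StructureDataset


@dataclass(frozen=True)
class EnergyResult:
    """Per-protein folding free energies (kcal/mol) and solubility score."""

    protein_id: str
    w_sol: float
    w_insol: float
    w_tot: float
    loo: bool

    @property
    def score(self) -> float:
        return self.w_insol - self.w_sol


@dataclass(frozen=True)
class SequenceFeatures:
    length: int
    isoelectric_point: float
    aliphatic_index: float
    vil_fraction: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not (0.0 < self.isoelectric_point < 14.0):
            raise ValueError("isoelectric point outside (0, 14)")
        if self.aliphatic_index < 0 or not (0.0 <= self.vil_fraction <= 1.0):
            raise ValueError("invalid feature values")


def folding_energy(
    protein: ProteinRecord,
    table: PotentialTable,
    tensor: PairCountTensor | None = None,
) -> float:
    """Total pair energy of one protein under a potential table.

    Because the potential is piecewise constant over distance bins, the
    double sum over residue pairs equals the contraction of the protein's
    raw pair-count tensor with the table values (masked bins hold zero).
    """
    if tensor is None:
        tensor = count_pairs(protein, table.scheme)
    elif tensor.scheme != table.scheme:
        raise ValueError("tensor and table disagree on binning scheme")
    return float(np.sum(tensor.counts * table.values))


def loo_tables(
    dataset: StructureDataset,
    index: int,
    config: RunConfig | None = None,
    stack: np.ndarray | None = None,
) -> tuple[PotentialTable, PotentialTable, PotentialTable]:
    """Potentials re-derived with protein ``index`` removed from all sets.

    Count subtraction on integer-valued tensors is exact, so the result is
    bit-identical to a from-scratch derivation without the target.
    """
    config = config or RunConfig()
    scheme = BinningScheme.from_config(config)
    if stack is None:
        stack = stack_counts(dataset.records, scheme)
    own = stack[index]
    sol_counts = stack[list(dataset.sol_indices)].sum(axis=0)
    insol_counts = stack[list(dataset.insol_indices)].sum(axis=0)
    if index in set(dataset.sol_indices):
        sol_counts = sol_counts - own
    else:
        insol_counts = insol_counts - own
    if sol_counts.sum() == 0 or insol_counts.sum() == 0:
        raise ValueError("leave-one-out emptied a derivation subset")
    return derive_from_counts(sol_counts, insol_counts, config, scheme)


def loo_energies(
    dataset: StructureDataset,
    config: RunConfig | None = None,
    stack: np.ndarray | None = None,
) -> list[EnergyResult]:
    """Strict leave-one-out energies for every protein of a split dataset.

    Implemented by subtracting the target's cached raw counts from the
    pooled subset and total counts and re-running smoothing, thresholding
    and derivation — exactly equivalent to re-deriving from scratch without
    the target.
    """
    config = config or RunConfig()
    scheme = BinningScheme.from_config(config)
    if stack is None:
        stack = stack_counts(dataset.records, scheme)
    results = []
    for p, rec in enumerate(dataset.records):
        w_sol, w_insol, w_tot = loo_tables(dataset, p, config, stack)
        tensor = PairCountTensor(
            counts=stack[p], scheme=scheme, provenance=rec.protein_id
        )
        results.append(
            EnergyResult(
                protein_id=rec.protein_id,
                w_sol=folding_energy(rec, w_sol, tensor),
                w_insol=folding_energy(rec, w_insol, tensor),
                w_tot=folding_energy(rec, w_tot, tensor),
                loo=True,
            )
        )
    return results


def pearson(x, y) -> float:
    """Product-moment correlation with explicit degenerate-input errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson needs two equal-length 1-d arrays, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# sequence features

#: Side-chain and terminal pKa values (EMBOSS convention) for the
#: Henderson-Hasselbalch net-charge model behind the isoelectric point.
PKA_POSITIVE = {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

#: Aliphatic-index side-chain volume weights relative to alanine.
AI_WEIGHT_VAL = 2.9
AI_WEIGHT_ILE_LEU = 3.9


def net_charge(sequence: str, ph: float) -> float:
    counts = {aa: sequence.count(aa) for aa in "KRHDECY"}
    pos = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["nterm"]))
    for aa in "KRH":
        pos += counts[aa] / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
    neg = 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["cterm"] - ph))
    for aa in "DECY":
        neg += counts[aa] / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return pos - neg


def isoelectric_point(sequence: str, tol: float = 1e-6) -> float:
    """pH of zero net charge by bisection (net charge is monotone in pH)."""
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def sequence_features(sequence: str) -> SequenceFeatures:
    """Length, isoelectric point, aliphatic index and Val/Ile/Leu fraction.

    The aliphatic index follows the standard mole-fraction convention
    AI = 100 * (X_Ala + 2.9 * X_Val + 3.9 * (X_Ile + X_Leu)).
    """
    if not sequence:
        raise ValueError("empty sequence")
    validate_sequence(sequence)
    n = len(sequence)
    x = {aa: sequence.count(aa) / n for aa in "AVIL"}
    ai = 100.0 * (x["A"] + AI_WEIGHT_VAL * x["V"] + AI_WEIGHT_ILE_LEU * (x["I"] + x["L"]))
    vil = (sequence.count("V") + sequence.count("I") + sequence.count("L")) / n
    return SequenceFeatures(
        length=n,
        isoelectric_point=isoelectric_point(sequence),
        aliphatic_index=ai,
        vil_fraction=vil,
    )


def compare_compositions(
    sequences_a: list[str],
    sequences_b: list[str],
    residue_group: str = "VIL",
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-protein residue-group fractions and a two-sample KS test.

    Returns (fractions_a, fractions_b, ks_statistic, p_value).
    """
    if not sequences_a or not sequences_b:
        raise ValueError("both sequence sets must be non-empty")
    group = set(residue_group)

    def fracs(seqs):
        return np.array([sum(s.count(aa) for aa in group) / len(s) for s in seqs])

    fa, fb = fracs(sequences_a), fracs(sequences_b)
    if np.array_equal(np.sort(fa), np.sort(fb)):
        return fa, fb, 0.0, 1.0
    res = stats.ks_2samp(fa, fb)
    return fa, fb, float(res.statistic), float(res.pvalue)
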