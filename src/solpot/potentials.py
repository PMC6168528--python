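"""Inverse-Boltzmann distance potentials, plain and solubility-dependent.

The pseudo-energy of observing residue types s, s' at centroid distance d is

    dW(s, s', d) = -kBT * ln[ F(s, s', d | D_joint)
                              / ( F(s, s' | D_comp) * F(d | D_joint) ) ]

with frequencies F estimated from occurrence counts in a structure dataset.
Taking the joint and composition dataset to be the same full set gives the
classical total potential.  The solubility-dependent variants take the
joint frequencies (and the distance marginal) from the soluble or the
insoluble half of the dataset while keeping the pair-composition frequency
from the full set, so that composition differences between the halves do
not masquerade as distance preferences.

Bins whose (smoothed) occurrence count does not exceed the threshold are
masked and carry an energy of exactly zero.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import AA_ORDER, N_PAIRS, PAIR_LIST, pair_index
from .config import RunConfig
from .counting import (
    LONG_RANGE,
    N_SEP,
    SEP_LABELS,
    BinningScheme,
    PairCountTensor,
    SchemeMismatchError,
    bin_index,
    bin_indices,
    prepare_counts,
    separation_class,
    smoothing_kernel,
)
from .structure_io import ProteinRecord, StructureDataset

logger = logging.getLogger(__name__)


@dataclass
class PotentialTable:
    """dW(s, s', sep-class, d-bin) in kcal/mol with a zero-forcing mask."""

    values: np.ndarray
    mask: np.ndarray
    scheme: BinningScheme
    kbt: float = 0.593
    provenance: str = "custom"

    def __post_init__(self) -> None:
        expected = (N_PAIRS, N_SEP, self.scheme.n_bins)
        if self.values.shape != expected or self.mask.shape != expected:
            raise ValueError(f"values/mask must have shape {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("potential values must be finite")
        if np.any(self.values[self.mask] != 0.0):
            raise ValueError("masked bins must hold exactly zero")

    def get(self, aa1: str, aa2: str) -> np.ndarray:
        """(n_sep, n_bins) energies of an unordered pair; order-insensitive."""
        return self.values[pair_index(aa1, aa2)]

    def evaluate(self, aa1: str, aa2: str, separation: int, d: float) -> float:
        """Energy contribution of one residue pair at distance d (Å)."""
        if separation < 2:
            raise ValueError("separation must be >= 2")
        cls = separation_class(separation)
        b = bin_index(d, self.scheme)
        return float(self.values[pair_index(aa1, aa2), cls, b])


def evaluate(table: PotentialTable, aa1: str, aa2: str, separation: int, d: float) -> float:
    return table.evaluate(aa1, aa2, separation, d)


def derive_potential(
    joint_source: PairCountTensor,
    composition_source: PairCountTensor,
    joint_mask: np.ndarray,
    config: RunConfig | None = None,
    provenance: str = "custom",
) -> PotentialTable:
    """Inverse-Boltzmann potential from smoothed joint/composition tensors.

    ``joint_mask`` is the occurrence-threshold mask of the joint tensor;
    masked bins, empty bins, and pairs with zero composition frequency get a
    potential of exactly zero (the latter with a warning).
    """
    config = config or RunConfig()
    if joint_source.scheme != composition_source.scheme:
        raise SchemeMismatchError("joint and composition tensors disagree on binning")
    if joint_source.state != "smoothed" or composition_source.state != "smoothed":
        raise ValueError("derive_potential expects smoothed tensors")

    nj = joint_source.counts                      # (P, S, B)
    n_joint = nj.sum(axis=(0, 2))                 # (S,)  per-class totals
    n_d = nj.sum(axis=0)                          # (S, B)
    n_ss = composition_source.counts.sum(axis=2)  # (P, S)
    n_comp = composition_source.counts.sum(axis=(0, 2))  # (S,)

    zero_comp = (n_ss == 0) & (nj.sum(axis=2) > 0)
    if np.any(zero_comp):
        logger.warning(
            "%d pair/class slots have zero composition frequency; masked",
            int(zero_comp.sum()),
        )

    mask = (
        np.asarray(joint_mask, dtype=bool)
        | (nj <= 0)
        | (n_ss[:, :, None] <= 0)
        | (n_d[None, :, :] <= 0)
    )
    values = np.zeros_like(nj, dtype=float)
    ok = ~mask
    # dW = -kBT ln( n_ss'd * n_comp / (n_ss' * n_d) ), per separation class
    num = nj * n_comp[None, :, None]
    den = n_ss[:, :, None] * n_d[None, :, :]
    values[ok] = -config.kbt * np.log(num[ok] / den[ok])
    return PotentialTable(
        values=values, mask=mask, scheme=joint_source.scheme,
        kbt=config.kbt, provenance=provenance,
    )


def derive_from_counts(
    sol_counts: np.ndarray,
    insol_counts: np.ndarray,
    config: RunConfig,
    scheme: BinningScheme | None = None,
) -> tuple[PotentialTable, PotentialTable, PotentialTable]:
    """(W_sol, W_insol, W_tot) from pooled raw count arrays of the two halves."""
    scheme = scheme or BinningScheme.from_config(config)
    sol_raw = PairCountTensor(counts=sol_counts, scheme=scheme, provenance="sol")
    insol_raw = PairCountTensor(counts=insol_counts, scheme=scheme, provenance="insol")
    tot_raw = PairCountTensor(
        counts=sol_counts + insol_counts, scheme=scheme, provenance="tot"
    )
    sol_s, sol_m = prepare_counts(sol_raw, config)
    insol_s, insol_m = prepare_counts(insol_raw, config)
    tot_s, tot_m = prepare_counts(tot_raw, config)
    w_sol = derive_potential(sol_s, tot_s, sol_m, config, provenance="sol")
    w_insol = derive_potential(insol_s, tot_s, insol_m, config, provenance="insol")
    w_tot = derive_potential(tot_s, tot_s, tot_m, config, provenance="tot")
    return w_sol, w_insol, w_tot


def derive_from_stack(
    stack: np.ndarray,
    sol_indices,
    insol_indices,
    config: RunConfig,
    scheme: BinningScheme | None = None,
) -> tuple[PotentialTable, PotentialTable, PotentialTable]:
    """(W_sol, W_insol, W_tot) from stacked per-protein raw count tensors.

    The stack layout lets the randomization null and the leave-one-out loop
    re-pool subsets cheaply without recounting structures.
    """
    scheme = scheme or BinningScheme.from_config(config)
    if len(sol_indices) == 0 or len(insol_indices) == 0:
        raise ValueError("both subsets must be non-empty")
    sol_counts = stack[list(sol_indices)].sum(axis=0)
    insol_counts = stack[list(insol_indices)].sum(axis=0)
    return derive_from_counts(sol_counts, insol_counts, config, scheme)


def derive_all(
    dataset: StructureDataset,
    config: RunConfig | None = None,
    stack: np.ndarray | None = None,
) -> tuple[PotentialTable, PotentialTable, PotentialTable]:
    """Derive the soluble, insoluble and total potentials of a split dataset."""
    from .counting import stack_counts

    config = config or RunConfig()
    scheme = BinningScheme.from_config(config)
    if stack is None:
        stack = stack_counts(dataset.records, scheme)
    return derive_from_stack(
        stack, dataset.sol_indices, dataset.insol_indices, config, scheme
    )


# ---------------------------------------------------------------------------
# group potentials


@dataclass(frozen=True)
class GroupSpec:
    """A pooled potential over residue pairs sharing one physical mechanism.

    Before pooling, each observed distance is shifted towards smaller values
    by the radius excess of both partners over the group's reference (the
    smallest member residue), aligning the contact minima of differently
    sized side chains.
    """

    name: str
    member_pairs: tuple[tuple[str, str], ...]
    radius_by_aa: dict
    reference_aa: str
    min_occurrences: float = 20.0

    def __post_init__(self) -> None:
        r_ref = self.radius_by_aa.get(self.reference_aa, 0.0)
        for a1, a2 in self.member_pairs:
            for aa in (a1, a2):
                if self.radius_by_aa.get(aa, 0.0) < r_ref - 1e-9:
                    raise ValueError(
                        f"radius of {aa} below reference {self.reference_aa}"
                    )

    def shift(self, aa: str) -> float:
        return self.radius_by_aa.get(aa, 0.0) - self.radius_by_aa.get(
            self.reference_aa, 0.0
        )


@dataclass
class GroupPotential:
    """Single pooled distance profile (long-range class) of a residue group."""

    name: str
    values: np.ndarray        # (n_bins,)
    mask: np.ndarray          # (n_bins,)
    scheme: BinningScheme
    kbt: float
    provenance: str
    pooled_counts: np.ndarray  # smoothed pooled counts per bin


def empirical_radii(records: list[ProteinRecord]) -> dict[str, float]:
    """Per-type mean centroid-to-farthest-side-chain-atom distance (Å)."""
    sums: dict[str, float] = {aa: 0.0 for aa in AA_ORDER}
    ns: dict[str, int] = {aa: 0 for aa in AA_ORDER}
    for rec in records:
        for site in rec.sites:
            sums[site.aa] += site.sidechain_extent
            ns[site.aa] += 1
    return {aa: (sums[aa] / ns[aa] if ns[aa] else 0.0) for aa in AA_ORDER}


def _group_raw_profile(
    records: list[ProteinRecord], spec: GroupSpec, scheme: BinningScheme
) -> np.ndarray:
    """Pooled radius-shifted distance histogram, long-range pairs only."""
    members = {frozenset(p) for p in spec.member_pairs}
    profile = np.zeros(scheme.n_bins)
    for rec in records:
        n = rec.n_residues
        if n < 11:
            continue
        i_idx, j_idx = np.triu_indices(n, k=9)  # |i-j| > 8
        chain = rec.chain_ids()
        keep = chain[i_idx] == chain[j_idx]
        i_idx, j_idx = i_idx[keep], j_idx[keep]
        seq = np.array(list(rec.sequence))
        pair_sets = [frozenset((a, b)) for a, b in zip(seq[i_idx], seq[j_idx])]
        sel = np.array([p in members for p in pair_sets], dtype=bool)
        if not sel.any():
            continue
        i_sel, j_sel = i_idx[sel], j_idx[sel]
        cent = rec.centroids()
        d = np.linalg.norm(cent[j_sel] - cent[i_sel], axis=1)
        shifts = np.array(
            [spec.shift(a) + spec.shift(b) for a, b in zip(seq[i_sel], seq[j_sel])]
        )
        d_shifted = np.maximum(d - shifts, 1e-6)
        bins, _ = bin_indices(d_shifted, scheme)
        np.add.at(profile, bins, 1.0)
    return profile


def derive_group_potential(
    joint_records: list[ProteinRecord],
    joint_tensor_smoothed: PairCountTensor,
    composition_source: PairCountTensor,
    spec: GroupSpec,
    config: RunConfig | None = None,
    provenance: str = "group",
) -> GroupPotential:
    """Pooled radius-shifted group potential for the long-range class.

    The pooled shifted histogram plays the joint frequency; the distance
    marginal comes from the joint subset's ordinary counts and the group
    composition frequency is the sum of the member pairs' composition
    frequencies.  Threshold: smoothed pooled count must exceed
    ``spec.min_occurrences`` (default 20).
    """
    config = config or RunConfig()
    scheme = joint_tensor_smoothed.scheme
    raw = _group_raw_profile(joint_records, spec, scheme)
    pooled = np.convolve(raw, smoothing_kernel(config.alpha), mode="same")

    n_joint = joint_tensor_smoothed.counts[:, LONG_RANGE, :].sum()
    n_d = joint_tensor_smoothed.counts[:, LONG_RANGE, :].sum(axis=0)
    member_idx = [pair_index(a, b) for a, b in spec.member_pairs]
    n_group = composition_source.counts[member_idx, LONG_RANGE, :].sum()
    n_comp = composition_source.counts[:, LONG_RANGE, :].sum()

    mask = (pooled <= spec.min_occurrences) | (n_d <= 0)
    values = np.zeros(scheme.n_bins)
    if n_group <= 0 or raw.sum() == 0:
        logger.warning("group %s: empty pooled counts, all bins masked", spec.name)
        mask[:] = True
    else:
        ok = ~mask
        values[ok] = -config.kbt * np.log(
            pooled[ok] * n_comp / (n_group * n_d[ok])
        )
    return GroupPotential(
        name=spec.name, values=values, mask=mask, scheme=scheme,
        kbt=config.kbt, provenance=provenance, pooled_counts=pooled,
    )


# ---------------------------------------------------------------------------
# serialization

_TSV_HEADER = "aa1\taa2\tsep_class\tbin_lo\tbin_hi\tmasked\tdeltaW_kcal_mol\n"


def dataset_hash(records: list[ProteinRecord]) -> str:
    h = hashlib.sha256()
    for r in records:
        h.update(f"{r.protein_id}:{r.solubility}:{r.n_residues};".encode())
    return h.hexdigest()[:16]


def write_potential(table: PotentialTable, path: str | Path, sidecar: dict | None = None) -> None:
    """Write the TSV table plus a JSON sidecar; reload is bit-exact."""
    path = Path(path)
    edges = table.scheme.bin_edges()
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for p, (a1, a2) in enumerate(PAIR_LIST):
            for s, label in enumerate(SEP_LABELS):
                for b in range(table.scheme.n_bins):
                    fh.write(
                        f"{a1}\t{a2}\t{label}\t{edges[b, 0]:.1f}\t{edges[b, 1]:.1f}\t"
                        f"{int(table.mask[p, s, b])}\t{float(table.values[p, s, b])!r}\n"
                    )
    meta = {
        "kbt": table.kbt,
        "provenance": table.provenance,
        "scheme": {
            "d_min": table.scheme.d_min,
            "d_max": table.scheme.d_max,
            "bin_width": table.scheme.bin_width,
            "separate_overflow": table.scheme.separate_overflow,
        },
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_potential(path: str | Path) -> PotentialTable:
    import pandas as pd

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    scheme = BinningScheme(**meta["scheme"])
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    values = np.zeros((N_PAIRS, N_SEP, scheme.n_bins))
    mask = np.zeros((N_PAIRS, N_SEP, scheme.n_bins), dtype=bool)
    sep_idx = {label: i for i, label in enumerate(SEP_LABELS)}
    lo_to_bin = {round(edge, 6): i for i, edge in enumerate(scheme.bin_edges()[:, 0])}
    p_idx = df.apply(lambda r: pair_index(r["aa1"], r["aa2"]), axis=1).to_numpy()
    s_idx = df["sep_class"].map(sep_idx).to_numpy()
    b_idx = df["bin_lo"].round(6).map(lo_to_bin).to_numpy()
    values[p_idx, s_idx, b_idx] = df["deltaW_kcal_mol"].to_numpy(dtype=float)
    mask[p_idx, s_idx, b_idx] = df["masked"].to_numpy(dtype=bool)
    return PotentialTable(
        values=values, mask=mask, scheme=scheme,
        kbt=float(meta["kbt"]), provenance=meta.get("provenance", "custom"),
    )
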