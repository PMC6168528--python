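"""Structure parsing, annotation tables and labeled dataset assembly.

A protein enters the pipeline as an ordered list of residue sites, one per
retained standard residue, each carrying the residue type and the geometric
center (centroid) of its side-chain heavy atoms.  Glycine, whose side chain
is a lone hydrogen, and any residue with no resolved side-chain heavy atoms
fall back to the C-alpha position.  Datasets are split into a soluble and a
weakly soluble ("insoluble") half at a solubility threshold (default 64 %,
with the threshold value itself going to the soluble side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .alphabet import AA_ORDER, RESIDUE_ALIASES, THREE_TO_ONE

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class StructureParseError(RuntimeError):
    """The structure file could not be read or contains no usable residues."""


class MissingChainError(StructureParseError):
    """A chain requested in the annotation row is absent from the file."""


class AnnotationSchemaError(ValueError):
    """The annotation table violates its schema."""


class LabelingError(ValueError):
    """An operation requiring solubility labels met an unlabeled record."""


@dataclass(frozen=True)
class ResidueSite:
    """One residue: type, chain, filtered sequence position and centroid.

    ``sidechain_extent`` is the distance (Å) from the centroid to the
    farthest side-chain heavy atom; it is 0 for glycine/C-alpha fallbacks and
    feeds the empirical residue-radius table used by group potentials.
    """

    aa: str
    chain_id: str
    seq_index: int
    centroid: np.ndarray
    sidechain_extent: float = 0.0

    def __post_init__(self) -> None:
        if self.aa not in AA_ORDER:
            raise ValueError(f"non-canonical residue type {self.aa!r}")
        c = np.asarray(self.centroid, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("centroid must be a finite 3-vector")
        object.__setattr__(self, "centroid", c)


@dataclass
class ProteinRecord:
    """A protein with optional solubility label and (once parsed) its sites."""

    protein_id: str
    structure_source: str
    chain_selection: tuple[str, ...]
    solubility: float | None = None
    sequence: str = ""
    sites: list[ResidueSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.solubility is not None and not (0.0 <= self.solubility <= 100.0):
            raise ValueError(
                f"{self.protein_id}: solubility {self.solubility} outside [0, 100]"
            )
        self._check_sites()

    def _check_sites(self) -> None:
        if len(self.sequence) != len(self.sites):
            raise ValueError(f"{self.protein_id}: sequence/sites length mismatch")
        for i, (letter, site) in enumerate(zip(self.sequence, self.sites)):
            if letter != site.aa:
                raise ValueError(
                    f"{self.protein_id}: sequence[{i}]={letter} != site {site.aa}"
                )
            if site.seq_index != i:
                raise ValueError(f"{self.protein_id}: non-contiguous seq_index at {i}")

    @property
    def n_residues(self) -> int:
        return len(self.sites)

    def centroids(self) -> np.ndarray:
        """(N, 3) array of side-chain centroids in site order."""
        if not self.sites:
            return np.zeros((0, 3))
        return np.stack([s.centroid for s in self.sites])

    def chain_ids(self) -> np.ndarray:
        return np.array([s.chain_id for s in self.sites])

    def with_sites(self, sequence: str, sites: list[ResidueSite]) -> "ProteinRecord":
        rec = ProteinRecord(
            protein_id=self.protein_id,
            structure_source=self.structure_source,
            chain_selection=self.chain_selection,
            solubility=self.solubility,
            sequence=sequence,
            sites=sites,
        )
        return rec


@dataclass
class StructureDataset:
    """Labeled protein collection with a solubility split.

    ``sol_indices`` / ``insol_indices`` index into ``records``: the soluble
    subset holds every protein with solubility >= ``split_threshold``, the
    insoluble subset the strict complement.
    """

    records: list[ProteinRecord]
    split_threshold: float
    sol_indices: tuple[int, ...]
    insol_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        all_idx = sorted(self.sol_indices) + sorted(self.insol_indices)
        if sorted(all_idx) != list(range(len(self.records))):
            raise ValueError("split subsets must partition the record list")
        for i in self.sol_indices:
            if self.records[i].solubility < self.split_threshold:
                raise ValueError("soluble subset holds an under-threshold record")
        for i in self.insol_indices:
            if self.records[i].solubility >= self.split_threshold:
                raise ValueError("insoluble subset holds an over-threshold record")

    @property
    def n_sol(self) -> int:
        return len(self.sol_indices)

    @property
    def n_insol(self) -> int:
        return len(self.insol_indices)

    def subset(self, which: str) -> list[ProteinRecord]:
        if which == "sol":
            return [self.records[i] for i in self.sol_indices]
        if which == "insol":
            return [self.records[i] for i in self.insol_indices]
        if which == "tot":
            return list(self.records)
        raise ValueError(f"unknown subset {which!r}")


# ---------------------------------------------------------------------------
# structure parsing


def _select_altloc_atoms(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve altlocs: per atom name keep the highest-occupancy conformer,
    ties broken by altloc identifier order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        cur = best.get(atom.name)
        if cur is None:
            best[atom.name] = atom
            continue
        if atom.occ > cur.occ or (atom.occ == cur.occ and atom.altloc < cur.altloc):
            best[atom.name] = atom
    return list(best.values())


def parse_structure(
    path: str | Path,
    chain_selection: set[str] | tuple[str, ...] | list[str],
) -> tuple[str, list[ResidueSite]]:
    """Parse a PDB/mmCIF file into ordered residue sites.

    Returns ``(sequence, sites)`` for the selected chains (file order),
    keeping the 20 standard residue types (MSE mapped to MET), using model 1
    of multi-model entries, and computing each centroid as the unweighted
    mean of the side-chain heavy atoms (C-alpha fallback for glycine or when
    all side-chain heavy atoms are missing).
    """
    chains = list(chain_selection)
    if not chains:
        raise ValueError("chain_selection must not be empty")
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"cannot read structure {path}: {exc}") from exc
    if len(structure) == 0:
        raise StructureParseError(f"{path}: no models")
    model = structure[0]
    if len(structure) > 1:
        logger.info("%s: %d models present, using model 1", path, len(structure))

    present = {ch.name for ch in model}
    missing = [c for c in chains if c not in present]
    if missing:
        raise MissingChainError(
            f"{path}: chain(s) {missing} absent (available: {sorted(present)})"
        )

    sequence: list[str] = []
    sites: list[ResidueSite] = []
    dropped_nonstandard = 0
    for chain in model:
        if chain.name not in chains:
            continue
        prev_seqid: int | None = None
        gap_logged = False
        for residue in chain:
            name = RESIDUE_ALIASES.get(residue.name, residue.name)
            one = THREE_TO_ONE.get(name)
            if one is None:
                info = gemmi.find_tabulated_residue(residue.name)
                if info is not None and info.is_amino_acid():
                    dropped_nonstandard += 1
                    logger.warning(
                        "%s: dropping non-standard residue %s %s/%s",
                        path, residue.name, chain.name, residue.seqid.num,
                    )
                continue  # waters, ligands, nucleic acids: silently excluded
            if prev_seqid is not None and residue.seqid.num != prev_seqid + 1:
                if not gap_logged:
                    logger.info(
                        "%s: author numbering gap in chain %s near %d; sequence "
                        "separation uses filtered order, not author numbers",
                        path, chain.name, residue.seqid.num,
                    )
                    gap_logged = True
            prev_seqid = residue.seqid.num

            atoms = _select_altloc_atoms(residue)
            heavy = [a for a in atoms if a.element.name not in ("H", "D")]
            if not heavy:
                logger.warning(
                    "%s: residue %s %s/%s has no heavy atoms, skipped",
                    path, residue.name, chain.name, residue.seqid.num,
                )
                continue
            side = [a for a in heavy if a.name not in BACKBONE_ATOMS]
            ca = next((a for a in heavy if a.name == "CA"), None)
            if side:
                coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in side])
                centroid = coords.mean(axis=0)
                extent = float(np.max(np.linalg.norm(coords - centroid, axis=1)))
            elif ca is not None:
                centroid = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
                extent = 0.0
            else:
                logger.warning(
                    "%s: residue %s %s/%s lacks side chain and CA, skipped",
                    path, residue.name, chain.name, residue.seqid.num,
                )
                continue
            sites.append(
                ResidueSite(
                    aa=one,
                    chain_id=chain.name,
                    seq_index=len(sites),
                    centroid=centroid,
                    sidechain_extent=extent,
                )
            )
            sequence.append(one)

    if not sites:
        raise StructureParseError(f"{path}: no standard residues in selected chains")
    if dropped_nonstandard:
        logger.info("%s: dropped %d non-standard residues", path, dropped_nonstandard)
    return "".join(sequence), sites


def parse_record(record: ProteinRecord, structure_dir: str | Path | None = None) -> ProteinRecord:
    """Parse the structure referenced by an annotation record."""
    src = Path(record.structure_source)
    if structure_dir is not None and not src.is_absolute():
        src = Path(structure_dir) / src
    sequence, sites = parse_structure(src, record.chain_selection)
    return record.with_sites(sequence, sites)


# ---------------------------------------------------------------------------
# annotation tables and splitting

REQUIRED_COLUMNS = ("protein_id", "structure_source", "chain", "solubility")


def load_annotation_table(path: str | Path) -> list[ProteinRecord]:
    """Read a TSV/CSV annotation table into unparsed protein records.

    Columns: protein_id, structure_source, chain (comma-joined chain ids),
    solubility in percent (may be empty for scoring-only entries).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype={"protein_id": str, "chain": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationSchemaError(f"{path}: missing column(s) {missing}")
    dup = df["protein_id"][df["protein_id"].duplicated()]
    if not dup.empty:
        raise AnnotationSchemaError(f"{path}: duplicated protein_id {sorted(set(dup))}")
    records = []
    for row in df.itertuples(index=False):
        sol = getattr(row, "solubility")
        sol = None if pd.isna(sol) else float(sol)
        chains = tuple(c.strip() for c in str(row.chain).split(",") if c.strip())
        if not chains:
            raise AnnotationSchemaError(f"{path}: empty chain for {row.protein_id}")
        records.append(
            ProteinRecord(
                protein_id=str(row.protein_id),
                structure_source=str(row.structure_source),
                chain_selection=chains,
                solubility=sol,
            )
        )
    return records


def split_dataset(records: list[ProteinRecord], threshold: float = 64.0) -> StructureDataset:
    """Split labeled records at a solubility threshold (>= goes soluble)."""
    unlabeled = [r.protein_id for r in records if r.solubility is None]
    if unlabeled:
        raise LabelingError(f"unlabeled record(s): {unlabeled}")
    sol = tuple(i for i, r in enumerate(records) if r.solubility >= threshold)
    insol = tuple(i for i, r in enumerate(records) if r.solubility < threshold)
    ds = StructureDataset(
        records=list(records),
        split_threshold=threshold,
        sol_indices=sol,
        insol_indices=insol,
    )
    logger.info(
        "split at %.1f%%: %d soluble / %d insoluble of %d",
        threshold, ds.n_sol, ds.n_insol, len(records),
    )
    return ds


# ---------------------------------------------------------------------------
# manifest round-trip


def write_manifest(dataset: StructureDataset, path: str | Path) -> None:
    """Write the dataset manifest TSV (id, size, label, subset)."""
    subset = {}
    for i in dataset.sol_indices:
        subset[i] = "sol"
    for i in dataset.insol_indices:
        subset[i] = "insol"
    rows = [
        {
            "protein_id": r.protein_id,
            "n_residues": r.n_residues,
            "solubility": r.solubility,
            "subset": subset[i],
        }
        for i, r in enumerate(dataset.records)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein_id": str})
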