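"""Seed-deterministic synthetic structure datasets with plantable contacts.

The generator produces geometric surrogate proteins: a self-avoiding random
walk of C-alpha positions with a fixed 3.8 Å virtual-bond step, a side-chain
centroid displaced from each C-alpha by a random offset (zero for glycine),
and residue types drawn from an average globular-protein composition.  The
derivation pipeline consumes nothing but residue types, sequence separations
and centroid distances, so this level of realism exercises every stage.

Class-conditional signal is planted directly as residue-pair contacts: a
chosen number of long-range (|i-j| > 8) residue pairs per protein are
mutated to the target types and their centroids moved to a chosen contact
distance, in the soluble or the insoluble class only.  A ground-truth
manifest records every planted contact for recovery scoring.  With no
planted contacts the two classes are exchangeable by construction, which is
the null configuration used for calibration of the significance test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import AA_ORDER, ONE_TO_THREE
from .counting import BinningScheme
from .structure_io import ProteinRecord, ResidueSite, StructureDataset, split_dataset

#: Average amino-acid frequencies of globular proteins (UniProt-style
#: background), in the canonical alphabet order A R N D C Q E G H I L K M F P S T W Y V.
DEFAULT_COMPOSITION = np.array(
    [8.25, 5.53, 4.06, 5.45, 1.38, 3.93, 6.75, 7.07, 2.27, 5.96,
     9.66, 5.84, 2.42, 3.86, 4.70, 6.56, 5.34, 1.08, 2.92, 6.87]
)
DEFAULT_COMPOSITION = DEFAULT_COMPOSITION / DEFAULT_COMPOSITION.sum()

CA_STEP = 3.8           # Å, virtual C-alpha bond length
SELF_AVOID_RADIUS = 2.0  # Å, soft steric exclusion between C-alphas
MAX_STEP_RETRIES = 100
CENTROID_OFFSET_MEAN = 2.4   # Å, typical C-alpha-to-centroid displacement
CENTROID_OFFSET_SD = 0.6
CENTROID_OFFSET_MIN = 0.5


class PlantingError(RuntimeError):
    """No eligible residue pair was available for contact planting."""


@dataclass(frozen=True)
class PlantedBias:
    """One class-conditional contact enrichment.

    ``enrichment`` is the expected number of planted contacts per protein of
    the enriched class (fractional parts realized as a Bernoulli draw).
    """

    pair: tuple[str, str]
    distance: float
    enrichment: float
    enrich_class: str  # "sol" | "insol"

    def __post_init__(self) -> None:
        if self.enrichment < 0:
            raise ValueError("enrichment must be non-negative")
        if not (3.0 <= self.distance < 10.0):
            raise ValueError("target distance must lie within [3, 10) Å")
        if self.enrich_class not in ("sol", "insol"):
            raise ValueError("enrich_class must be 'sol' or 'insol'")


#: Study conditions for planted-signal recovery: strong Lys-Glu salt-bridge
#: enrichment at 4 Å in the soluble class and Trp-Trp aromatic stacking at
#: 6.3 Å in the insoluble class, eight contacts per protein.
RECOVERY_BIASES = (
    PlantedBias(pair=("K", "E"), distance=4.0, enrichment=8.0, enrich_class="sol"),
    PlantedBias(pair=("W", "W"), distance=6.3, enrichment=8.0, enrich_class="insol"),
)


@dataclass(frozen=True)
class GeneratorParams:
    """Complete description of one synthetic dataset (seed included)."""

    n_per_class: tuple[int, int] = (30, 30)  # (soluble, insoluble)
    length_range: tuple[int, int] = (80, 120)
    seed: int = 0
    planted_biases: tuple[PlantedBias, ...] = ()
    sol_range: tuple[float, float] = (64.0, 100.0)
    insol_range: tuple[float, float] = (0.0, 64.0)
    composition: tuple[float, ...] = tuple(DEFAULT_COMPOSITION)


@dataclass
class SyntheticProtein:
    """A generated protein plus the C-alpha trace it was built on."""

    record: ProteinRecord
    ca: np.ndarray  # (N, 3)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-9:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def generate_chain(
    length: int,
    seed: int | np.random.Generator,
    protein_id: str = "synthetic",
    composition: np.ndarray | None = None,
) -> SyntheticProtein:
    """Self-avoiding random-walk chain with side-chain centroids.

    Deterministic given (length, seed).  Consecutive C-alphas are exactly
    3.8 Å apart; steps that would come within 2 Å of any earlier C-alpha
    are resampled (up to 100 times, then accepted as-is).
    """
    if length < 2:
        raise ValueError("chain length must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp = DEFAULT_COMPOSITION if composition is None else np.asarray(composition)
    comp = comp / comp.sum()

    ca = np.zeros((length, 3))
    for i in range(1, length):
        for _ in range(MAX_STEP_RETRIES):
            step = _random_unit(rng) * CA_STEP
            candidate = ca[i - 1] + step
            if i < 2:
                break
            dmin = np.min(np.linalg.norm(ca[: i - 1] - candidate, axis=1))
            if dmin >= SELF_AVOID_RADIUS:
                break
        ca[i] = candidate

    aa_codes = rng.choice(len(AA_ORDER), size=length, p=comp)
    sequence = "".join(AA_ORDER[k] for k in aa_codes)
    sites = []
    for i, aa in enumerate(sequence):
        if aa == "G":
            centroid = ca[i].copy()
        else:
            offset = max(
                CENTROID_OFFSET_MIN,
                rng.normal(CENTROID_OFFSET_MEAN, CENTROID_OFFSET_SD),
            )
            centroid = ca[i] + _random_unit(rng) * offset
        sites.append(ResidueSite(aa=aa, chain_id="A", seq_index=i, centroid=centroid))
    record = ProteinRecord(
        protein_id=protein_id,
        structure_source="",
        chain_selection=("A",),
        sequence=sequence,
        sites=sites,
    )
    return SyntheticProtein(record=record, ca=ca)


def plant_contacts(
    protein: SyntheticProtein,
    pair: tuple[str, str],
    target_distance: float,
    k: int,
    seed: int | np.random.Generator,
    scheme: BinningScheme | None = None,
) -> tuple[SyntheticProtein, list[dict]]:
    """Plant k long-range contacts of the given pair type at a distance.

    Residue pairs with |i-j| > 8 are drawn at random (disjoint residues),
    mutated to the target types, and the second centroid is translated so
    the pair distance equals the center of the bin containing
    ``target_distance`` — the planted contact therefore falls into
    ``bin_index(target_distance)`` exactly.

    Returns the modified protein and the list of planted contacts.
    """
    if k == 0:
        return protein, []
    scheme = scheme or BinningScheme()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = protein.record.n_residues
    if n < 11:
        raise PlantingError("chain too short for long-range planting")
    from .counting import bin_index

    target_bin = bin_index(target_distance, scheme)
    d_planted = float(scheme.bin_centers()[target_bin])

    seq = list(protein.record.sequence)
    centroids = [s.centroid.copy() for s in protein.record.sites]
    used: set[int] = set()
    planted: list[dict] = []
    attempts = 0
    while len(planted) < k and attempts < 2000:
        attempts += 1
        i = int(rng.integers(0, n - 9))
        j = int(rng.integers(i + 9, n))
        if i in used or j in used:
            continue
        a1, a2 = pair
        seq[i], seq[j] = a1, a2
        delta = centroids[j] - centroids[i]
        norm = np.linalg.norm(delta)
        u = delta / norm if norm > 1e-9 else _random_unit(rng)
        centroids[j] = centroids[i] + u * d_planted
        used.update((i, j))
        planted.append({"i": i, "j": j, "distance": d_planted, "pair": f"{a1}{a2}"})
    if len(planted) < k:
        raise PlantingError(
            f"only {len(planted)} of {k} contacts could be planted"
        )
    sites = [
        ResidueSite(
            aa=seq[i],
            chain_id=s.chain_id,
            seq_index=i,
            centroid=centroids[i],
            sidechain_extent=s.sidechain_extent,
        )
        for i, s in enumerate(protein.record.sites)
    ]
    record = protein.record.with_sites("".join(seq), sites)
    return SyntheticProtein(record=record, ca=protein.ca), planted


def generate_dataset(
    params: GeneratorParams | None = None,
) -> tuple[StructureDataset, list[SyntheticProtein], dict]:
    """Two labeled protein classes with class-conditional planted contacts.

    Returns the split dataset, the synthetic proteins (with C-alpha traces,
    for structure-file export) and a ground-truth manifest listing every
    planted contact.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed)
    comp = np.asarray(params.composition)
    proteins: list[SyntheticProtein] = []
    manifest: dict = {"seed": params.seed, "planted": []}
    lo, hi = params.length_range
    for cls, n_cls, (s_lo, s_hi) in (
        ("sol", params.n_per_class[0], params.sol_range),
        ("insol", params.n_per_class[1], params.insol_range),
    ):
        for k in range(n_cls):
            length = int(rng.integers(lo, hi + 1))
            sp = generate_chain(length, rng, protein_id=f"{cls}_{k:03d}",
                                composition=comp)
            for bias in params.planted_biases:
                if bias.enrich_class != cls:
                    continue
                n_plant = int(np.floor(bias.enrichment))
                frac = bias.enrichment - n_plant
                if frac > 0 and rng.random() < frac:
                    n_plant += 1
                if n_plant == 0:
                    continue
                sp, planted = plant_contacts(
                    sp, bias.pair, bias.distance, n_plant, rng
                )
                for entry in planted:
                    manifest["planted"].append(
                        {"protein_id": sp.record.protein_id, **entry}
                    )
            solubility = float(rng.uniform(s_lo, s_hi))
            # keep strictly inside the class range so the 64 % split is exact
            if cls == "insol":
                solubility = min(solubility, np.nextafter(s_hi, 0.0))
            sp.record.solubility = solubility
            proteins.append(sp)
    dataset = split_dataset([sp.record for sp in proteins], threshold=64.0)
    return dataset, proteins, manifest


# ---------------------------------------------------------------------------
# structure-file export

def format_atom_line(
    serial: int,
    name: str,
    res3: str,
    chain: str,
    resseq: int,
    xyz,
    occ: float = 1.0,
    b: float = 0.0,
    element: str = "C",
    altloc: str = " ",
) -> str:
    """One strict-column PDB ATOM record (atom names of up to 3 characters)."""
    name_field = f" {name:<3s}" if len(name) < 4 else name
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name_field:4s}{altloc:1s}{res3:>3s} {chain:1s}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}\n"
    )


def write_pdb(protein: SyntheticProtein, path: str | Path) -> None:
    """Write a minimal PDB: C-alpha trace plus one centroid pseudo-atom (CB).

    The parser recomputes each centroid as the mean of the side-chain heavy
    atoms, i.e. the CB pseudo-atom itself, so export/import round-trips the
    geometry to coordinate precision (glycine falls back to C-alpha).
    """
    rec = protein.record
    with open(path, "w") as fh:
        serial = 1
        for i, site in enumerate(rec.sites):
            res3 = ONE_TO_THREE[site.aa]
            ca_xyz = site.centroid if site.aa == "G" else protein.ca[i]
            fh.write(format_atom_line(serial, "CA", res3, "A", i + 1, ca_xyz))
            serial += 1
            if site.aa != "G":
                fh.write(format_atom_line(serial, "CB", res3, "A", i + 1,
                                          site.centroid))
                serial += 1
        fh.write("END\n")


def write_dataset(
    dataset: StructureDataset,
    proteins: list[SyntheticProtein],
    manifest: dict,
    out_dir: str | Path,
) -> Path:
    """Export structures, the annotation table and the truth manifest."""
    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    lines = ["protein_id\tstructure_source\tchain\tsolubility"]
    for sp in proteins:
        rel = f"structures/{sp.record.protein_id}.pdb"
        write_pdb(sp, out / rel)
        sp.record.structure_source = rel
        lines.append(
            f"{sp.record.protein_id}\t{rel}\tA\t{sp.record.solubility!r}"
        )
    (out / "annotation.tsv").write_text("\n".join(lines) + "\n")
    (out / "truth.json").write_text(json.dumps(manifest, indent=1))
    return out / "annotation.tsv"
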