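"""Protein-protein complex representation, PDB ingestion and dataset curation.

A curated entry is a dimer: two disjoint chain groups (receptor and ligand),
each backed by coordinates from a single PDB model, joined to one unambiguous
experimental affinity (pKd = -log10 Kd).  Curation applies the filters used
when building refined structure-affinity training sets: ambiguous or
conflicting affinities, multiple ligands, multimeric assemblies, missing
coordinates and inter-chain steric clashes are excluded, and every exclusion
is logged with a reason so that |retained| + |excluded| = |input|.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "ComplexEntry",
    "AffinityRecord",
    "ExclusionReason",
    "ExclusionLog",
    "CurationConfig",
    "StructureMethod",
    "AssayMethod",
    "EmptyStructureError",
    "PDBFormatError",
    "parse_complex",
    "write_complex",
    "pkd_from_kd",
    "kd_from_pkd",
    "detect_steric_clash",
    "curate_dataset",
    "aggregate_conditions",
    "chain_sequences",
    "read_metadata",
]


class EmptyStructureError(ValueError):
    """Raised when a PDB text contains no ATOM records."""


class PDBFormatError(ValueError):
    """Raised when a PDB record cannot be parsed."""


class StructureMethod(str, enum.Enum):
    XRAY = "XRAY"
    NMR = "NMR"
    OTHER = "OTHER"


class AssayMethod(str, enum.Enum):
    ITC = "ITC"
    SPR = "SPR"
    INHIBITION = "INHIBITION"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


class ExclusionReason(str, enum.Enum):
    AMBIGUOUS_AFFINITY = "AMBIGUOUS_AFFINITY"
    MULTIPLE_LIGANDS = "MULTIPLE_LIGANDS"
    MULTIMER = "MULTIMER"
    MISSING_COORDINATES = "MISSING_COORDINATES"
    STERIC_CLASH = "STERIC_CLASH"
    MISSING_METADATA = "MISSING_METADATA"


@dataclass(frozen=True)
class AtomRecord:
    """One heavy (or hydrogen) atom from a PDB ATOM/HETATM record."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y) and math.isfinite(self.z)):
            raise ValueError(f"non-finite coordinates for atom serial {self.serial}")
        if not self.element:
            raise ValueError(f"empty element for atom serial {self.serial}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0,1] for atom {self.serial}")

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class ComplexEntry:
    """A protein-protein dimer: atoms plus receptor/ligand chain assignment."""

    complex_id: str
    receptor_chains: frozenset[str]
    ligand_chains: frozenset[str]
    atoms: list[AtomRecord]
    method: StructureMethod = StructureMethod.OTHER
    resolution: float | None = None
    cryst_temperature: float | None = None
    cryst_ph: float | None = None

    def __post_init__(self) -> None:
        self.receptor_chains = frozenset(self.receptor_chains)
        self.ligand_chains = frozenset(self.ligand_chains)
        if self.receptor_chains & self.ligand_chains:
            raise ValueError("receptor and ligand chain sets overlap")
        if not self.receptor_chains or not self.ligand_chains:
            raise ValueError("both chain groups must be non-empty")
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")

    def group_of(self, chain_id: str) -> str | None:
        """'receptor', 'ligand', or None for an unassigned chain."""
        if chain_id in self.receptor_chains:
            return "receptor"
        if chain_id in self.ligand_chains:
            return "ligand"
        return None

    def group_atoms(self, group: str) -> list[AtomRecord]:
        chains = self.receptor_chains if group == "receptor" else self.ligand_chains
        return [a for a in self.atoms if a.chain_id in chains]

    def unassigned_chains(self, include_hetero: bool = False) -> set[str]:
        return {
            a.chain_id
            for a in self.atoms
            if self.group_of(a.chain_id) is None and (include_hetero or not a.is_hetero)
        }

    def coordinates(self, group: str | None = None) -> np.ndarray:
        atoms = self.atoms if group is None else self.group_atoms(group)
        if not atoms:
            return np.empty((0, 3))
        return np.array([[a.x, a.y, a.z] for a in atoms])


@dataclass(frozen=True)
class AffinityRecord:
    """Experimental affinity (pKd) with the conditions of the binding assay.

    ``qualifier`` distinguishes exact measurements ("=") from inequality
    bounds (">" / "<", e.g. Kd > x), which count as ambiguous in curation.
    """

    complex_id: str
    pkd: float
    assay_method: AssayMethod = AssayMethod.UNKNOWN
    assay_temperature: float | None = None
    assay_ph: float | None = None
    source: str = ""
    qualifier: str = "="

    def __post_init__(self) -> None:
        if not math.isfinite(self.pkd):
            raise ValueError("pKd must be finite")
        if self.qualifier not in {"=", ">", "<"}:
            raise ValueError(f"unknown affinity qualifier {self.qualifier!r}")

    @property
    def kd(self) -> float:
        """Dissociation constant in molar, 10^(-pKd)."""
        return 10.0 ** (-self.pkd)


@dataclass
class ExclusionLog:
    """Per-complex exclusion reasons accumulated during curation."""

    entries: list[tuple[str, ExclusionReason, str]] = field(default_factory=list)

    def add(self, complex_id: str, reason: ExclusionReason, detail: str = "") -> None:
        self.entries.append((complex_id, reason, detail))

    def reasons(self) -> dict[str, ExclusionReason]:
        return {cid: reason for cid, reason, _ in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["complex_id", "reason", "detail"])

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class CurationConfig:
    """Tunable curation rules.

    ambiguity_window
        Two affinity records for the same complex that disagree by more than
        this many pKd units make the affinity ambiguous (default 0.5).
    clash_cutoff
        Inter-chain-group heavy-atom distance (Angstrom) below which the
        complex is flagged as sterically clashed (default 2.0, well inside
        any physical non-bonded contact).
    allow_multichain_groups
        When False (default) each binding side must be a single polypeptide
        chain; a group with several chains is logged as MULTIMER.
    """

    ambiguity_window: float = 0.5
    clash_cutoff: float = 2.0
    allow_multichain_groups: bool = False


def pkd_from_kd(kd: float) -> float:
    """pKd = -log10(Kd), Kd in molar.

    >>> pkd_from_kd(1e-9)
    9.0
    """
    if kd <= 0 or not math.isfinite(kd):
        raise ValueError(f"Kd must be positive and finite, got {kd}")
    return -math.log10(kd)


def kd_from_pkd(pkd: float) -> float:
    """Inverse of :func:`pkd_from_kd`."""
    return 10.0 ** (-pkd)


def parse_complex(
    pdb_text: str,
    receptor_chains: set[str],
    ligand_chains: set[str],
    complex_id: str = "",
    method: StructureMethod = StructureMethod.OTHER,
    resolution: float | None = None,
    cryst_temperature: float | None = None,
    cryst_ph: float | None = None,
) -> ComplexEntry:
    """Parse PDB text into a :class:`ComplexEntry`.

    Only the first MODEL of a multi-model (NMR-style) file is used.
    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by first occurrence).  HETATM records are retained but
    flagged ``is_hetero``.
    """
    if set(receptor_chains) & set(ligand_chains):
        raise ValueError("receptor and ligand chain sets overlap")
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError on bad records
        raise PDBFormatError(str(exc)) from exc
    if len(structure) == 0:
        raise EmptyStructureError("no ATOM records found")
    model = structure[0]

    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            # resolve altlocs: keep, per atom name, the highest-occupancy copy
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in residue:
                name = atom.name
                if name not in best:
                    best[name] = atom
                    order.append(name)
                elif atom.occ > best[name].occ:
                    best[name] = atom
            for name in order:
                atom = best[name]
                element = atom.element.name.strip() or name[:1]
                try:
                    rec = AtomRecord(
                        serial=atom.serial,
                        atom_name=name,
                        element=element.upper(),
                        residue_name=residue.name,
                        residue_seq=residue.seqid.num,
                        chain_id=chain.name,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        is_hetero=residue.het_flag == "H",
                    )
                except ValueError as exc:
                    raise PDBFormatError(
                        f"bad atom record (serial {atom.serial}, {chain.name}/{residue.name}): {exc}"
                    ) from exc
                atoms.append(rec)
    if not atoms:
        raise EmptyStructureError("no ATOM records found")
    return ComplexEntry(
        complex_id=complex_id,
        receptor_chains=frozenset(receptor_chains),
        ligand_chains=frozenset(ligand_chains),
        atoms=atoms,
        method=method,
        resolution=resolution,
        cryst_temperature=cryst_temperature,
        cryst_ph=cryst_ph,
    )


def write_complex(entry: ComplexEntry) -> str:
    """Serialise an entry back to minimal PDB text (ATOM/HETATM + TER + END)."""
    lines = []
    prev_chain: str | None = None
    for atom in entry.atoms:
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = atom.chain_id
        record = "HETATM" if atom.is_hetero else "ATOM  "
        name = atom.atom_name
        # standard PDB alignment: 1-3 char names start in column 14
        padded = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"{record}{atom.serial:5d} {padded:<4s} {atom.residue_name:>3s} "
            f"{atom.chain_id:1s}{atom.residue_seq:4d}    "
            f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def detect_steric_clash(
    entry: ComplexEntry, clash_cutoff: float = 2.0
) -> tuple[bool, list[tuple[AtomRecord, AtomRecord, float]]]:
    """Find inter-chain-group heavy-atom pairs closer than ``clash_cutoff`` A.

    Returns ``(clash, pairs)`` where pairs lists every offending
    (receptor atom, ligand atom, distance) triple.  Hydrogens are ignored.
    Uses a KD-tree; equivalent to the all-pairs scan.
    """
    rec = [a for a in entry.group_atoms("receptor") if a.element != "H"]
    lig = [a for a in entry.group_atoms("ligand") if a.element != "H"]
    if not rec or not lig:
        raise ValueError("both chain groups need at least one heavy atom")
    rec_xyz = np.array([[a.x, a.y, a.z] for a in rec])
    lig_xyz = np.array([[a.x, a.y, a.z] for a in lig])
    tree = cKDTree(lig_xyz)
    pairs: list[tuple[AtomRecord, AtomRecord, float]] = []
    for i, neighbours in enumerate(tree.query_ball_point(rec_xyz, clash_cutoff)):
        for j in neighbours:
            d = float(np.linalg.norm(rec_xyz[i] - lig_xyz[j]))
            if d < clash_cutoff:
                pairs.append((rec[i], lig[j], d))
    return bool(pairs), pairs


def aggregate_conditions(values: list[float] | None) -> float | None:
    """Collapse several reported condition values (e.g. temperatures) to one.

    Arithmetic mean; an empty or missing list yields None (absent).
    """
    if not values:
        return None
    return float(np.mean(values))


def curate_dataset(
    entries: list[ComplexEntry],
    affinities: list[AffinityRecord],
    rules: CurationConfig | None = None,
) -> tuple[list[tuple[ComplexEntry, AffinityRecord]], ExclusionLog]:
    """Apply the dimer-dataset filters and return (retained, exclusion log).

    Retention requires: exactly one binding entity per side, at least one
    unambiguous affinity record, heavy atoms on both sides, and no
    inter-group steric clash.  Every input complex either appears in the
    retained list or exactly once in the log.
    """
    rules = rules or CurationConfig()
    by_id: dict[str, list[AffinityRecord]] = {}
    for rec in affinities:
        by_id.setdefault(rec.complex_id, []).append(rec)

    retained: list[tuple[ComplexEntry, AffinityRecord]] = []
    log = ExclusionLog()
    for entry in entries:
        records = by_id.get(entry.complex_id, [])
        if not records:
            log.add(entry.complex_id, ExclusionReason.MISSING_METADATA, "no affinity record")
            continue
        if any(r.qualifier != "=" for r in records):
            log.add(entry.complex_id, ExclusionReason.AMBIGUOUS_AFFINITY, "inequality affinity")
            continue
        pkds = [r.pkd for r in records]
        if max(pkds) - min(pkds) > rules.ambiguity_window:
            log.add(
                entry.complex_id,
                ExclusionReason.AMBIGUOUS_AFFINITY,
                f"records disagree by {max(pkds) - min(pkds):.2f} pKd",
            )
            continue
        if entry.unassigned_chains():
            log.add(
                entry.complex_id,
                ExclusionReason.MULTIPLE_LIGANDS,
                f"unassigned chains {sorted(entry.unassigned_chains())}",
            )
            continue
        if not rules.allow_multichain_groups and (
            len(entry.receptor_chains) > 1 or len(entry.ligand_chains) > 1
        ):
            log.add(entry.complex_id, ExclusionReason.MULTIMER, "multi-chain binding side")
            continue
        rec_heavy = [a for a in entry.group_atoms("receptor") if a.element != "H"]
        lig_heavy = [a for a in entry.group_atoms("ligand") if a.element != "H"]
        if not rec_heavy or not lig_heavy:
            log.add(entry.complex_id, ExclusionReason.MISSING_COORDINATES, "empty chain group")
            continue
        clash, pairs = detect_steric_clash(entry, rules.clash_cutoff)
        if clash:
            log.add(entry.complex_id, ExclusionReason.STERIC_CLASH, f"{len(pairs)} pairs")
            continue
        retained.append((entry, records[0]))
    assert len(retained) + len(log) == len(entries)
    return retained, log


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def chain_sequences(entry: ComplexEntry) -> dict[str, str]:
    """One-letter amino-acid sequence per chain, in residue order.

    Non-standard residues are mapped to 'X'; hetero records are skipped.
    """
    seqs: dict[str, list[str]] = {}
    seen: set[tuple[str, int]] = set()
    for atom in entry.atoms:
        if atom.is_hetero:
            continue
        key = (atom.chain_id, atom.residue_seq)
        if key in seen:
            continue
        seen.add(key)
        seqs.setdefault(atom.chain_id, []).append(_THREE_TO_ONE.get(atom.residue_name, "X"))
    return {cid: "".join(parts) for cid, parts in seqs.items()}


_METADATA_COLUMNS = [
    "complex_id", "receptor_chains", "ligand_chains", "pkd", "method",
    "resolution_A", "cryst_temp_K", "cryst_pH", "assay_method",
    "assay_temp_K", "assay_pH",
]


def read_metadata(path) -> pd.DataFrame:
    """Read the per-complex metadata CSV (one row per complex).

    Missing values are empty fields; chain groups are strings of chain ids.
    """
    df = pd.read_csv(path, dtype={"receptor_chains": str, "ligand_chains": str})
    missing = [c for c in ("complex_id", "pkd") if c not in df.columns]
    if missing:
        raise ValueError(f"metadata CSV missing required columns: {missing}")
    for col in _METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[_METADATA_COLUMNS]
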