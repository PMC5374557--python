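"""Explanatory structural variables for affinity models.

From a curated dimer we extract: counts of inter-chain atom-atom
interactions (disulfide bridges, salt bridges, hydrogen bonds, cation-pi,
aromatic stacking, hydrophobic and van der Waals contacts), solvent
accessible surface areas and the change on binding (delta-SASA), a surface
hydrophobicity aggregate, a surface-tension aggregate, and (when apo
coordinates exist) the bound/unbound interface RMSD.  Optional covariates
describing the crystallographic and binding-assay conditions can be
appended for condition-aware models.

Interaction criteria are geometric, heavy-atom based (crystal structures
usually lack hydrogens) and applied with a fixed precedence so that every
atom pair contributes to at most one class.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, fields
from functools import lru_cache
from importlib import resources

import numpy as np

from .sasa import UnknownElementError, compute_sasa, sasa_by_residue, vdw_radius
from .structures import AffinityRecord, AssayMethod, AtomRecord, ComplexEntry

__all__ = [
    "InteractionCriteria",
    "FeatureVector",
    "FeatureOptions",
    "INTERACTION_CLASSES",
    "ASSAY_LEVELS",
    "compute_interactions",
    "delta_sasa",
    "hydrophobicity_score",
    "surface_tension",
    "interface_rmsd",
    "kabsch_superpose",
    "build_feature_vector",
    "feature_table",
]

INTERACTION_CLASSES = (
    "disulfide",
    "salt_bridge",
    "hydrogen_bond",
    "cation_pi",
    "aromatic",
    "hydrophobic",
    "vdw_contact",
)

# one-hot encoding order for the assay-method covariate; OTHER/UNKNOWN is the
# reference level and gets no indicator column
ASSAY_LEVELS = ("ITC", "SPR", "INHIBITION")

_POSITIVE_ATOMS = {
    ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
_NEGATIVE_ATOMS = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
}
_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
# side-chain carbons of hydrophobic residues count as apolar
_APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}


@dataclass(frozen=True)
class InteractionCriteria:
    """Distance cutoffs (Angstrom) for each inter-chain interaction class.

    Precedence when a pair satisfies several predicates:
    disulfide > salt bridge > hydrogen bond > cation-pi > aromatic >
    hydrophobic > van der Waals.  Ring-mediated classes (cation-pi,
    aromatic) are measured to/between ring centroids; their member atom
    pairs are then excluded from the lower-precedence pairwise classes.
    """

    hydrogen_bond: float = 3.5
    salt_bridge: float = 4.0
    disulfide: float = 2.5
    cation_pi: float = 6.0
    aromatic: float = 7.0
    hydrophobic: float = 4.5
    vdw_slack: float = 0.5
    version: str = "default-1"

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and v <= 0:
                raise ValueError(f"cutoff {f.name} must be positive")


def _is_apolar_carbon(atom: AtomRecord) -> bool:
    return (
        atom.element == "C"
        and atom.atom_name not in ("C", "CA")
        and atom.residue_name in _APOLAR_RESIDUES
    )


def _rings(atoms: list[AtomRecord]) -> list[tuple[np.ndarray, frozenset[int]]]:
    """Complete aromatic rings among ``atoms``: (centroid, member indices)."""
    by_res: dict[tuple[str, int, str], dict[str, int]] = {}
    for i, a in enumerate(atoms):
        names = _RING_ATOMS.get(a.residue_name)
        if names and a.atom_name in names:
            by_res.setdefault((a.chain_id, a.residue_seq, a.residue_name), {})[a.atom_name] = i
    rings = []
    for (_, _, resname), members in by_res.items():
        if set(members) == set(_RING_ATOMS[resname]):
            idx = frozenset(members.values())
            centroid = np.mean([[atoms[i].x, atoms[i].y, atoms[i].z] for i in idx], axis=0)
            rings.append((centroid, idx))
    return rings


def compute_interactions(
    entry: ComplexEntry, criteria: InteractionCriteria | None = None
) -> dict[str, int]:
    """Count inter-chain-group interactions per class.

    Only receptor-ligand atom pairs are considered; hydrogens and atoms
    with untabulated elements are skipped (the latter with a warning).
    Deterministic given the criteria.
    """
    criteria = criteria or InteractionCriteria()
    groups = {}
    for name in ("receptor", "ligand"):
        atoms = []
        for a in entry.group_atoms(name):
            if a.element == "H" or a.is_hetero:
                continue
            try:
                vdw_radius(a.element)
            except UnknownElementError:
                warnings.warn(
                    f"{entry.complex_id}: atom {a.serial} has unknown element "
                    f"{a.element!r}; excluded from interaction counts",
                    stacklevel=2,
                )
                continue
            atoms.append(a)
        groups[name] = atoms
    rec, lig = groups["receptor"], groups["ligand"]
    counts = dict.fromkeys(INTERACTION_CLASSES, 0)

    rec_rings = _rings(rec)
    lig_rings = _rings(lig)

    # ring-mediated classes first; remember atoms engaged in a counted ring
    # interaction so their pairs don't double-count as hydrophobic/vdW
    excluded_pairs: set[tuple[int, int]] = set()
    for c_a, idx_a in rec_rings:
        for c_b, idx_b in lig_rings:
            if np.linalg.norm(c_a - c_b) <= criteria.aromatic:
                counts["aromatic"] += 1
                excluded_pairs.update((i, j) for i in idx_a for j in idx_b)
    for cation_side, ring_side, cation_atoms, rings, flip in (
        ("receptor", "ligand", rec, lig_rings, False),
        ("ligand", "receptor", lig, rec_rings, True),
    ):
        for i, a in enumerate(cation_atoms):
            if (a.residue_name, a.atom_name) not in _POSITIVE_ATOMS:
                continue
            pos = np.array([a.x, a.y, a.z])
            for centroid, idx in rings:
                if np.linalg.norm(pos - centroid) <= criteria.cation_pi:
                    counts["cation_pi"] += 1
                    for j in idx:
                        excluded_pairs.add((j, i) if flip else (i, j))

    for i, a in enumerate(rec):
        pa = np.array([a.x, a.y, a.z])
        for j, b in enumerate(lig):
            d = float(np.linalg.norm(pa - np.array([b.x, b.y, b.z])))
            cls = _classify_pair(a, b, d, criteria, (i, j) in excluded_pairs)
            if cls is not None:
                counts[cls] += 1
    return counts


def _classify_pair(
    a: AtomRecord, b: AtomRecord, d: float, criteria: InteractionCriteria, ring_engaged: bool
) -> str | None:
    """Pairwise classification with the documented precedence order."""
    if (
        a.residue_name == "CYS" and a.atom_name == "SG"
        and b.residue_name == "CYS" and b.atom_name == "SG"
        and d <= criteria.disulfide
    ):
        return "disulfide"
    ka, kb = (a.residue_name, a.atom_name), (b.residue_name, b.atom_name)
    if d <= criteria.salt_bridge and (
        (ka in _POSITIVE_ATOMS and kb in _NEGATIVE_ATOMS)
        or (ka in _NEGATIVE_ATOMS and kb in _POSITIVE_ATOMS)
    ):
        return "salt_bridge"
    if d <= criteria.hydrogen_bond and a.element in ("N", "O") and b.element in ("N", "O"):
        return "hydrogen_bond"
    if ring_engaged:
        return None
    if d <= criteria.hydrophobic and _is_apolar_carbon(a) and _is_apolar_carbon(b):
        return "hydrophobic"
    if d <= vdw_radius(a.element) + vdw_radius(b.element) + criteria.vdw_slack:
        return "vdw_contact"
    return None


def delta_sasa(
    entry: ComplexEntry, probe_radius: float = 1.4, n_points: int = 960
) -> dict[str, float]:
    """SASA of the complex, of each side alone, and the binding change.

    delta = SASA(complex) - [SASA(receptor) + SASA(ligand)], with the
    separated sides taken from the same (rigid) coordinates; at most zero
    up to sampling tolerance, since burial cannot create surface.
    """
    rec = [a for a in entry.group_atoms("receptor") if not a.is_hetero]
    lig = [a for a in entry.group_atoms("ligand") if not a.is_hetero]
    _, s_rec = compute_sasa(rec, probe_radius, n_points)
    _, s_lig = compute_sasa(lig, probe_radius, n_points)
    _, s_cpx = compute_sasa(rec + lig, probe_radius, n_points)
    return {
        "sasa_complex": s_cpx,
        "sasa_receptor": s_rec,
        "sasa_ligand": s_lig,
        "delta_sasa": s_cpx - (s_rec + s_lig),
    }


@lru_cache(maxsize=1)
def _hydrophobicity_table() -> dict[str, float]:
    text = resources.files("ppaffinity.data").joinpath("hydrophobicity.csv").read_text()
    rows = [r for r in text.splitlines() if r and not r.startswith("#")]
    return {res: float(score) for res, score in csv.reader(rows[1:])}


@lru_cache(maxsize=1)
def _tension_table() -> tuple[dict[str, float], dict[str, dict[str, float]]]:
    with resources.files("ppaffinity.data").joinpath("surface_tension.json").open() as fh:
        table = json.load(fh)
    return table["element"], table["charged_overrides"]


def _surface_residues(
    atoms: list[AtomRecord],
    surface_threshold: float,
    probe_radius: float,
    n_points: int,
) -> tuple[list[tuple[str, int]], dict[tuple[str, int], float]]:
    per_res = sasa_by_residue(atoms, probe_radius=probe_radius, n_points=n_points)
    surface = [key for key, area in per_res.items() if area > surface_threshold]
    return surface, per_res


def hydrophobicity_score(
    atoms: list[AtomRecord],
    surface_threshold: float = 5.0,
    terminal_correction: float = -0.05,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Mean hydrophobicity over surface residues, on a ~[-1, +2] scale.

    Each residue carries a tabulated score (hydrophilic ~ -1 to hydrophobic
    ~ +2); chain-terminal residues get an additive modulation (default
    -0.05, the free termini being charged).  A residue is "surface" when
    its summed heavy-atom SASA exceeds ``surface_threshold`` (A^2).
    Residues missing from the table are skipped with a warning.
    """
    protein = [a for a in atoms if not a.is_hetero and a.element != "H"]
    if not protein:
        raise ValueError("no protein atoms")
    surface, _ = _surface_residues(protein, surface_threshold, probe_radius, n_points)
    if not surface:
        raise ValueError("no surface residues (all buried)")
    table = _hydrophobicity_table()
    resname = {(a.chain_id, a.residue_seq): a.residue_name for a in protein}
    termini = _chain_termini(protein)
    scores = []
    for key in surface:
        name = resname[key]
        if name not in table:
            warnings.warn(f"residue {name} not in hydrophobicity table; skipped", stacklevel=2)
            continue
        s = table[name]
        if key in termini:
            s += terminal_correction
        scores.append(s)
    if not scores:
        raise ValueError("no scoreable surface residues")
    return float(np.mean(scores))


def _chain_termini(atoms: list[AtomRecord]) -> set[tuple[str, int]]:
    first_last: dict[str, tuple[int, int]] = {}
    for a in atoms:
        lo, hi = first_last.get(a.chain_id, (a.residue_seq, a.residue_seq))
        first_last[a.chain_id] = (min(lo, a.residue_seq), max(hi, a.residue_seq))
    out: set[tuple[str, int]] = set()
    for cid, (lo, hi) in first_last.items():
        out.add((cid, lo))
        out.add((cid, hi))
    return out


def surface_tension(
    atoms_or_entry,
    surface_threshold: float = 5.0,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Sum of per-residue atomic surface-tension contributions over the surface.

    Each surface residue contributes the sum of its atoms' tabulated
    values (per-element defaults, with overrides for formally charged
    side-chain atoms); buried residues contribute nothing.
    """
    atoms = atoms_or_entry.atoms if isinstance(atoms_or_entry, ComplexEntry) else atoms_or_entry
    protein = [a for a in atoms if not a.is_hetero and a.element != "H"]
    if not protein:
        raise ValueError("no protein atoms")
    surface, _ = _surface_residues(protein, surface_threshold, probe_radius, n_points)
    element_tab, overrides = _tension_table()
    surface_set = set(surface)
    total = 0.0
    for a in protein:
        if (a.chain_id, a.residue_seq) not in surface_set:
            continue
        override = overrides.get(a.residue_name, {}).get(a.atom_name)
        total += override if override is not None else element_tab.get(a.element, 0.0)
    return total


def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal least-squares rigid superposition (rotation R, translation t).

    Returns (R, t, moved) with ``moved = mobile @ R.T + t`` minimising the
    RMSD to ``target``.  Proper rotation enforced (det +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    A, B = mobile - mc, target - tc
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t, mobile @ R.T + t


def interface_rmsd(
    bound: list[AtomRecord] | np.ndarray,
    unbound: list[AtomRecord] | np.ndarray,
    mapping: list[tuple[int, int]] | None = None,
) -> float:
    """RMSD (A) between bound and unbound coordinates after Kabsch superposition.

    ``mapping`` pairs bound/unbound atom indices; when omitted the arrays
    must align 1:1.  Requires >= 3 non-collinear pairs.
    """
    b = np.array([[a.x, a.y, a.z] for a in bound]) if not isinstance(bound, np.ndarray) else bound
    u = (
        np.array([[a.x, a.y, a.z] for a in unbound])
        if not isinstance(unbound, np.ndarray)
        else unbound
    )
    if mapping is not None:
        bi, ui = zip(*mapping)
        b, u = b[list(bi)], u[list(ui)]
    if len(b) != len(u):
        raise ValueError("bound/unbound atom counts differ and no mapping given")
    if len(b) < 3:
        raise ValueError("need at least 3 mapped atom pairs")
    centered = b - b.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) atom set; superposition ill-defined")
    _, _, moved = kabsch_superpose(u, b)
    return float(np.sqrt(((moved - b) ** 2).sum(axis=1).mean()))


@dataclass(frozen=True)
class FeatureOptions:
    """Which covariate blocks to attach to a FeatureVector."""

    cryst_conditions: bool = False  # cryst_temp, cryst_pH
    resolution: bool = False
    assay_conditions: bool = False  # assay_temp, assay_pH
    assay_method: bool = False  # one-hot, OTHER/UNKNOWN reference
    probe_radius: float = 1.4
    n_points: int = 960
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)


class MissingCovariateError(ValueError):
    """A requested covariate is absent from the metadata for this complex."""


@dataclass
class FeatureVector:
    """Per-complex explanatory variables, in a stable column order."""

    complex_id: str
    values: dict[str, float]

    def to_row(self) -> dict[str, float | str]:
        return {"complex_id": self.complex_id, **self.values}

    @property
    def columns(self) -> list[str]:
        return list(self.values)


def build_feature_vector(
    entry: ComplexEntry,
    affinity: AffinityRecord | None = None,
    options: FeatureOptions | None = None,
) -> FeatureVector:
    """Assemble the model's explanatory variables for one curated dimer.

    Column order is fixed: interaction counts, SASA block, hydrophobicity,
    surface tension, then any requested covariates.  Raises
    :class:`MissingCovariateError` when a requested covariate is absent,
    so callers can drop-and-log the complex.
    """
    opts = options or FeatureOptions()
    values: dict[str, float] = {}
    values.update(compute_interactions(entry, opts.criteria))
    values.update(delta_sasa(entry, opts.probe_radius, opts.n_points))
    protein = [a for a in entry.atoms if not a.is_hetero]
    values["hydrophobicity"] = hydrophobicity_score(
        protein, probe_radius=opts.probe_radius, n_points=opts.n_points
    )
    values["surface_tension"] = surface_tension(
        protein, probe_radius=opts.probe_radius, n_points=opts.n_points
    )
    if opts.cryst_conditions:
        for label, val in (("cryst_temp", entry.cryst_temperature), ("cryst_pH", entry.cryst_ph)):
            if val is None:
                raise MissingCovariateError(f"{entry.complex_id}: missing {label}")
            values[label] = val
    if opts.resolution:
        if entry.resolution is None:
            raise MissingCovariateError(f"{entry.complex_id}: missing resolution")
        values["resolution"] = entry.resolution
    if opts.assay_conditions:
        if affinity is None:
            raise MissingCovariateError(f"{entry.complex_id}: no affinity record")
        for label, val in (
            ("assay_temp", affinity.assay_temperature),
            ("assay_pH", affinity.assay_ph),
        ):
            if val is None:
                raise MissingCovariateError(f"{entry.complex_id}: missing {label}")
            values[label] = val
    if opts.assay_method:
        if affinity is None:
            raise MissingCovariateError(f"{entry.complex_id}: no affinity record")
        method = affinity.assay_method.value
        for level in ASSAY_LEVELS:
            values[f"assay_{level}"] = 1.0 if method == level else 0.0
    return FeatureVector(entry.complex_id, values)


def feature_table(vectors: list[FeatureVector]):
    """Stack FeatureVectors into a DataFrame indexed by complex_id."""
    import pandas as pd

    return pd.DataFrame([v.to_row() for v in vectors]).set_index("complex_id")
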