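"""Solvent-accessible surface area by Shrake-Rupley sphere sampling.

Each atom's van der Waals sphere is inflated by the probe radius (default
1.4 A, a water-sized probe) and sampled with a deterministic Fibonacci
lattice of ``n_points`` points; a point is accessible when it lies outside
every other inflated sphere.  Per-atom SASA is the accessible fraction of
the inflated sphere's area 4*pi*(r_vdw + probe)^2.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .structures import AtomRecord

__all__ = ["vdw_radius", "compute_sasa", "sasa_by_residue", "UnknownElementError"]


class UnknownElementError(KeyError):
    """Raised when an element has no tabulated van der Waals radius."""


@lru_cache(maxsize=1)
def _radius_table() -> dict[str, float]:
    with resources.files("ppaffinity.data").joinpath("bondi_radii.json").open() as fh:
        table = json.load(fh)
    return {k: v for k, v in table.items() if not k.startswith("_")}


def vdw_radius(element: str) -> float:
    try:
        return _radius_table()[element.upper()]
    except KeyError:
        raise UnknownElementError(f"no van der Waals radius for element {element!r}") from None


@lru_cache(maxsize=8)
def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-angle spiral)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sasa(
    atoms: list[AtomRecord],
    probe_radius: float = 1.4,
    n_points: int = 960,
    include_hydrogens: bool = False,
) -> tuple[np.ndarray, float]:
    """Per-atom and total SASA (A^2) of an atom set.

    Hydrogens are excluded by default (heavy-atom SASA, the convention for
    crystal structures without hydrogens).  Returns ``(per_atom, total)``
    where ``per_atom`` aligns with the (filtered) atom list order.
    """
    if not atoms:
        raise ValueError("need at least one atom")
    if not include_hydrogens:
        atoms = [a for a in atoms if a.element != "H"]
        if not atoms:
            raise ValueError("no heavy atoms present")
    xyz = np.array([[a.x, a.y, a.z] for a in atoms])
    radii = np.array([vdw_radius(a.element) for a in atoms]) + probe_radius
    sphere = _fibonacci_sphere(n_points)

    tree = cKDTree(xyz)
    max_r = radii.max()
    per_atom = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = xyz[i] + radii[i] * sphere
        neighbours = [j for j in tree.query_ball_point(xyz[i], radii[i] + max_r) if j != i]
        if neighbours:
            nb = np.asarray(neighbours)
            d2 = ((pts[:, None, :] - xyz[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return per_atom, float(per_atom.sum())


def sasa_by_residue(
    atoms: list[AtomRecord], probe_radius: float = 1.4, n_points: int = 960
) -> dict[tuple[str, int], float]:
    """Summed heavy-atom SASA per (chain_id, residue_seq)."""
    heavy = [a for a in atoms if a.element != "H"]
    per_atom, _ = compute_sasa(heavy, probe_radius=probe_radius, n_points=n_points)
    out: dict[tuple[str, int], float] = {}
    for atom, area in zip(heavy, per_atom):
        key = (atom.chain_id, atom.residue_seq)
        out[key] = out.get(key, 0.0) + float(area)
    return out
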