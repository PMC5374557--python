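"""Synthetic inputs with the statistical structure the analysis assumes.

Two kinds of artifact are generated, both bit-reproducible from a seed:

* feature -> affinity tables following the scoring model itself,
  y = exp(b0 + sum b_i x_i) + Gaussian noise, optionally with (a)
  resolution-dependent degradation of the features entering the latent
  predictor (emulating the loss of coordinate precision in low-resolution
  crystals) and (b) additive per-assay-method pKd offsets (emulating
  systematic differences between ITC, SPR and inhibition measurements);

* toy two-chain PDB dimers whose inter-chain atom pairs realise exactly a
  requested number of interactions of each class under the default
  geometric criteria, for exercising the structural feature extractors
  against a planted ground truth.

The geometry of the toy dimers is deliberately schematic (residues are
sparse atom clusters, not real conformers); they validate bookkeeping,
not energetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import AtomRecord, ComplexEntry, write_complex

__all__ = [
    "GeneratorConfig",
    "FEATURE_NAMES",
    "generate_feature_table",
    "generate_resolution_effect_dataset",
    "generate_assay_effect_dataset",
    "generate_toy_complex",
]

FEATURE_NAMES = ("hbond_count", "hydrophobic_count", "buried_area", "surface_score")


def _default_beta() -> dict[str, float]:
    # two truly active features, two inert
    return {"hbond_count": 0.3, "hydrophobic_count": 0.2, "buried_area": 0.0, "surface_score": 0.0}


def _default_probs() -> dict[str, float]:
    return {"ITC": 0.3, "SPR": 0.3, "INHIBITION": 0.2, "OTHER": 0.2}


def _default_offsets() -> dict[str, float]:
    return {"ITC": 0.0, "SPR": 0.0, "INHIBITION": 0.0, "OTHER": 0.0}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study population.

    n_complexes
        Sample size (default 500).
    beta0, beta
        True intercept and per-feature coefficients of the latent
        log-scale predictor; defaults give pKd values in the familiar
        2-14 range with two active and two inert features.
    noise_sd
        Additive Gaussian error on the pKd scale (default 0.2).
    resolution_range
        Crystal resolution drawn Uniform[a, b] Angstrom.
    gamma, feature_noise_sd
        Resolution-dependent feature degradation: the features entering
        the latent predictor are x + N(0, m*tau) with multiplier
        m = 1 + gamma * max(0, resolution - threshold); the stored table
        holds the clean draws.  gamma = 0 or tau = 0 disables it.
    assay_probs, assay_offsets
        Categorical assay-method assignment and additive per-method pKd
        offsets delta_m.
    """

    n_complexes: int = 500
    beta0: float = 1.0
    beta: dict[str, float] = field(default_factory=_default_beta)
    noise_sd: float = 0.2
    resolution_range: tuple[float, float] = (1.5, 3.5)
    resolution_threshold: float = 2.5
    gamma: float = 0.0
    feature_noise_sd: float = 0.0
    assay_probs: dict[str, float] = field(default_factory=_default_probs)
    assay_offsets: dict[str, float] = field(default_factory=_default_offsets)

    def __post_init__(self) -> None:
        if self.n_complexes < 10:
            raise ValueError("n_complexes must be >= 10")
        if self.noise_sd < 0 or self.gamma < 0 or self.feature_noise_sd < 0:
            raise ValueError("noise_sd, gamma and feature_noise_sd must be >= 0")
        if abs(sum(self.assay_probs.values()) - 1.0) > 1e-9:
            raise ValueError("assay_probs must sum to 1")
        if not all(math.isfinite(v) for v in self.assay_offsets.values()):
            raise ValueError("assay offsets must be finite")
        if set(self.beta) - set(FEATURE_NAMES):
            raise ValueError(f"unknown features in beta: {set(self.beta) - set(FEATURE_NAMES)}")


def _draw_features(rng: np.random.Generator, n: int) -> pd.DataFrame:
    # count-like features as scaled Poissons, area-like as scaled Gammas
    return pd.DataFrame(
        {
            "hbond_count": rng.poisson(8.0, n) / 4.0,
            "hydrophobic_count": rng.poisson(12.0, n) / 6.0,
            "buried_area": rng.gamma(2.0, 1.0, n) / 2.0,
            "surface_score": rng.gamma(2.0, 1.0, n) / 2.0,
        }
    )


def generate_feature_table(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, dict]:
    """Draw (features X, pKd y, metadata, truth record) from the config.

    A single RNG stream drives every draw, so the output is reproducible
    bit-for-bit from (config, seed).  The truth record stores everything
    a recovery test needs: coefficients, the degraded features that
    actually generated y, per-row offsets and noise.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    n = config.n_complexes
    ids = [f"SYN{i:04d}" for i in range(n)]
    X = _draw_features(rng, n)
    X.index = pd.Index(ids, name="complex_id")

    lo, hi = config.resolution_range
    resolution = rng.uniform(lo, hi, n)
    multiplier = 1.0 + config.gamma * np.maximum(0.0, resolution - config.resolution_threshold)

    tau = config.feature_noise_sd
    X_latent = X.copy()
    if tau > 0:
        for name in FEATURE_NAMES:
            X_latent[name] = X[name] + rng.normal(0.0, multiplier * tau)

    eta = np.full(n, config.beta0)
    for name, b in config.beta.items():
        eta = eta + b * X_latent[name].to_numpy()

    levels = sorted(config.assay_probs)
    methods = rng.choice(levels, size=n, p=[config.assay_probs[m] for m in levels])
    offsets = np.array([config.assay_offsets.get(m, 0.0) for m in methods])
    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    y = pd.Series(np.exp(eta) + noise + offsets, index=X.index, name="pkd")

    metadata = pd.DataFrame(
        {
            "complex_id": ids,
            "method": "XRAY",
            "resolution_A": resolution,
            "assay_method": methods,
        }
    )
    truth = {
        "beta0": config.beta0,
        "beta": dict(config.beta),
        "noise_sd": config.noise_sd,
        "gamma": config.gamma,
        "feature_noise_sd": tau,
        "assay_offsets": dict(config.assay_offsets),
        "resolution": resolution,
        "latent_features": X_latent,
        "eta": eta,
        "noise": noise,
        "methods": methods,
        "seed": seed,
    }
    return X, y, metadata, truth


def generate_resolution_effect_dataset(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, dict, np.ndarray]:
    """A dataset with planted resolution-dependent feature degradation.

    Defaults: n = 400, gamma = 2, feature-noise tau = 0.3, resolutions
    Uniform[1.5, 3.5] spanning the 2.5 A threshold.  Returns the usual
    table plus a boolean high-resolution stratum label (resolution <=
    threshold).  Cross-validated accuracy on the stratum exceeds the full
    mixture in expectation.
    """
    if config is None:
        config = GeneratorConfig(n_complexes=400, gamma=2.0, feature_noise_sd=0.3)
    if config.gamma <= 0 or config.feature_noise_sd <= 0:
        raise ValueError("resolution-effect dataset needs gamma > 0 and feature_noise_sd > 0")
    lo, hi = config.resolution_range
    if not lo < config.resolution_threshold < hi:
        raise ValueError("resolution range must span the stratum threshold")
    X, y, metadata, truth = generate_feature_table(config, seed)
    labels = metadata["resolution_A"].to_numpy() <= config.resolution_threshold
    return X, y, metadata, truth, labels


def generate_assay_effect_dataset(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, dict]:
    """A dataset with planted per-assay-method affinity offsets.

    Defaults: n = 300, delta = +1 for inhibition assays and -1 for ITC
    (inhibition reads high, calorimetry reads low), 0 for SPR/OTHER.
    """
    if config is None:
        config = GeneratorConfig(
            n_complexes=300,
            assay_offsets={"ITC": -1.0, "SPR": 0.0, "INHIBITION": 1.0, "OTHER": 0.0},
        )
    if len(set(config.assay_offsets.values())) < 2:
        raise ValueError("need at least two distinct assay offsets")
    return generate_feature_table(config, seed)


# ---------------------------------------------------------------------------
# toy dimers with planted contacts

_SLOT_SPACING = 20.0  # A between planted-contact slots; beyond every cutoff
_HEX = [
    (math.cos(k * math.pi / 3.0), math.sin(k * math.pi / 3.0)) for k in range(6)
]
_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


def _ring_atoms(x: float, y: float, radius: float = 1.39) -> list[tuple[str, str, float, float, float]]:
    # ring plane perpendicular to the interface axis: keeps every ring atom
    # >= the centroid separation away from the partner, so only the
    # centroid-based classes fire
    return [
        (name, "C", x, y + radius * cy, radius * cz)
        for name, (cy, cz) in zip(_RING_NAMES, _HEX)
    ]


def _planted_residues(cls: str, y: float):
    """(chain A atoms, chain B atoms) realising exactly one contact of class
    ``cls`` at slot height ``y``; atoms are (name, element, resname, x, y, z)."""
    if cls == "hydrogen_bond":
        return (
            [("N", "N", "GLY", -1.45, y, 0.0), ("CA", "C", "GLY", -4.5, y, 0.0)],
            [("O", "O", "GLY", 1.45, y, 0.0), ("CA", "C", "GLY", 4.5, y, 0.0)],
        )
    if cls == "salt_bridge":
        return (
            [("NZ", "N", "LYS", -1.75, y, 0.0), ("CA", "C", "LYS", -5.0, y, 0.0)],
            [("OD1", "O", "ASP", 1.75, y, 0.0), ("CA", "C", "ASP", 5.0, y, 0.0)],
        )
    if cls == "disulfide":
        return (
            [("SG", "S", "CYS", -1.15, y, 0.0), ("CA", "C", "CYS", -4.5, y, 0.0)],
            [("SG", "S", "CYS", 1.15, y, 0.0), ("CA", "C", "CYS", 4.5, y, 0.0)],
        )
    if cls == "hydrophobic":
        return (
            [("CD1", "C", "ILE", -2.1, y, 0.0), ("CA", "C", "ILE", -5.5, y, 0.0)],
            [("CD1", "C", "ILE", 2.1, y, 0.0), ("CA", "C", "ILE", 5.5, y, 0.0)],
        )
    if cls == "vdw_contact":
        return (
            [("CA", "C", "GLY", -1.75, y, 0.0)],
            [("CA", "C", "GLY", 1.75, y, 0.0)],
        )
    if cls == "aromatic":
        a = [(n, e, "PHE", x, yy, zz) for n, e, x, yy, zz in _ring_atoms(-3.0, y)]
        a.append(("CA", "C", "PHE", -7.0, y, 0.0))
        b = [(n, e, "PHE", x, yy, zz) for n, e, x, yy, zz in _ring_atoms(3.0, y)]
        b.append(("CA", "C", "PHE", 7.0, y, 0.0))
        return a, b
    if cls == "cation_pi":
        a = [("NZ", "N", "LYS", -2.5, y, 0.0), ("CA", "C", "LYS", -6.0, y, 0.0)]
        b = [(n, e, "PHE", x, yy, zz) for n, e, x, yy, zz in _ring_atoms(2.5, y)]
        b.append(("CA", "C", "PHE", 6.5, y, 0.0))
        return a, b
    raise ValueError(f"no planted-contact template for interaction class {cls!r}")


def generate_toy_complex(
    contacts: dict[str, int],
    chain_size: int = 6,
    extra_separation: float = 0.0,
    complex_id: str = "TOY1",
) -> tuple[str, dict[str, int]]:
    """Emit PDB text of a two-chain dimer with planted interface contacts.

    ``contacts`` maps interaction-class names to requested counts; each
    instance occupies its own slot along the interface, far enough from
    every other that no accidental interactions arise.  Chains A
    (receptor) and B (ligand) each carry ``chain_size`` inert backbone
    residues well away from the interface.  ``extra_separation`` shifts
    chain B away along the interface normal: 0 keeps the planted counts,
    >= 10 A breaks every contact (ground truth all zero); intermediate
    shifts are rejected as geometrically ambiguous.

    Returns (pdb_text, ground-truth per-class counts).
    """
    for cls, count in contacts.items():
        if count < 0:
            raise ValueError(f"negative count for {cls}")
        _planted_residues(cls, 0.0)  # validates the class name
    if 0.0 < extra_separation < 10.0:
        raise ValueError(
            "extra_separation between 0 and 10 A leaves contacts partially formed; "
            "use 0 (planted) or >= 10 (fully separated)"
        )
    body_top = (chain_size - 1) * 6.0
    atoms_a: list[tuple[str, str, str, float, float, float]] = []
    atoms_b: list[tuple[str, str, str, float, float, float]] = []
    for i in range(chain_size):
        y = i * 6.0
        atoms_a.append(("N", "N", "GLY", -11.0, y, 0.0))
        atoms_a.append(("CA", "C", "GLY", -10.0, y, 0.6))
        atoms_a.append(("C", "C", "GLY", -9.3, y, 1.7))
        atoms_a.append(("O", "O", "GLY", -9.0, y, 2.8))
        atoms_b.append(("N", "N", "GLY", 11.0, y, 0.0))
        atoms_b.append(("CA", "C", "GLY", 10.0, y, 0.6))
        atoms_b.append(("C", "C", "GLY", 9.3, y, 1.7))
        atoms_b.append(("O", "O", "GLY", 9.0, y, 2.8))

    slot = 0
    planted_a: list[list[tuple[str, str, str, float, float, float]]] = []
    planted_b: list[list[tuple[str, str, str, float, float, float]]] = []
    for cls in sorted(contacts):
        for _ in range(contacts[cls]):
            y = body_top + _SLOT_SPACING + slot * _SLOT_SPACING
            a, b = _planted_residues(cls, y)
            planted_a.append([(n, e, r, x, yy, zz) for n, e, r, x, yy, zz in a])
            planted_b.append([(n, e, r, x, yy, zz) for n, e, r, x, yy, zz in b])
            slot += 1

    records: list[AtomRecord] = []
    serial = 1

    def emit(chain: str, residues: list[list[tuple]], xshift: float) -> None:
        nonlocal serial
        for seq, res_atoms in enumerate(residues, start=1):
            for name, element, resname, x, y, z in res_atoms:
                records.append(
                    AtomRecord(
                        serial=serial,
                        atom_name=name,
                        element=element,
                        residue_name=resname,
                        residue_seq=seq,
                        chain_id=chain,
                        x=x + xshift,
                        y=y,
                        z=z,
                    )
                )
                serial += 1

    body_a = [
        [atoms_a[4 * i + j] for j in range(4)] for i in range(chain_size)
    ]
    body_b = [
        [atoms_b[4 * i + j] for j in range(4)] for i in range(chain_size)
    ]
    emit("A", body_a + planted_a, 0.0)
    emit("B", body_b + planted_b, extra_separation)

    entry = ComplexEntry(
        complex_id=complex_id,
        receptor_chains=frozenset({"A"}),
        ligand_chains=frozenset({"B"}),
        atoms=records,
    )
    truth = {cls: 0 for cls in (
        "disulfide", "salt_bridge", "hydrogen_bond", "cation_pi",
        "aromatic", "hydrophobic", "vdw_contact",
    )}
    if extra_separation == 0.0:
        truth.update({cls: int(c) for cls, c in contacts.items()})
    return write_complex(entry), truth
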