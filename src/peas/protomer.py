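"""Charge-site enumeration and two-tier ranking of protomers/deprotomers.

For a neutral input molecule, every titratable nitrogen and oxygen is
enumerated and turned into a singly charged adduct model — [M+H]+ by adding
a proton at a lone-pair-bearing N/O, or [M−H]− by removing a proton from an
N–H/O–H. The candidate charge models are ranked by a cheap primary scorer,
then the top models are re-scored (and optionally re-geometrized) by a more
trustworthy secondary scorer whose ordering supersedes the primary ranking.
Relative energies and gas-phase mole fractions are reported per rank.

Scorers are pluggable through the :class:`SiteScorer` contract. The built-in
:class:`SurrogateScorer` is a deterministic heuristic (fixed site-affinity
constants plus the steric clash score) meant for testing and as a template
for wiring in trained ranking models or ML potentials.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .chem_core import Atom, Conformer, Molecule, clash_energy

logger = logging.getLogger(__name__)

__all__ = [
    "GAS_CONSTANT_KCAL",
    "PROTON_BOND_LENGTHS",
    "ChargeSite",
    "ChargeModel",
    "SiteScorer",
    "SurrogateScorer",
    "NoTitratableSiteError",
    "enumerate_sites",
    "build_charge_model",
    "rank_charge_models",
    "mole_fractions",
    "builtin_surrogate_scorer",
]

#: Molar gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.98720425864e-3

#: Standard X–H bond lengths (Å) used when placing the added proton.
PROTON_BOND_LENGTHS = {"N": 1.01, "O": 0.96}

PROTONATION = "protonation"
DEPROTONATION = "deprotonation"
ADDUCT_PROTONATED = "[M+H]+"
ADDUCT_DEPROTONATED = "[M-H]-"


class NoTitratableSiteError(ValueError):
    """The input molecule has no N/O site compatible with the requested
    adduct; the pipeline terminates with an error in this case."""


@dataclass(frozen=True)
class ChargeSite:
    """One titratable N or O atom and the direction of titration."""

    atom_index: int
    element: str
    mode: str  # "protonation" | "deprotonation"

    def __post_init__(self) -> None:
        if self.element not in ("N", "O"):
            raise ValueError(f"titratable sites are N or O, got {self.element}")
        if self.mode not in (PROTONATION, DEPROTONATION):
            raise ValueError(f"unknown mode {self.mode!r}")

    def label(self) -> str:
        return f"{self.element}{self.atom_index}"


@dataclass
class ChargeModel:
    """A singly charged adduct: the charged molecule, the site that carries
    the charge, and the two-tier scores/rank assigned during ranking."""

    molecule: Molecule
    site: ChargeSite
    adduct: str
    geometry: Conformer
    primary_score: float | None = None
    secondary_score: float | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        expected = 1 if self.adduct == ADDUCT_PROTONATED else -1
        if self.molecule.formal_charge != expected:
            raise ValueError(
                f"adduct {self.adduct} requires formal charge {expected}, "
                f"got {self.molecule.formal_charge}"
            )

    @property
    def best_score(self) -> float:
        if self.secondary_score is not None:
            return self.secondary_score
        if self.primary_score is not None:
            return self.primary_score
        raise ValueError("model has not been scored")


@runtime_checkable
class SiteScorer(Protocol):
    """Scoring contract: lower score = more stable charge model.

    ``score`` may return either a bare scalar or ``(scalar, coords)`` when
    the scorer also relaxes the geometry (an "optimizing" scorer). Must be
    deterministic for a fixed input and seed.
    """

    def score(self, model: ChargeModel) -> float | tuple[float, np.ndarray]: ...


def enumerate_sites(mol: Molecule, adduct: str) -> list[ChargeSite]:
    """All titratable N and O atoms compatible with the adduct, in stable
    atom-index order.

    [M+H]+ accepts any N with fewer than 4 connections or O with fewer than
    3 (a lone pair is available); [M−H]− accepts any N or O bearing at least
    one hydrogen. Raises :class:`NoTitratableSiteError` when nothing
    qualifies.
    """
    if mol.formal_charge != 0:
        raise ValueError("site enumeration requires a neutral molecule")
    if adduct not in (ADDUCT_PROTONATED, ADDUCT_DEPROTONATED):
        raise ValueError(f"unknown adduct {adduct!r}")
    mode = PROTONATION if adduct == ADDUCT_PROTONATED else DEPROTONATION
    sites: list[ChargeSite] = []
    for idx, atom in enumerate(mol.atoms):
        if atom.element not in ("N", "O"):
            continue
        degree = len(mol.neighbors(idx))
        if mode == PROTONATION:
            limit = 4 if atom.element == "N" else 3
            if degree < limit:
                sites.append(ChargeSite(idx, atom.element, mode))
        else:
            if mol.hydrogen_neighbors(idx):
                sites.append(ChargeSite(idx, atom.element, mode))
    if not sites:
        raise NoTitratableSiteError(
            f"no titratable N/O site for adduct {adduct} in molecule {mol.name!r}"
        )
    return sites


def build_charge_model(mol: Molecule, site: ChargeSite) -> ChargeModel:
    """Construct the charged adduct for one site.

    Protonation appends one H at the standard N–H/O–H bond length along the
    least-crowded direction (the direction on a deterministic unit-sphere
    grid that maximizes the minimum distance to all existing atoms, seeded
    by the anti-bonding direction). Deprotonation removes the lowest-index
    hydrogen on the site atom. All other atoms keep their indices and exact
    coordinates, so sibling models share geometry except at the charge site.
    """
    charged = mol.copy()
    if site.mode == PROTONATION:
        pos = _proton_position(mol, site.atom_index)
        charged.atoms.append(Atom("H", pos))
        new_idx = charged.n_atoms - 1
        charged.bonds.append((site.atom_index, new_idx, 1))
        charged.formal_charge = 1
        adduct = ADDUCT_PROTONATED
    else:
        hs = mol.hydrogen_neighbors(site.atom_index)
        if not hs:
            raise ValueError(f"site atom {site.atom_index} has no hydrogen to remove")
        h_idx = hs[0]
        del charged.atoms[h_idx]
        charged.bonds = [
            (i - (i > h_idx), j - (j > h_idx), o)
            for i, j, o in charged.bonds
            if h_idx not in (i, j)
        ]
        charged.formal_charge = -1
        adduct = ADDUCT_DEPROTONATED
    charged.name = mol.name
    # re-normalize (i < j) ordering after reindexing
    charged.bonds = [(min(i, j), max(i, j), o) for i, j, o in charged.bonds]
    geometry = charged.to_conformer(conf_id=f"{site.label()}_{site.mode}")
    return ChargeModel(molecule=charged, site=site, adduct=adduct, geometry=geometry)


def _proton_position(mol: Molecule, site_idx: int) -> np.ndarray:
    """Least-crowded proton placement: scan a Fibonacci sphere of candidate
    directions (plus the anti-bonding direction) and pick the one whose new
    H maximizes the minimum distance to every existing atom."""
    coords = mol.coords
    site_pos = coords[site_idx]
    bond_len = PROTON_BOND_LENGTHS[mol.atoms[site_idx].element]
    candidates = list(_fibonacci_sphere(64))
    nbrs = mol.neighbors(site_idx)
    if nbrs:
        away = np.zeros(3)
        for k in nbrs:
            v = site_pos - coords[k]
            nv = np.linalg.norm(v)
            if nv > 1e-9:
                away += v / nv
        if np.linalg.norm(away) > 1e-9:
            candidates.insert(0, away / np.linalg.norm(away))
    others = np.delete(coords, site_idx, axis=0)
    best_dir, best_min = candidates[0], -np.inf
    for d in candidates:
        p = site_pos + bond_len * d
        dmin = float(np.min(np.linalg.norm(others - p, axis=1))) if len(others) else np.inf
        if dmin > best_min + 1e-12:
            best_min, best_dir = dmin, d
    return site_pos + bond_len * best_dir


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def rank_charge_models(
    models: Sequence[ChargeModel],
    primary: SiteScorer,
    secondary: SiteScorer,
    top_k: int | None = None,
) -> list[ChargeModel]:
    """Two-tier ranking: primary scores order all models, then the secondary
    scorer re-scores (and may re-geometrize) the ``top_k`` best, and its
    ordering supersedes the primary ranking within that group. Remaining
    models follow in primary order. Ranks are reassigned 1..K; ties break by
    primary score, then by site atom index. Scorer failures drop the model
    with a warning; if every model fails, an error is raised.
    """
    if not models:
        raise ValueError("no charge models to rank")
    if top_k is not None and top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")

    scored: list[ChargeModel] = []
    for m in models:
        try:
            m.primary_score = _apply_scorer(primary, m, update_geometry=False)
        except Exception as exc:  # pragma: no cover - exercised via failing scorer test
            logger.warning("primary scorer failed on site %s: %s", m.site.label(), exc)
            continue
        scored.append(m)
    if not scored:
        raise RuntimeError("primary scorer failed on every charge model")

    scored.sort(key=lambda m: (m.primary_score, m.site.atom_index))
    k = len(scored) if top_k is None else min(top_k, len(scored))

    head, tail = scored[:k], scored[k:]
    rescored: list[ChargeModel] = []
    for m in head:
        try:
            m.secondary_score = _apply_scorer(secondary, m, update_geometry=True)
        except Exception as exc:
            logger.warning("secondary scorer failed on site %s: %s", m.site.label(), exc)
            continue
        rescored.append(m)
    if not rescored and not tail:
        raise RuntimeError("secondary scorer failed on every charge model")
    rescored.sort(key=lambda m: (m.secondary_score, m.primary_score, m.site.atom_index))

    final = rescored + tail
    for rank, m in enumerate(final, start=1):
        m.rank = rank
    return final


def _apply_scorer(scorer: SiteScorer, model: ChargeModel, update_geometry: bool) -> float:
    result = scorer.score(model) if hasattr(scorer, "score") else scorer(model)  # type: ignore[operator]
    if isinstance(result, tuple):
        value, coords = result
        if update_geometry:
            model.geometry = Conformer(
                conf_id=model.geometry.conf_id,
                coords=np.asarray(coords, dtype=float),
                energy=float(value),
            )
    else:
        value = result
        if update_geometry:
            model.geometry.energy = float(value)
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"scorer returned non-finite score {value}")
    return value


def mole_fractions(energies: Sequence[float], temperature: float = 298.15) -> np.ndarray:
    """Boltzmann gas-phase mole fractions from relative energies in
    kcal/mol: x_i = exp(−(E_i − E_min)/RT) / Σ_j exp(−(E_j − E_min)/RT).

    Shifting by E_min makes the computation overflow-free; the result is
    invariant to adding any constant to all energies.
    """
    if len(energies) == 0:
        raise ValueError("at least one energy is required")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    e = np.asarray(energies, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    w = np.exp(-(e - e.min()) / (GAS_CONSTANT_KCAL * temperature))
    return w / w.sum()


# ---------------------------------------------------------------------------
# Built-in surrogate scorer

# Fixed site-affinity constants (kcal/mol scale). For protonation the entry
# approximates a gas-phase proton affinity (larger = more basic, so it enters
# the score negated); amine N > imine/aromatic N > carbonyl O > hydroxyl/ether
# O. For deprotonation the entry approximates a gas-phase acidity (smaller =
# more acidic = better); carboxylic O–H < generic O–H < N–H.
_PROTON_AFFINITY = {
    ("N", 3): 225.0,  # sp3 amine
    ("N", 2): 218.0,  # imine / aromatic N
    ("N", 1): 210.0,  # nitrile-like
    ("O", 1): 197.0,  # carbonyl O
    ("O", 2): 190.0,  # hydroxyl / ether O
}
_ACIDITY = {"O": 347.0, "N": 366.0}
_CARBOXYL_ACIDITY = 338.0


def builtin_surrogate_scorer(model: ChargeModel) -> float:
    """Deterministic heuristic score for a charge model (lower = better).

    A fixed base affinity keyed on the site element and its heavy-atom
    environment plus the clash-score energy of the geometry. It reproduces
    coarse chemical preferences (amine N protonates ahead of ether O,
    carboxylic acids deprotonate ahead of amines) well enough to exercise
    the ranking machinery; it is an explicit surrogate, swappable through
    the :class:`SiteScorer` contract.
    """
    site = model.site
    mol = model.molecule
    clash = clash_energy(mol, model.geometry.coords)
    if site.mode == PROTONATION:
        # connection count of the site atom in the neutral parent
        # (charged degree minus the added proton) selects the affinity row
        neutral_degree = len(mol.neighbors(site.atom_index)) - 1
        hi = 3 if site.element == "N" else 2
        key = (site.element, int(np.clip(neutral_degree, 1, hi)))
        affinity = _PROTON_AFFINITY[key]
        return -affinity + clash
    acidity = _ACIDITY[site.element]
    if site.element == "O" and _is_carboxyl_like(mol, site.atom_index):
        acidity = _CARBOXYL_ACIDITY
    return acidity + clash


def _is_carboxyl_like(mol: Molecule, o_idx: int) -> bool:
    """True when the O sits on a carbon that carries another oxygen (the
    carboxylate/ester pattern that delocalizes the negative charge)."""
    for c in mol.heavy_neighbors(o_idx):
        if mol.atoms[c].element != "C":
            continue
        for other in mol.heavy_neighbors(c):
            if other != o_idx and mol.atoms[other].element == "O":
                return True
    return False


@dataclass
class SurrogateScorer:
    """Class wrapper around :func:`builtin_surrogate_scorer` satisfying the
    :class:`SiteScorer` contract; ``optimizing=True`` makes it return the
    (unchanged) geometry alongside the score, exercising the optimizing-
    scorer code path."""

    optimizing: bool = False

    def score(self, model: ChargeModel) -> float | tuple[float, np.ndarray]:
        value = builtin_surrogate_scorer(model)
        if self.optimizing:
            return value, model.geometry.coords
        return value
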