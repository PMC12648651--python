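"""Diverse low-energy conformer generation per charge model.

Generation goes through the :class:`ConformerGenerator` contract so that
external engines can be plugged in; the built-in generator enumerates a
deterministic torsion grid over the molecule's rotatable bonds and scores
geometries with the repulsive clash energy. A similarity+energy filter then
removes high-energy members and structural near-duplicates, targeting (by
default) 1000 unique low-energy conformers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import networkx as nx
import numpy as np

from .chem_core import Conformer, Ensemble, clash_energy, rotatable_bonds, write_xyz
from .normal_walk import svd_rmsd
from .protomer import ChargeModel

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_NUM_OF_CONF",
    "GeneratorConfig",
    "ConformerGenerator",
    "TorsionGridGenerator",
    "torsion_grid_generate",
    "diversity_filter",
    "generate_ensemble",
]

#: Default target number of unique low-energy conformers per charge model.
DEFAULT_NUM_OF_CONF = 1000


@dataclass
class GeneratorConfig:
    """Knobs of the generation + filtering stage.

    num_of_conf: target ensemble size (the generator may undershoot when the
        molecule's torsional space is small — that is not an error).
    rmsd_cutoff: Å; conformers closer than this (superposed RMSD) to an
        already-kept one are considered duplicates.
    energy_window: kcal/mol above the ensemble minimum; anything higher is
        discarded as not low-energy.
    torsion_grid_deg: grid spacing for the built-in torsion driver; must
        divide 360.
    """

    num_of_conf: int = DEFAULT_NUM_OF_CONF
    rmsd_cutoff: float = 0.5
    energy_window: float = 50.0
    torsion_grid_deg: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_of_conf < 1:
            raise ValueError(f"num_of_conf must be >= 1, got {self.num_of_conf}")
        if self.rmsd_cutoff < 0:
            raise ValueError(f"rmsd_cutoff must be >= 0, got {self.rmsd_cutoff}")
        if self.energy_window <= 0:
            raise ValueError(f"energy_window must be > 0, got {self.energy_window}")
        if self.torsion_grid_deg <= 0 or 360 % self.torsion_grid_deg != 0:
            raise ValueError(
                f"torsion_grid_deg must divide 360, got {self.torsion_grid_deg}"
            )


@runtime_checkable
class ConformerGenerator(Protocol):
    """Generation contract: produce energied conformers for a charge model.

    Implementations must be deterministic for a fixed config seed and emit
    geometries with the charge model's exact atom count and ordering.
    """

    def generate(self, model: ChargeModel, config: GeneratorConfig) -> list[Conformer]: ...


def torsion_grid_generate(model: ChargeModel, config: GeneratorConfig) -> list[Conformer]:
    """Enumerate torsion-grid conformers of a charge model.

    Every rotatable bond gets ``360 / torsion_grid_deg`` settings; all
    combinations are enumerated (the smaller fragment rotates about each
    bond) unless the grid exceeds ``num_of_conf``, in which case a seeded
    uniform subsample of combinations is taken. Each geometry is scored with
    the clash energy. A rigid molecule (no rotatable bonds) yields exactly
    the input geometry.
    """
    mol = model.molecule
    bonds = rotatable_bonds(mol)
    base = model.geometry.coords
    if not bonds:
        return [Conformer("grid_0", base.copy(), energy=clash_energy(mol, base))]

    n_settings = 360 // config.torsion_grid_deg
    angles = np.deg2rad(np.arange(n_settings) * config.torsion_grid_deg)
    total = n_settings ** len(bonds)
    if total > config.num_of_conf:
        rng = np.random.default_rng(config.seed)
        combo_ids = _sample_unique(rng, total, config.num_of_conf)
    else:
        combo_ids = list(range(total))

    movers = [_rotating_side(mol, i, j) for i, j in bonds]
    out: list[Conformer] = []
    for cid in combo_ids:
        coords = base.copy()
        rem = cid
        for (i, j), side in zip(bonds, movers):
            setting = rem % n_settings
            rem //= n_settings
            if setting:
                coords = _rotate_about_bond(coords, i, j, side, angles[setting])
        out.append(Conformer(f"grid_{cid}", coords, energy=clash_energy(mol, coords)))
    return out


def _rotating_side(mol, i: int, j: int) -> np.ndarray:
    """Atom indices of the smaller fragment when bond (i, j) is cut; that
    side rotates. Tie → the side containing the higher-index endpoint."""
    g = mol.graph()
    g.remove_edge(i, j)
    side_i = nx.node_connected_component(g, i)
    side_j = nx.node_connected_component(g, j)
    if len(side_j) < len(side_i) or (len(side_j) == len(side_i)):
        side = side_j - {j}
    else:
        side = side_i - {i}
    return np.fromiter(sorted(side), dtype=int)


def _rotate_about_bond(
    coords: np.ndarray, i: int, j: int, side: np.ndarray, angle: float
) -> np.ndarray:
    """Rodrigues rotation of ``side`` atoms about the i→j axis; the axis
    endpoints themselves never move, so later bond axes stay valid."""
    axis = coords[j] - coords[i]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return coords
    k = axis / norm
    out = coords.copy()
    v = coords[side] - coords[j]
    cos_a, sin_a = np.cos(angle), np.sin(angle)
    rotated = (
        v * cos_a
        + np.cross(k, v) * sin_a
        + np.outer(v @ k, k) * (1.0 - cos_a)
    )
    out[side] = rotated + coords[j]
    return out


def _sample_unique(rng: np.random.Generator, total: int, k: int) -> list[int]:
    """k distinct integers in [0, total) without materializing the range
    (totals grow exponentially with rotatable-bond count)."""
    if k >= total:
        return list(range(total))
    chosen: set[int] = set()
    while len(chosen) < k:
        need = k - len(chosen)
        chosen.update(int(v) for v in rng.integers(0, total, size=2 * need))
        while len(chosen) > k:
            chosen.pop()
    return sorted(chosen)


@dataclass
class TorsionGridGenerator:
    """Contract wrapper for :func:`torsion_grid_generate`."""

    def generate(self, model: ChargeModel, config: GeneratorConfig) -> list[Conformer]:
        return torsion_grid_generate(model, config)


def diversity_filter(
    conformers: Sequence[Conformer],
    config: GeneratorConfig,
    molecule,
    rank_label: int = 1,
) -> Ensemble:
    """Remove high-energy and structurally redundant conformers.

    Conformers above ``min_energy + energy_window`` are dropped first. The
    rest are scanned greedily in ascending energy (tie → input index): a
    conformer is kept unless its superposed RMSD to an already-kept member
    is below ``rmsd_cutoff``. The scan stops at ``num_of_conf`` survivors.
    The global minimum-energy conformer is always kept; output preserves
    input order. An empty input yields an empty ensemble with a warning —
    an insufficient ensemble is a downstream-filtering concern, not a
    failure.
    """
    if not conformers:
        logger.warning("diversity_filter received an empty conformer list")
        return Ensemble(molecule=molecule, conformers=[], rank_label=rank_label)
    energies = [c.energy if c.energy is not None else 0.0 for c in conformers]
    emin = min(energies)
    eligible = [i for i, e in enumerate(energies) if e <= emin + config.energy_window]
    order = sorted(eligible, key=lambda i: (energies[i], i))
    kept: list[int] = []
    for i in order:
        if len(kept) >= config.num_of_conf:
            break
        if all(
            svd_rmsd(conformers[i].coords, conformers[j].coords) >= config.rmsd_cutoff
            for j in kept
        ):
            kept.append(i)
    kept.sort()
    return Ensemble(
        molecule=molecule,
        conformers=[conformers[i] for i in kept],
        rank_label=rank_label,
    )


def generate_ensemble(
    model: ChargeModel,
    config: GeneratorConfig,
    generator: ConformerGenerator | None = None,
    out_dir: str | Path | None = None,
) -> Ensemble:
    """Run a generator for one ranked charge model and filter its output.

    When ``out_dir`` is given, each surviving conformer is written as an
    individual XYZ file under ``<out_dir>/opt_Rank[n]_ensemble/``.
    """
    if model.rank is None:
        raise ValueError("charge model must be ranked before ensemble generation")
    generator = generator or TorsionGridGenerator()
    raw = generator.generate(model, config)
    n = model.molecule.n_atoms
    for c in raw:
        if c.n_atoms != n:
            raise ValueError(
                f"generator {type(generator).__name__} emitted conformer {c.conf_id} "
                f"with {c.n_atoms} atoms; charge model has {n}"
            )
    ensemble = diversity_filter(raw, config, model.molecule, rank_label=model.rank)
    if out_dir is not None:
        folder = Path(out_dir) / f"opt_Rank{model.rank}_ensemble"
        folder.mkdir(parents=True, exist_ok=True)
        for idx, conf in enumerate(ensemble):
            write_xyz(model.molecule, folder / f"conf_{idx}.xyz", conformer=conf)
    return ensemble
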