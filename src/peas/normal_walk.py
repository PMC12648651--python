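"""Similarity reduction of conformer ensembles by a stepped walk across the
reference-RMSD distribution.

Large focused ensembles are expensive to carry into quantum-chemical
refinement, so ensembles with more than 50 members are thinned: every
conformer's RMSD to a reference (the lowest-energy member) is computed by
SVD/Kabsch superposition, the RMSD range is traversed from its trailing tail
(minimum) to its leading tail (maximum) in ``20 × ROT`` steps — ROT being
the rotatable-bond count, so flexible molecules keep proportionally more
structures — and each step retains a single lowest-energy representative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .chem_core import Ensemble, rotatable_bond_count

logger = logging.getLogger(__name__)

__all__ = [
    "WALK_STEP_FACTOR",
    "SIZE_THRESHOLD",
    "SimilarityReport",
    "svd_rmsd",
    "walk_steps",
    "ensemble_rmsd_stats",
    "normal_walk_reduce",
]

#: Steps per rotatable bond in the walk; a heuristic giving sufficient
#: sampling of the RMSD distribution.
WALK_STEP_FACTOR = 20

#: Ensembles at or below this size are already an acceptable final output
#: and bypass reduction.
SIZE_THRESHOLD = 50


def svd_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD between two equal-length ordered point sets over rigid
    superposition (Kabsch algorithm).

    Both sets are centered, the optimal rotation is obtained from the SVD of
    the 3×3 cross-covariance with the determinant sign correction that
    excludes reflections, and the RMSD after rotation is returned. Symmetric
    in its arguments.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 1:
        raise ValueError(f"point sets must be matching N×3 arrays, got {P.shape} and {Q.shape}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    # reflection-excluding correction: flip the smallest singular direction
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Pc @ R.T - Qc
    return float(np.sqrt((diff * diff).sum() / P.shape[0]))


def walk_steps(rot: int) -> int:
    """Number of walk steps for a molecule with ``rot`` rotatable bonds:
    ``20 × ROT``, floored at 1 so rigid molecules still take one step."""
    if rot < 0:
        raise ValueError(f"rotatable-bond count must be >= 0, got {rot}")
    return max(1, WALK_STEP_FACTOR * rot)


@dataclass
class SimilarityReport:
    """Reference-based RMSD statistics of an ensemble plus the walk step
    count. ``rmsds`` is aligned with the ensemble's conformer order; the
    reference's own entry is 0. Mean/sd/min/max are over the non-reference
    members, with the population (not sample) standard deviation."""

    reference_id: str
    reference_index: int
    rmsds: np.ndarray
    mean: float
    sd: float
    rmsd_min: float
    rmsd_max: float
    steps: int


def _reference_index(ensemble: Ensemble) -> int:
    """Lowest-energy conformer (ties → lowest index); first conformer when
    any energy is absent."""
    energies = ensemble.energies
    if any(e is None for e in energies):
        return 0
    return int(np.argmin(energies))


def ensemble_rmsd_stats(ensemble: Ensemble) -> SimilarityReport:
    """RMSD of every member to the reference conformer, summarized as the
    distribution the walk traverses."""
    if len(ensemble) < 2:
        raise ValueError(f"need >= 2 conformers to compute ensemble statistics, got {len(ensemble)}")
    ref_idx = _reference_index(ensemble)
    ref = ensemble.conformers[ref_idx]
    rmsds = np.array(
        [
            0.0 if i == ref_idx else svd_rmsd(c.coords, ref.coords)
            for i, c in enumerate(ensemble.conformers)
        ]
    )
    others = np.delete(rmsds, ref_idx)
    steps = walk_steps(rotatable_bond_count(ensemble.molecule))
    return SimilarityReport(
        reference_id=ref.conf_id,
        reference_index=ref_idx,
        rmsds=rmsds,
        mean=float(others.mean()),
        sd=float(others.std(ddof=0)),
        rmsd_min=float(others.min()),
        rmsd_max=float(others.max()),
        steps=steps,
    )


def normal_walk_reduce(
    ensemble: Ensemble,
    size_threshold: int = SIZE_THRESHOLD,
    variant: str = "binned",
) -> Ensemble:
    """Remove redundant conformers from an oversized ensemble.

    Ensembles of ``size_threshold`` or fewer members are returned unchanged.
    Otherwise the reference-RMSD range [min, max] is partitioned into
    ``walk_steps(ROT)`` intervals — equal-width by default
    (``variant="binned"``); with ``variant="quantile"`` the interval edges
    sit at quantiles of the fitted normal distribution N(mean, sd), so walk
    positions concentrate where the RMSD density is highest. Each occupied
    interval keeps exactly its lowest-energy member (tie → lowest input
    index); everything else at that walk position is removed as falling
    below the position's similarity score. The reference conformer is always
    retained and input ordering is preserved.
    """
    if variant not in ("binned", "quantile"):
        raise ValueError(f"unknown walk variant {variant!r}")
    if len(ensemble) <= size_threshold:
        return ensemble
    report = ensemble_rmsd_stats(ensemble)
    ref_idx = report.reference_index
    energies = [
        c.energy if c.energy is not None else float("inf") for c in ensemble.conformers
    ]

    if report.rmsd_max - report.rmsd_min <= 1e-12:
        logger.warning(
            "degenerate RMSD distribution (min == max == %.4f Å); keeping the "
            "reference and one representative",
            report.rmsd_min,
        )
        rep = min(
            (i for i in range(len(ensemble))),
            key=lambda i: (energies[i], i),
        )
        keep = sorted({ref_idx, rep})
        return Ensemble(
            molecule=ensemble.molecule,
            conformers=[ensemble.conformers[i] for i in keep],
            rank_label=ensemble.rank_label,
        )

    edges = _walk_edges(report, variant)
    n_bins = len(edges) - 1
    best_in_bin: dict[int, int] = {}
    for i in range(len(ensemble)):
        if i == ref_idx:
            continue
        b = int(np.clip(np.searchsorted(edges, report.rmsds[i], side="right") - 1, 0, n_bins - 1))
        cur = best_in_bin.get(b)
        if cur is None or (energies[i], i) < (energies[cur], cur):
            best_in_bin[b] = i
    keep = sorted({ref_idx, *best_in_bin.values()})
    return Ensemble(
        molecule=ensemble.molecule,
        conformers=[ensemble.conformers[i] for i in keep],
        rank_label=ensemble.rank_label,
    )


def _walk_edges(report: SimilarityReport, variant: str) -> np.ndarray:
    """Interval edges for the walk positions, trailing tail to leading tail."""
    if variant == "binned" or report.sd <= 1e-12:
        return np.linspace(report.rmsd_min, report.rmsd_max, report.steps + 1)
    dist = norm(loc=report.mean, scale=report.sd)
    probs = np.linspace(dist.cdf(report.rmsd_min), dist.cdf(report.rmsd_max), report.steps + 1)
    edges = dist.ppf(probs)
    edges[0], edges[-1] = report.rmsd_min, report.rmsd_max
    return edges
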