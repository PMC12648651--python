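"""Collision-cross-section prediction and reference-focused filtering.

Every conformer in an ensemble gets a predicted CCS through the
:class:`CCSPredictor` contract, and only conformers whose prediction lands
inside an accuracy-derived window around the user's experimental reference
CCS are kept — the surviving set is a conformational space *focused* on the
measurement. The built-in predictor is the orientation-averaged projection
approximation (PA): the mean projected area of the union of atom-centered
disks with gas-probe-inflated van der Waals radii, estimated by seeded
Monte-Carlo sampling. Trained CCS models plug in through the same contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from ._elements import vdw_radius
from .chem_core import Conformer, Ensemble, Molecule, write_xyz

logger = logging.getLogger(__name__)

__all__ = [
    "N2_PROBE_RADIUS",
    "DEFAULT_PREDICTOR_ACCURACY",
    "FINAL_OUTPUT_MAX",
    "PACCSResult",
    "pa_ccs",
    "pa_ccs_detail",
    "CCSPredictor",
    "ProjectionAreaPredictor",
    "FocusConfig",
    "FocusResult",
    "focus_filter",
]

#: Effective radius added to every atomic vdW radius for the N2 buffer gas, Å.
N2_PROBE_RADIUS = 1.55

#: Fractional 1-sigma relative error assumed for the built-in predictor; it
#: doubles as the default focus-window width (3%, the experimental-viability
#: scale of drift-tube CCS assignments).
DEFAULT_PREDICTOR_ACCURACY = 0.03

#: A focus ensemble at or below this size is an acceptable final output.
FINAL_OUTPUT_MAX = 50


@dataclass
class PACCSResult:
    """Monte-Carlo PA estimate: mean projected area and its standard error
    across orientations (Å²)."""

    value: float
    stderr: float
    n_orientations: int

    def __float__(self) -> float:
        return self.value


def pa_ccs_detail(
    elements: Sequence[str],
    coords: np.ndarray,
    n_orientations: int = 64,
    n_points: int = 4096,
    probe_radius: float = N2_PROBE_RADIUS,
    seed: int = 0,
) -> PACCSResult:
    """Orientation-averaged projected area of the union of probe-inflated
    vdW disks (the projection approximation to the CCS).

    For each of ``n_orientations`` seeded uniform random rotations the atom
    centers are projected onto a plane and the union area of the disks is
    estimated by rejection sampling with ``n_points`` uniform points over
    the disks' bounding box. Returns the mean over orientations with its
    standard error. Deterministic for a fixed seed.
    """
    if n_orientations < 1 or n_points < 1:
        raise ValueError("n_orientations and n_points must be >= 1")
    coords = np.asarray(coords, dtype=float)
    radii = np.array([vdw_radius(e) + probe_radius for e in elements])
    if coords.shape != (len(radii), 3):
        raise ValueError(f"coords shape {coords.shape} does not match {len(radii)} atoms")
    rng = np.random.default_rng(seed)
    areas = np.empty(n_orientations)
    for o in range(n_orientations):
        rot = _uniform_rotation(rng)
        xy = (coords @ rot.T)[:, :2]
        lo = (xy - radii[:, None]).min(axis=0)
        hi = (xy + radii[:, None]).max(axis=0)
        box_area = float(np.prod(hi - lo))
        pts = rng.uniform(lo, hi, size=(n_points, 2))
        d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        inside = (d2 <= radii[None, :] ** 2).any(axis=1)
        areas[o] = box_area * inside.mean()
    stderr = float(areas.std(ddof=1) / np.sqrt(n_orientations)) if n_orientations > 1 else float("nan")
    return PACCSResult(value=float(areas.mean()), stderr=stderr, n_orientations=n_orientations)


def pa_ccs(
    elements: Sequence[str],
    coords: np.ndarray,
    n_orientations: int = 64,
    n_points: int = 4096,
    probe_radius: float = N2_PROBE_RADIUS,
    seed: int = 0,
) -> float:
    """Scalar convenience wrapper around :func:`pa_ccs_detail` (Å²)."""
    return pa_ccs_detail(elements, coords, n_orientations, n_points, probe_radius, seed).value


def _uniform_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform rotation matrix via a normalized Gaussian quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


@runtime_checkable
class CCSPredictor(Protocol):
    """Prediction contract: positive CCS in Å², deterministic for a fixed
    seed, plus an ``accuracy`` attribute (fractional 1-sigma relative error)
    that parameterizes the focus window."""

    accuracy: float

    def predict(self, conformer: Conformer) -> float: ...


@dataclass
class ProjectionAreaPredictor:
    """PA-based CCSPredictor bound to one molecule's element list.

    Every ``predict`` call reuses the same seed, so predictions are a pure
    function of the geometry and filtering is idempotent.
    """

    molecule: Molecule
    probe_radius: float = N2_PROBE_RADIUS
    n_orientations: int = 64
    n_points: int = 4096
    seed: int = 0
    accuracy: float = DEFAULT_PREDICTOR_ACCURACY
    last_stderr: float = field(default=float("nan"), init=False, repr=False)

    def predict(self, conformer: Conformer) -> float:
        res = pa_ccs_detail(
            self.molecule.elements,
            conformer.coords,
            n_orientations=self.n_orientations,
            n_points=self.n_points,
            probe_radius=self.probe_radius,
            seed=self.seed,
        )
        self.last_stderr = res.stderr
        return res.value


@dataclass
class FocusConfig:
    """Reference CCS and the relative window that defines viability.

    window_fraction defaults to the predictor's accuracy when left None:
    a conformer survives when |CCS_pred − CCS_ref| ≤ window_fraction·CCS_ref.
    """

    ccs_ref: float
    window_fraction: float | None = None
    final_output_max: int = FINAL_OUTPUT_MAX

    def __post_init__(self) -> None:
        if self.ccs_ref <= 0:
            raise ValueError(f"ccs_ref must be positive, got {self.ccs_ref}")
        if self.window_fraction is not None and not (0 < self.window_fraction < 1):
            raise ValueError(
                f"window_fraction must be in (0, 1), got {self.window_fraction}"
            )


@dataclass
class FocusResult:
    """Focused ensemble plus the per-conformer prediction table and, when
    nothing survived, a structured advisory telling the user how to
    backtrack."""

    ensemble: Ensemble
    table: pd.DataFrame
    advisory: str | None = None


def focus_filter(
    ensemble: Ensemble,
    predictor: CCSPredictor,
    focus: FocusConfig,
    out_dir: str | Path | None = None,
) -> FocusResult:
    """Annotate every conformer with a predicted CCS and keep those inside
    the focus window around the reference.

    Input order is preserved and the operation is idempotent. An empty
    result is not an error: it returns an empty ensemble together with an
    advisory to regenerate with a much larger conformer target. Predictor
    failures drop the affected conformer with a warning. With ``out_dir``
    set, survivors are written under ``<out_dir>/opt_Rank[n]_focus/`` next
    to a ``ccs_pred.csv`` sidecar listing every prediction and its kept
    flag.
    """
    if len(ensemble) == 0:
        raise ValueError("cannot focus an empty ensemble")
    window = focus.window_fraction if focus.window_fraction is not None else predictor.accuracy
    half_width = window * focus.ccs_ref
    rows = []
    kept: list[Conformer] = []
    for conf in ensemble:
        try:
            pred = float(predictor.predict(conf))
        except Exception as exc:
            logger.warning("CCS predictor failed on %s: %s", conf.conf_id, exc)
            continue
        conf.ccs_pred = pred
        keep = abs(pred - focus.ccs_ref) <= half_width
        rows.append({"conf_id": conf.conf_id, "ccs_pred": pred, "kept": keep})
        if keep:
            kept.append(conf)
    table = pd.DataFrame(rows, columns=["conf_id", "ccs_pred", "kept"])
    focused = Ensemble(
        molecule=ensemble.molecule, conformers=kept, rank_label=ensemble.rank_label
    )
    advisory = None
    if not kept:
        advisory = (
            f"no conformer fell within ±{window * 100:.1f}% of the reference CCS "
            f"{focus.ccs_ref:.1f} Å²; regenerate with num_of_conf >> 1000 to widen "
            "the sampled conformational space"
        )
        logger.warning("%s", advisory)
    if out_dir is not None:
        folder = Path(out_dir) / f"opt_Rank{ensemble.rank_label}_focus"
        folder.mkdir(parents=True, exist_ok=True)
        for idx, conf in enumerate(focused):
            write_xyz(ensemble.molecule, folder / f"conf_{idx}.xyz", conformer=conf)
        table.to_csv(folder / "ccs_pred.csv", index=False, float_format="%.4f")
    return FocusResult(ensemble=focused, table=table, advisory=advisory)
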