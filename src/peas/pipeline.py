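"""End-to-end orchestration and ensemble evaluation.

One call runs the full chain with no user intervention between stages:
titratable-site enumeration → charge-model ranking → per-rank conformer
generation → CCS focus filtering → normal-walk reduction of oversized focus
ensembles → Boltzmann-weighted CCS evaluation against the ≤3% viability
criterion. Outputs land in the canonical tree::

    <output_root>/<molecule name>/
        opt_Rank[n]_<site>.xyz
        results_sum.log
        Conformer/opt_Rank[n]_ensemble/
        Conformer/opt_Rank[n]_focus/
    <output_root>/<molecule name>.zip   (focus folders + log)
"""

from __future__ import annotations

import logging
import os
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ccs_focus import (
    FINAL_OUTPUT_MAX,
    FocusConfig,
    ProjectionAreaPredictor,
    focus_filter,
)
from .chem_core import Ensemble, Molecule, parse_smiles, read_xyz, write_xyz
from .confgen import GeneratorConfig, TorsionGridGenerator, generate_ensemble
from .normal_walk import normal_walk_reduce
from .protomer import (
    ADDUCT_DEPROTONATED,
    ADDUCT_PROTONATED,
    SurrogateScorer,
    build_charge_model,
    enumerate_sites,
    mole_fractions,
    rank_charge_models,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VIABILITY_THRESHOLD_PCT",
    "PipelineConfig",
    "RankResult",
    "EvaluationReport",
    "boltzmann_weighted_ccs",
    "ccs_percent_error",
    "run_pipeline",
    "write_results_log",
]

#: Maximum Boltzmann-weighted CCS error (percent) for an ensemble to count
#: as experimentally viable.
VIABILITY_THRESHOLD_PCT = 3.0

_ADDUCT_ALIASES = {
    "[M+H]+": ADDUCT_PROTONATED,
    "MH+": ADDUCT_PROTONATED,
    "M+H": ADDUCT_PROTONATED,
    "[M-H]-": ADDUCT_DEPROTONATED,
    "M-H-": ADDUCT_DEPROTONATED,
    "M-H": ADDUCT_DEPROTONATED,
}


def sanitize_name(name: str) -> str:
    """Whitespace becomes underscores; path separators are rejected."""
    if not name or not name.strip():
        raise ValueError("molecule_name must be non-empty")
    if "/" in name or "\\" in name or os.sep in name:
        raise ValueError(f"molecule_name must not contain path separators: {name!r}")
    return re.sub(r"\s+", "_", name.strip())


@dataclass
class PipelineConfig:
    """Everything a full run needs besides the chemical input itself."""

    molecule_name: str
    adduct: str
    ccs_ref: float | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    window_fraction: float | None = None
    final_output_max: int = FINAL_OUTPUT_MAX
    temperature: float = 298.15
    seed: int = 0
    output_root: str | Path = "Completed_Job"
    n_orientations: int = 64
    n_points: int = 4096

    def __post_init__(self) -> None:
        self.molecule_name = sanitize_name(self.molecule_name)
        key = self.adduct.strip()
        if key not in _ADDUCT_ALIASES:
            raise ValueError(
                f"unknown adduct {self.adduct!r}; expected one of {sorted(_ADDUCT_ALIASES)}"
            )
        self.adduct = _ADDUCT_ALIASES[key]
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")


@dataclass
class RankResult:
    """Per-rank outcome: ensemble sizes at each stage and the weighted-CCS
    evaluation (absent when no reference CCS was supplied or the focus
    ensemble came back empty)."""

    rank: int
    site_label: str
    mode: str
    relative_energy: float
    mole_fraction: float
    n_generated: int
    n_focused: int
    n_reduced: int
    weighted_ccs: float | None = None
    ccs_error_pct: float | None = None
    viable: bool | None = None
    advisory: str | None = None


@dataclass
class EvaluationReport:
    molecule_name: str
    adduct: str
    ccs_ref: float | None
    temperature: float
    ranks: list[RankResult] = field(default_factory=list)

    @property
    def any_viable(self) -> bool:
        return any(r.viable for r in self.ranks if r.viable is not None)


def boltzmann_weighted_ccs(
    ccs_values: Sequence[float], energies: Sequence[float], temperature: float = 298.15
) -> float:
    """Ensemble CCS as the Boltzmann average Σ w_i·CCS_i with weights from
    the conformer energies (kcal/mol) at the given temperature."""
    if len(ccs_values) == 0 or len(ccs_values) != len(energies):
        raise ValueError(
            f"need equal-length non-empty lists, got {len(ccs_values)} CCS values "
            f"and {len(energies)} energies"
        )
    w = mole_fractions(energies, temperature)
    return float(np.dot(w, np.asarray(ccs_values, dtype=float)))


def ccs_percent_error(ccs_calc: float, ccs_ref: float) -> float:
    """Unsigned percent deviation of a computed CCS from the reference."""
    if ccs_ref <= 0:
        raise ValueError(f"ccs_ref must be positive, got {ccs_ref}")
    return 100.0 * abs(ccs_calc - ccs_ref) / ccs_ref


def run_pipeline(
    chem_input: str | Path,
    config: PipelineConfig,
    generator=None,
    predictor_factory=None,
) -> EvaluationReport:
    """Execute the full sampling chain for one molecule.

    ``chem_input`` is a SMILES string or a path to an XYZ file. ``generator``
    and ``predictor_factory`` default to the built-in torsion-grid generator
    and the projection-approximation predictor; ``predictor_factory`` is
    called with the charged molecule and the run seed so each rank predicts
    with its own element list.
    """
    mol = _load_input(chem_input, config)
    root = Path(config.output_root) / config.molecule_name
    conf_dir = root / "Conformer"
    root.mkdir(parents=True, exist_ok=True)

    sites = enumerate_sites(mol, config.adduct)  # raises NoTitratableSiteError
    models = [build_charge_model(mol, s) for s in sites]
    scorer = SurrogateScorer()
    ranked = rank_charge_models(models, primary=scorer, secondary=scorer)

    generator = generator or TorsionGridGenerator()
    if predictor_factory is None:
        predictor_factory = lambda molecule, seed: ProjectionAreaPredictor(
            molecule,
            n_orientations=config.n_orientations,
            n_points=config.n_points,
            seed=seed,
        )

    scores = [m.best_score for m in ranked]
    rel = np.asarray(scores) - min(scores)
    fracs = mole_fractions(scores, config.temperature)

    report = EvaluationReport(
        molecule_name=config.molecule_name,
        adduct=config.adduct,
        ccs_ref=config.ccs_ref,
        temperature=config.temperature,
    )

    for model, rel_e, frac in zip(ranked, rel, fracs):
        write_xyz(
            model.molecule,
            root / f"opt_Rank{model.rank}_{model.site.label()}.xyz",
            conformer=model.geometry,
        )
        gen_cfg = GeneratorConfig(
            num_of_conf=config.generator.num_of_conf,
            rmsd_cutoff=config.generator.rmsd_cutoff,
            energy_window=config.generator.energy_window,
            torsion_grid_deg=config.generator.torsion_grid_deg,
            seed=config.seed + model.rank,
        )
        ensemble = generate_ensemble(model, gen_cfg, generator, out_dir=conf_dir)
        logger.info(
            "rank %d (%s): %d conformers generated", model.rank, model.site.label(), len(ensemble)
        )
        rank_res = RankResult(
            rank=model.rank,
            site_label=model.site.label(),
            mode=model.site.mode,
            relative_energy=float(rel_e),
            mole_fraction=float(frac),
            n_generated=len(ensemble),
            n_focused=0,
            n_reduced=0,
        )
        if config.ccs_ref is not None and len(ensemble) > 0:
            predictor = predictor_factory(model.molecule, config.seed)
            focus_cfg = FocusConfig(
                ccs_ref=config.ccs_ref,
                window_fraction=config.window_fraction,
                final_output_max=config.final_output_max,
            )
            focus_res = focus_filter(ensemble, predictor, focus_cfg, out_dir=conf_dir)
            focused = focus_res.ensemble
            rank_res.n_focused = len(focused)
            rank_res.advisory = focus_res.advisory
            if len(focused) > config.final_output_max:
                reduced = normal_walk_reduce(focused, size_threshold=config.final_output_max)
                _rewrite_focus_folder(model.molecule, reduced, conf_dir)
            else:
                reduced = focused
            rank_res.n_reduced = len(reduced)
            if len(reduced) > 0:
                ccs_vals = [c.ccs_pred for c in reduced]
                energies = [c.energy if c.energy is not None else 0.0 for c in reduced]
                weighted = boltzmann_weighted_ccs(ccs_vals, energies, config.temperature)
                err = ccs_percent_error(weighted, config.ccs_ref)
                rank_res.weighted_ccs = weighted
                rank_res.ccs_error_pct = err
                rank_res.viable = err <= VIABILITY_THRESHOLD_PCT
        report.ranks.append(rank_res)

    log_path = root / "results_sum.log"
    write_results_log(report, log_path)
    _package_zip(root, report, Path(config.output_root) / f"{config.molecule_name}.zip")
    return report


def _load_input(chem_input: str | Path, config: PipelineConfig) -> Molecule:
    text = str(chem_input)
    if text.lower().endswith(".xyz") or Path(text).exists():
        mol = read_xyz(text, name=config.molecule_name)
    else:
        mol = parse_smiles(text, name=config.molecule_name, seed=config.seed + 2024)
    return mol


def _rewrite_focus_folder(molecule: Molecule, reduced: Ensemble, conf_dir: Path) -> None:
    """Replace a rank's focus folder contents with the reduced survivors,
    leaving the ccs_pred.csv sidecar in place."""
    folder = conf_dir / f"opt_Rank{reduced.rank_label}_focus"
    for f in folder.glob("conf_*.xyz"):
        f.unlink()
    for idx, conf in enumerate(reduced):
        write_xyz(molecule, folder / f"conf_{idx}.xyz", conformer=conf)


def _package_zip(root: Path, report: EvaluationReport, zip_path: Path) -> Path:
    """Zip the focus folders plus results_sum.log with fixed timestamps so
    repeated runs produce byte-identical archives."""
    members: list[Path] = [root / "results_sum.log"]
    for rank_res in report.ranks:
        folder = root / "Conformer" / f"opt_Rank{rank_res.rank}_focus"
        if folder.is_dir():
            members.extend(sorted(folder.iterdir()))
    with zipfile.ZipFile(zip_path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for path in members:
            if not path.is_file():
                continue
            arcname = str(path.relative_to(root.parent))
            info = zipfile.ZipInfo(arcname, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, path.read_bytes())
    return zip_path


def write_results_log(report: EvaluationReport, path: str | Path) -> Path:
    """Plain-text results summary: one block per rank with stable field
    ordering and fixed numeric formats (so identical runs are
    byte-identical)."""
    lines = [
        "PEAS results summary",
        f"molecule: {report.molecule_name}",
        f"adduct: {report.adduct}",
        f"temperature_K: {report.temperature:.2f}",
        f"ccs_ref_A2: {report.ccs_ref:.4f}" if report.ccs_ref is not None else "ccs_ref_A2: none",
        "",
    ]
    for r in report.ranks:
        lines.append(f"Rank {r.rank}")
        lines.append(f"  site: {r.site_label} ({r.mode})")
        lines.append(f"  relative_energy_kcal_mol: {r.relative_energy:.4f}")
        lines.append(f"  mole_fraction: {r.mole_fraction:.6f}")
        lines.append(
            f"  conformers_generated/focused/reduced: {r.n_generated}/{r.n_focused}/{r.n_reduced}"
        )
        if r.weighted_ccs is not None:
            lines.append(f"  weighted_ccs_A2: {r.weighted_ccs:.4f}")
            lines.append(f"  ccs_error_pct: {r.ccs_error_pct:.4f}")
            lines.append(f"  viable_le_3pct: {'yes' if r.viable else 'no'}")
        if r.advisory:
            lines.append(f"  advisory: {r.advisory}")
        lines.append("")
    path = Path(path)
    path.write_text("\n".join(lines))
    return path
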