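# peas

Autonomous conformer-ensemble sampling for ion-mobility mass spectrometry
(IM-MS) structure assignment.

Assigning a gas-phase structure to an ion measured in a drift tube means
producing a small, diverse set of low-energy conformers of the right
protonation state whose computed collision cross-section (CCS) matches the
experiment. Doing that by hand — pick a charge site, generate rotamers,
screen thousands of geometries, deduplicate — is slow and irreproducible.
`peas` automates the chain for singly charged adducts of small molecules:

1. **Charge-site enumeration and ranking** — every titratable N/O of the
   neutral input becomes an [M+H]+ or [M−H]− charge model; a two-tier
   scorer ranks them (the secondary tier's ordering supersedes the
   primary's), and gas-phase mole fractions are reported per rank.
2. **Conformer generation** — a deterministic torsion-grid generator
   (pluggable contract) targets 1000 unique low-energy conformers per
   charge model, with similarity (RMSD ≥ 0.5 Å) and energy-window
   (50 kcal/mol) filtering.
3. **CCS focusing** — each conformer's CCS is predicted (built-in:
   Monte-Carlo projection approximation with N₂ probe radius 1.55 Å) and
   only conformers within an accuracy-derived window around the
   user-supplied reference CCS survive: |CCS_pred − CCS_ref| ≤ w·CCS_ref,
   w = 0.03 by default.
4. **Normal-walk reduction** — any focus ensemble with more than 50
   members is thinned by walking its reference-RMSD distribution in
   `steps = 20 × ROT` moves (ROT = rotatable-bond count) from minimum to
   maximum RMSD, keeping one lowest-energy representative per walk
   position. RMSDs are SVD/Kabsch superposed.
5. **Evaluation** — the surviving ensemble's Boltzmann-weighted CCS,
   `CCS_w = Σᵢ wᵢ·CCSᵢ` with `wᵢ ∝ exp(−ΔEᵢ/RT)`, is compared with the
   reference; the ensemble is *experimentally viable* when the error is
   ≤ 3%.

The trained components such a pipeline would use in production (a learned
site ranker, an ML potential, a neural CCS model, an external conformer
engine) are all represented by deterministic built-in surrogates behind
pluggable contracts (`SiteScorer`, `ConformerGenerator`, `CCSPredictor`) —
see `docs/methods.md` for exactly what the surrogates do and do not
emulate.

## Worked example

Glycine as its deprotonated adduct, with a reference CCS of 58.7 Å²:

```sh
peas run --input 'NCC(=O)O' --name glycine --adduct M-H- \
         --ccs-ref 58.70 --num-of-conf 50 --seed 1
```

prints

```
Rank 1 O4: 3 generated, 3 focused, 3 final  weighted CCS 58.4 Å², error 0.57% (viable)
Rank 2 N0: 3 generated, 3 focused, 3 final  weighted CCS 58.8 Å², error 0.10% (viable)
```

Rank 1 is the carboxylate deprotomer (site O4, the acidic proton): its
3-point torsion grid (one rotatable bond × 120° grid) all survives the 3%
focus window, and the Boltzmann-weighted CCS of the final ensemble misses
the reference by 0.57% — well inside the ≤3% viability criterion. Rank 2,
the N–H deprotomer, ranks behind it (relative surrogate score
+28 kcal/mol, mole fraction ≈ 0) but is also CCS-viable. The full per-rank
record lands in `Completed_Job/glycine/results_sum.log`, per-stage
geometries in `Completed_Job/glycine/Conformer/opt_Rank[n]_{ensemble,focus}/`,
and the final focus folders plus log are packaged as
`Completed_Job/glycine.zip`. Re-running with the same seed reproduces every
output byte-for-byte.

The same run is three lines of library code:

```python
from peas import PipelineConfig, run_pipeline
report = run_pipeline("NCC(=O)O", PipelineConfig(
    molecule_name="glycine", adduct="M-H-", ccs_ref=58.70, seed=1))
```

Two further subcommands expose single stages: `peas ccs <xyz>` (projection-
approximation CCS of one geometry) and `peas reduce <folder>` (normal-walk
reduction of a folder of XYZ conformers).

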