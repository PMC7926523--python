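# Methods

This note records the models, conventions and numerical choices behind
`vsfunnel`, what the synthetic generators do and do not emulate, and the
known limitations.

## Funnel model and assumptions

The package models virtual screening as a monotone funnel: four independent
filters applied in sequence, each a pure function from a compound library to
a sub-library. Docking itself is treated as an external boundary — the
consensus stage consumes per-program score CSVs and never evaluates a
scoring function. This matches how multi-program campaigns are actually run
(each engine is a separate, often proprietary, executable) and makes the
pipeline testable end-to-end with synthetic score tables.

## Stage conventions

**Standardization** (`chemio`). Largest covalent fragment, charge
neutralization where a neutral form exists, explicit hydrogens; records that
cannot be standardized are dropped and logged, never repaired. Tautomer and
stereoisomer enumeration and pKa-based protonation are out of scope.
Conformers come from distance-geometry embedding (ETKDG) with force-field
relaxation (MMFF), seeded and bitwise reproducible; 10 conformers per
compound by default — a middle-of-the-road ensemble size for flexible
drug-like molecules, configurable where it matters.

**Descriptors** (`descriptors`). MW is the average molecular weight; TPSA
the fragment-contribution scheme; logP the atomic-contribution (Crippen)
scheme; rotatable bonds exclude amide and ring bonds. HBD/HBA use the
rule-of-five group convention — HBD = number of N/O atoms bearing ≥1 H,
HBA = N + O count — so water counts one donor group and one acceptor. One
convention is fixed for both the envelope and the Lipinski check because
mixing donor/acceptor definitions across stages silently shifts envelope
boundaries. Envelope membership is closed (`min ≤ x ≤ max`), matching how
inclusive active-property ranges are quoted.

**Similarity** (`similarity`). The 166 structural keys follow the public
MDL-style definitions as shipped by RDKit; the dialect string
`rdkit-maccs-166` is recorded on every hit because vendor dialects differ
and cross-dialect Tanimoto values are not comparable. The threshold is
applied as ≥ 0.85. Ties in best-query attribution are broken by query list
order. The Tanimoto of two empty key sets is defined as 0.

**Pharmacophore** (`pharmacophore`). Feature perception is rule-based
(SMARTS anchors; ring and hydrophobe features at centroids). The default
tolerance radius is 1.5 Å — a conventional pharmacophore sphere size; the
pairwise edge tolerance in matching is the *sum* of the two radii. Matching
is a largest-clique search on the correspondence graph (exact, via
`networkx.max_weight_clique`; model sizes are ≤ 8 so runtime is trivial).
Because only pairwise distances are compared, matching is rigid-motion
invariant but also accepts mirror images — a documented limitation of any
distance-only acceptance region. "At least `min_match` features" counts any
subset of model features; requiring specific kinds is possible by raising
`min_match` or screening with a reduced model. Overlay model construction
clusters same-kind features by single linkage with link distance 2× the
default radius, keeps clusters supported by ≥ 75 % of the molecules, and
inflates the radius to the cluster RMS spread when that exceeds the default.
The alignment of the overlay is the caller's responsibility; stochastic
flexible alignment is out of scope, so tests use constructively aligned
feature clouds.

The bundled six-feature structure-based model carries *synthetic* geometry:
the feature census (3 HYD, 1 HBD, 1 HBA, 1 CAT, match ≥ 4) mirrors the
campaign-derived model, but the coordinates are plausible binding-site-scale
placements, because the source crystal complexes are external data.

**Consensus** (`consensus`). Ordinal ranking with lexicographic id
tie-break (published tables show strictly distinct ranks, so tie handling is
an artifact-level decision). A compound missing from any program's table is
excluded from consensus and logged — the conservative reading of how docking
failures propagate. Note that in the bundled reference hit table the printed
(rounded) scores and the printed ranks are not perfectly order-consistent
within every program; the package treats the ranks as authoritative.

**Enrichment** (`enrichment`). Depths are counts, not percentages
(percentage depths floor to a count, avoiding rounding ambiguity). The AUC
is the rank-sum (Mann–Whitney) estimator with ties counting ½, which is
exact under ties, rather than a trapezoid on thresholded ROC points; ROC
points are still exported for plotting. The ideal-EF convention: the
reference round values (100/20/10 at 1/5/10 % of a 10,000-compound library
with 42 actives) treat the library size as the nominal 10,000; with the
literal 10,042-compound union the same depths give 100.42/20.08/10.04. The
`ideal_n_total` override in `enrichment_report` exists exactly for this, and
the default uses the actual outcome size.

**Energetics** (`energetics`). ΔG_bind = G_complex − G_protein − G_ligand;
components VDW + EEL + EPB + ENPOLAR + EDISPER. EDISPER defaults to 0
because summary tables commonly omit it. Standard deviation is sample
(n−1) by default and configurable (`ddof`), since published tables rarely
state their convention. Whether components are frame-averaged before or
after summation is immaterial by linearity — asserted as a test invariant.

**Trajectory metrics** (`traj_metrics`). Cα-only with unit masses
(configurable); mass weighting changes Rg by < 1 % for proteins and is not
worth the bookkeeping by default. RMSF references the mean structure after
one superposition refinement pass (superpose onto frame 0 → mean →
re-superpose onto mean → final mean); further iteration changes values
below numerical noise for equilibrated trajectories. Kabsch uses SVD with a
determinant correction so reflections are never introduced. Chain ids are
carried so per-chain RMSF of a dimer can be reported.

## Synthetic generators: what they emulate, what they do not

`synthetic` replaces every external input with a seeded, pure generator:

* **Libraries** come from a fixed fragment grammar (8 scaffolds × 12 × 12
  substituents) chosen so that ≈ 94 % of assembled molecules fall inside the
  reference descriptor envelope. This emulates a drug-like vendor subset's
  *property distribution*, not its chemical diversity: the grammar spans a
  few hundred distinct scaffolded series, not millions of compounds.
* **Planted actives** are random small structural edits (F/Cl/CH₃/OH
  attachments) of the query compounds; edit depth controls expected
  similarity. At depth 1 nearly all planted actives stay above 0.85
  Tanimoto to their parent. Real actives are not single-edit relatives of
  each other, so passing the recovery tests shows the plumbing is correct,
  not that the screen would find novel chemotypes.
* **Score tables** are Gaussian-shift: decoys ~ N(μ, σ), actives
  ~ N(μ−δ, σ), independent across programs (defaults μ=−7, σ=1, δ=2 on a
  docking-like kcal/mol scale). The closed form AUC = Φ(δ/(σ√2)) makes the
  enrichment machinery exactly checkable. Real docking scores are neither
  Gaussian nor independent across programs.
* **Trajectories** are a fixed coil plus per-frame isotropic jitter plus a
  random rigid motion; frame 0 is unperturbed, so RMSD against the default
  reference has expectation σ√3 and the rigid motion must cancel exactly.
  There is no physics here — the generator validates the metrics, not
  dynamics.
* **Energy frames** draw each component independently from N(true, σ);
  totals are consistent per frame by construction.

The default validation design — 10,000 decoys, 42 planted actives, four
programs — mirrors the modeled campaign's decoy-embedding experiment.

## Problem sizes

The test suite exercises libraries of 100–500 compounds, score tables of
10,000–10,042 entries, trajectories of up to 100 frames × 200 positions, and
10,000-frame energy series; these sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances while keeping the full suite in
the tens of seconds. Brute-force oracles (all-pairs similarity, exhaustive
pharmacophore assignment, set-intersection consensus) are run on inputs
small enough for exact enumeration.

## Known limitations

* No docking, no force fields, no PB solver — scores and energies are
  consumed, never computed.
* Mirror-image pharmacophore matches are accepted (distance-only matching).
* The 166-key dialect is pinned to RDKit's; values are not comparable to
  other vendors' dialects.
* The bundled structure-based model's geometry is synthetic; screening
  results against it characterize the matcher, not the real binding site.
* Fingerprint-based screening of the synthetic library inherits the
  grammar's limited scaffold diversity; enrichment numbers on synthetic
  data are oracle checks, not performance claims about real screens.
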