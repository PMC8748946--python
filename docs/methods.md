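# Methods

## Per-residue dissimilarity

All receptor conformations are superposed onto an explicit reference by a
rigid-body least-squares (Kabsch) fit of their shared backbone atoms
(N, CA, C, O over the whole chain where available).  The reference is a
required parameter: nothing in the procedure makes one member canonical,
and the choice affects coordinates only through a common rigid motion, to
which all downstream quantities are invariant.

In the common frame, residue *k* of members *i* and *j* is compared by
heavy-atom RMSD with **no per-residue re-fitting**, so rigid displacement
of one residue against the rest of the pocket counts in full.  Atom
correspondence is the intersection of heavy-atom names present in all
members for that residue, sorted by name; members losing atoms to the
intersection trigger a warning, and an empty intersection is an error.
Side-chain label symmetry (PHE/TYR CD1–CD2, ASP OD1–OD2, GLU, ARG) is
**not** corrected: a ring flip renames atoms and can register as
dissimilarity.  This is the naive reading of the per-residue RMSD
definition, and a documented limitation.

The summed matrix T (Å) accumulates all K per-residue RMSDs; the count
matrix N counts residues strictly above the cutoff (default 2 Å, the
conventional structural-identity threshold).  The comparison is strict —
Θ(0) = 0 — so a residue sitting exactly at the cutoff does not count and
a pair with N = 0 is redundant.  That convention is forced by the
adjacency definition: the redundancy graph must have an edge exactly when
N = 0, and the printed form of the adjacency formula (a Kronecker delta
*factor*) would zero every off-diagonal entry; the implementation follows
the stated intent, `A_ij = (1 − Θ(N_ij))(1 − δ_ij)`, which is traceless
and has edges at N = 0.

## Redundancy removal

The greedy selection repeatedly takes the node of maximum degree *in the
current graph* and deletes its closed neighborhood; when no edges remain,
the surviving isolated nodes are all selected.  The output is provably an
independent dominating set: selected receptors are pairwise
non-redundant, and every eliminated receptor is redundant with the
representative that removed it (recorded for provenance).  Degree ties
break toward the lexicographically smallest id — the procedure is
otherwise order-dependent — and node ids are sorted internally, so the
result is independent of input order.  An optional tie-break by best
(lowest) crystallographic resolution is available when metadata exists.
No optimality is claimed: greedy maximum-degree selection does not
minimise the dominating set, and the test battery logs (without
asserting) its size against the brute-force minimum on tiny graphs.

Ward clustering of T or N uses the Lance–Williams recursion on the
precomputed (non-Euclidean) dissimilarity matrix, pinned to one update
rule for determinism; different linkage implementations can produce
different trees on non-Euclidean input.  Which matrix to cluster is a
parameter.  Cluster representatives minimise the summed dissimilarity to
their cluster mates, ties again by id.

## Feature table

Docking energetics are consumed, never computed: the AutoDock4 DLG parser
reads every `DOCKED: USER` run block and keeps the run with the lowest
estimated free energy of binding (equivalently, the lowest-energy member
of the top-ranked cluster, since clusters are ranked by lowest energy).
Line-to-term mapping: VHD ← "vdW + Hbond + desolv Energy" (the
intermolecular sum), ELC ← "Electrostatic Energy", TOR ← "Torsional Free
Energy", INT ← "Final Total Internal Energy", total ← "Estimated Free
Energy of Binding".  Which intramolecular pieces a given AutoDock build
folds into which printed line varies; the fixtures document the mapping
this parser assumes.

Inhibition constants convert to free energies as ΔG = RT ln Ki with
R = 1.9872×10⁻³ kcal/(mol·K) and T = 298.15 K by default (the temperature
is a parameter; assay temperatures are rarely reported).  Only
equality-relation affinity records are accepted; inequality rows are
dropped and counted in the log.  The feature grid must be complete —
failed dockings are a hard error rather than silently imputed, since the
learning stage assumes a full ligand × receptor grid.  Feature columns
follow the `<receptorID>_<TERM>` convention, 4R receptor-dependent
columns plus 8 descriptors (MW, ALP, PSA, NHA, NHD, NRB, NAR, NNH).

## Scenarios and metrics

Ensemble predictions aggregate per-receptor total scores as the mean or
the minimum per ligand; "best affinity" means most negative ΔG, making
"min" literal in free-energy units.  The enrichment-factor top set holds
the k = max(1, ⌊x·n/100⌋) strongest-affinity ligands (the floor is logged;
with 202 ligands and x = 20 the paper-scale set would be 40), ties broken
by ligand id so every report is deterministic.  Zero-variance score
vectors yield NaN correlations with a warning rather than an error.
The pair scan computes its metric surfaces with vectorised formulas that
the unit tests pin against the scalar scipy-based path.

## Random forest

The forest is an explicit bagging loop over scikit-learn regression
trees: each tree grows on a bootstrap sample (with replacement, same
size), considers `mtry` features per split and is capped at `maxnode`
leaves.  The in-bag mask of every tree is retained; the OOB prediction of
a sample is the mean over trees whose bootstrap excluded it, and samples
in every bootstrap are flagged and excluded from the OOB MSE.  Defaults
ntree = 500, maxnode = 80, mtry = 100: beyond ≈75 leaves both OOB and
test error become insensitive to tree depth, leaving mtry (50–100
reasonable) as the one effective hyperparameter.  When a model uses fewer
than `mtry` features (a top-k model has only 4k+8 columns), mtry is
clamped with a warning, matching R randomForest.

Permutation importance permutes one OOB column per (tree, feature) with a
seed derived from (forest seed, tree index, feature index) — one
permutation per pair, so the whole table is a pure function of (forest,
data).  The scaled measure divides the per-tree mean error increase by
the per-tree standard deviation; zero-sd features (e.g. constants) are
reported unscaled and flagged.  Impurity importance accumulates weighted
node-variance decreases per feature, normalised per tree; a feature never
split on scores exactly 0.  The scaled permutation measure is the primary
receptor-ranking signal (impurity importance is diagnostic; whether to
sum scaled or raw values per receptor is a switch, scaled by default).
Importance averaging over repeats re-seeds the forest on the full data
set; it does not re-split the data.

Receptor ranking sums importance over each receptor's four term features
only — descriptors are receptor-independent and never enter the sums.
Top-k evaluation is leave-one-out: one forest per held-out ligand, each
re-seeded deterministically from the base seed and the ligand index, with
per-forest OOB MSE and per-ligand errors retained.

## Synthetic generators

`gen_ensemble` plants redundancy groups: one base conformation per group
(a shared fold with the first `displaced_residues` binding-site residues
shifted by `displacement` Å times the group index), members jittered by
isotropic per-coordinate noise σ_in.  The expected per-residue RMSD
between two jittered copies is σ_in·√6; the spec validator requires a 5×
margin below the cutoff within groups and above it between groups, so the
redundancy graph is exactly a disjoint union of cliques by construction
and recovery is guaranteed, not probabilistic.  Defaults: groups (3,3),
K = 8 residues × 4 atoms, σ_in = 0.05 Å, displacement 5 Å, cutoff 2 Å.

`gen_table` plants an affinity signal: a latent true ΔG ~ U(−12, −6)
kcal/mol per ligand; the experimental target adds Gaussian noise
(sd 0.8 kcal/mol by default), making noise-sd² the irreducible error
floor of any regressor.  Informative receptors' VHD/ELC/INT are linear in
the latent ΔG (slopes 0.55/0.30/0.15) with per-feature noise
(sd 0.25 kcal/mol), and their total scores track ΔG with sd 0.4; decoy
receptors draw everything independently.  TOR is a per-ligand torsional
penalty, 0.2983 kcal/mol per rotatable bond, shared across receptors as
in the docking convention.  The informative-feature and score noise
levels were fixed once by design calibration: they are the signal
strength at which a forest on the informative features can reach the
noise floor to within the acceptance margin at 200 ligands, which pins
the realized signal-to-noise (reported as the fitted R² of the target on
the informative term features, ≈0.8 at defaults) and makes the
downstream recovery thresholds meaningful.  What the generator does *not*
emulate: correlated energy terms across receptors sharing a conformation,
heavy-tailed docking failures, activity cliffs, assay heterogeneity, and
any real force-field structure — so passing recovery tests demonstrates
the bookkeeping and the statistical machinery, not docking accuracy on
real complexes.

## Verification problem sizes

The shipped batteries run at desk scale: the bookkeeping identities use a
126-receptor table (7875 pairs, 504/512 features); selection is verified
by brute force on 150 random graphs of ≤12 nodes plus 100 planted-clique
ensembles; tensor and metric oracles use 10 random ensembles (n ≤ 8,
K ≤ 10) and 1000 random vector pairs; planted-receptor recovery uses 50
tables of 200 ligands × 30 receptors with forests of 300 trees, with the
top-3 leave-one-out check on the first of them; the learning-curve trend
battery uses a weak-signal table (feature and score noise sd 1.2) with
train fractions 0.1–0.6, 25 repeats and 60-tree forests, the
small-n/large-p regime in which the conservative OOB bias and the
improvement-with-data trend are expressed above split noise.  The OOB
bias is assessed on the median of per-split paired OOB − test
differences, which is far less noisy than comparing unpaired medians.

## Known limitations

- No side-chain symmetry correction in per-residue RMSD (see above).
- PDB reading keeps the first model and altloc "A"/blank only; occupancy
  is ignored.
- Greedy selection is deterministic but not minimum-cardinality.
- The DLG parser targets the AutoDock4 report layout; other versions may
  need a different line mapping.
- A boosted-trees learner is not bundled; the forest interface accepts
  alternative tree ensembles but no tuned defaults are provided.
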