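# Methods

This note documents the modelling choices, parameter defaults and
approximations behind `mutstab`, and what the shipped tests do and do not
demonstrate.

## Structures and mutant models

PDB files are reduced to the first model, highest-occupancy alternate
locations (ties resolved by file order), heavy atoms of the 20 standard
residues only; a small table maps common modified residues (MSE, SEP, …)
to their parents. Residues are addressed by author numbering plus
insertion code, matching the mutation-string convention `"A F7A"` (chain,
wild type, position, mutant; semicolons join double/triple mutants).

Mutant structures are built by **fixed-backbone idealised side-chain
substitution**: the mutated residue keeps N/CA/C/O (and CB, built at ideal
L-configuration geometry when absent), and the target side chain is grown
from a per-residue Z-matrix template (standard bond lengths/angles,
extended trans rotamer, approximate ideal ring geometry) via the
natural-extension reference frame. There is no energy minimisation and no
rotamer search — the construction is bit-reproducible and dependency-free,
at the cost of physical realism near the mutation site. This is a
deliberate approximation: pipelines that relax mutants with a molecular
modelling program will produce different (usually tighter) local geometry.

## Pharmacophore typing

Each heavy atom carries one or more of eight labels: Hydrophobic,
Positive, Negative, HAcceptor, HDonor, Aromatic, Sulphur, Neutral. The
per-atom table ships as `data/pharmacophore_table.tsv` and can be
overridden. Choices the literature leaves open, fixed here: histidine
side-chain nitrogens are Positive, HDonor and Aromatic (one fixed
protonation state, no pH dependence); aromatic carbons of Phe/Tyr/Trp are
also Hydrophobic while the polar imidazole ring carbons are not; atoms
matching no rule are Neutral; backbone N is a donor except in proline.
Only CYS SG and MET SD carry Sulphur.

## Cutoff-scanning signatures

The environment of a mutation set is every residue with ≥ 1 heavy atom
within `env_radius` (default 10 Å) of any heavy atom of a mutated residue.
For every unordered atom pair and every cutoff in the sweep (defaults
0–10 Å, step 2 Å, cumulative), each distinct unordered label-pair category
spanned by the two atoms' label sets is counted once: 36 categories × 5
bins. Distances equal to a cutoff count as inside (closed upper edge, with
a 10⁻⁹ Å tolerance so rigid transforms cannot flip a bin). Intra-residue
pairs are included; a pair of multi-label atoms contributes one count per
distinct category, not per label combination. The bin scheme and radius
are package defaults chosen to match typical published usage of
cutoff-scanning signatures; they are config-exposed, and no bit-level
agreement with any served tool is claimed. The implementation is verified
against a brute-force triple-loop enumeration by exact integer equality.

## Complementary features

* **Substitution deltas** over five committed physicochemical scales
  (Kyte–Doolittle hydrophobicity, residue volume, Grantham polarity,
  average flexibility, isoelectric point), mutant − wild type, exactly
  antisymmetric under exchange; plus BLOSUM62, PAM30, PAM70 and PAM250
  scores from Biopython. PAM70 stands in for the more common PAM120
  choice, which Biopython does not ship.
* **Solvent accessibility**: Shrake–Rupley with probe 1.4 Å and 960
  golden-spiral points per atom (240 in the fast pipeline default),
  normalised by theoretical per-residue maxima and clipped to [0, 1].
* **Residue depth**: mean distance of the residue's heavy atoms to the
  nearest accessible surface sample point — a surface-point approximation
  rather than a triangulated molecular surface. Interior cavities count as
  surface if the pairwise occlusion rule leaves them accessible.
* **Secondary structure**: 3-state torsion-window classifier — helix for
  φ ∈ [−90°, −30°] and ψ ∈ [−77°, −17°], strand for φ ∈ [−150°, −90°] and
  ψ ∈ [90°, 180°] ∪ [−180°, −170°], else coil; termini and residues with
  missing backbone atoms are coil. No hydrogen-bond analysis.
* **Contacts**: simplified distance + pharmacophore rules — H-bond at
  ≤ 3.5 Å (donor/acceptor), hydrophobic at ≤ 4.5 Å, ionic at ≤ 4.0 Å
  (opposite charges), aromatic at ≤ 5.0 Å, plus counts of polar and
  hydrophobic environment atoms within 5 Å. These replace a full
  interaction-typing program; thresholds are module constants.

Multi-mutant aggregation: delta-type features are summed over sites, site
descriptors averaged. Normalisation is per-column z-scoring with
population statistics fitted on training rows only (zero-variance columns
map to zero); the scaler is persisted as JSON inside the checkpoint.

## Network and loss

Each orientation's record is split into the signature block (3 × 36
channels × 5 bins: wild-type, mutant, difference) and the complementary
block. Sub-network: Conv1d stack over the bin axis (defaults 32→64
channels, kernel 3) → linear projection to the transformer width (64) →
pre-LN transformer encoder (1 layer, 4 heads) → mean-pool over bins;
complementary features through two dense layers (128, 64); concatenation
with a 32-dim linear projection of the raw inputs as the residual path;
dense head (64) → scalar. The identical sub-network is applied to forward
and reverse records; the served prediction is (f − r)/2, so swapping the
records negates the output exactly at any weights — anti-symmetry is
structural, not learned. The inference-time formula (f − r)/2 is implied
by the loss's error term; the anti-symmetry penalty |f + r| additionally
pushes the raw pair towards r = −f.

Loss: `logcosh((f − r)/2 − y) + |f + r|`, batch-averaged. log cosh is
computed as |x| + log1p(e^{−2|x|}) − log 2 (no overflow); the |·| kink
takes subgradient 0 at f = −r. Optimiser: Adam (lr 10⁻³), batch 64,
up to 100 epochs with early stopping on a held-out 10% validation split
(patience 10), dropout 0.1 on the fused representation during training.
All sizes are package defaults — the published architecture's tuned
hyperparameters are not public — and every block (conv, transformer,
dense-comp, head) can be ablated to a pass-through for ablation studies.
Training is deterministic given the seed.

## Dataset curation

Duplicates at (protein, mutation) level keep the record measured closest
to physiological conditions: smallest |pH − 7| first, then smallest
|T − 25 °C| (the ordering of the two criteria is this package's choice;
missing values rank last), remaining ties by input order. Blind-set
overlap removal drops training records matching a test record on both
protein identifier and mutation. Reverse augmentation adds, exactly once,
a mutant→wild-type record with negated ΔΔG for every forward record; the
augmented labels cancel pairwise. Folds: protein-level (shuffled proteins
greedily assigned largest-first to the lightest fold — forward/reverse
partners and all records of a protein share a fold) or mutation-level
(shuffled round-robin). Sign convention everywhere: ΔΔG ≥ 0 stabilising;
tables using the opposite convention are flipped with `--flip-sign`.

## Evaluation

Pearson, Spearman and Kendall tau-b via scipy; RMSE, MAE, and the mean
signed error (reported as `mse_signed`: in this field's tables "MSE"
denotes the signed bias, not mean squared error). Stratified reports split
by direction, sign of the true ΔΔG, and mutation multiplicity.
Anti-symmetry diagnostics report Pearson(f-predictions, r-predictions) and
the mean of f + r. Permutation importance shuffles one feature column
(jointly in the forward and reverse halves of a record, same permutation —
a permutation preserves the column's mean and variance exactly) and
reports the drop in Pearson correlation, averaged over 10 repeats by
default.

## Synthetic data and what the tests show

The fixture module generates ideal-geometry peptides (helix/strand at
chosen torsions), typed random atom clouds, geometric probes (spherical
cages, placed residue pairs), and labelled feature tables in which
y = coeffs · x + N(0, noise) with delta-type columns flipping sign between
orientations, so label anti-symmetry holds by construction. The study-
scale recovery experiment uses n = 2000, noise σ = 0.1, 1600/400 split.

Passing tests therefore demonstrate: exact agreement of the signature
implementation with its definition, structural anti-symmetry, loss and
gradient correctness, curation bookkeeping, and that the network can
recover a planted linear signal (held-out Pearson ≥ 0.9). They do **not**
demonstrate accuracy on experimental ΔΔG data: real benchmark performance
requires curated thermodynamic datasets, hundreds of PDB structures and
relaxed mutant models, all outside this repository's scope.

## Numerical and degenerate-input choices

Distances at bin edges use a 10⁻⁹ Å tolerance; constant vectors make
correlations NaN while error metrics are still reported; empty strata are
omitted; structures without ATOM records, unresolvable residues and
wild-type mismatches raise informative errors, and batch featurization
collects such mutations in a rejects list instead of aborting. Mutation
sets are limited to three substitutions (the validated regime); larger
entries are warned about and skipped by the CLI. Checkpoints (.npz) embed
the full model configuration and the feature scaler.
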