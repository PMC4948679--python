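# Methods

`cdrscore` implements the in-silico half of a simulation-assisted antibody
humanization workflow: given conformational ensembles of an antibody Fv
region (e.g. from replicate MD simulations), it quantifies how faithfully a
humanized variant reproduces the CDR loop conformations of the original
(murine) binder, and calibrates a binder/non-binder decision boundary from
measured dissociation constants.  The guiding assumption is conformational
selection: a variant whose CDR samples the same conformations as the known
binder is expected to retain binding, while the converse need not hold.

## Superposition and RMSD

All structural comparisons use a two-region protocol.  The **fit region**
— by default the backbone N/CA/C/O atoms of the two framework segments
flanking the loop (H:FR3 and H:FR4) — anchors a roto-translational
least-squares fit; the **RMSD region** — by default every atom of H:CDR3,
side chains included — is where the deviation is measured.  The optimal
rotation is the closed-form Kabsch solution (SVD of the weighted
covariance matrix) with the reflection branch forbidden by a determinant
sign correction.  Fits and RMSDs are unweighted by default; mass weighting
is available but not used anywhere in the default pipeline.  Geometry with
fewer than three fit atoms, or with collinear/coincident reference points
(second singular value below 1e-10 of the first), is rejected rather than
silently resolved.

Internal coordinates are in nanometres; PDB I/O converts to and from
Angstrom exactly once at the boundary.  Residue numbering is taken
verbatim from the input files ("author numbering"); no Kabat renumbering
is attempted — region ranges are user configuration.  Because the RMSD
region defaults to "all atoms", whether hydrogens enter the comparison is
decided by the input files; the synthetic fixtures are heavy-atom only.

## Reference extraction (clustering)

Wild-type frames are pooled across replicates (each replicate restricted
to its analysis window — by default the last 80% of frames, dropping the
start-structure-biased beginning — optionally strided) and a cross-RMSD
matrix is computed: each pair of frames is superposed on the fit region
and compared on the RMSD region.  Because fit and RMSD sets differ, the
two fit directions give minutely different values; the matrix is
symmetrized by averaging both directions.  Pairwise fitting (rather than
fitting everything to one reference frame) makes the matrix invariant to
frame order; the cost is O(N²) fits, mitigated by vectorizing the Kabsch
solve over batches of pairs and by the stride option.

Clustering uses the greedy neighbor-count algorithm standard in the MD
field: the frame with the most neighbors within the cutoff (default
0.2 nm; a frame is its own neighbor) becomes the central member structure
(CMS) of the next cluster, it and its neighbors are removed, and the
procedure repeats.  Ties in neighbor count are broken toward the lowest
pooled frame index — the published algorithm leaves this open, and a
deterministic rule is required for reproducibility.  Cluster extraction
order is non-increasing in cluster size and populations sum to one.

**Significant clusters.**  Scoring uses only clusters whose population
reaches a significance threshold, default 0.20.  The default reproduces
the canonical single-dominant-cluster situation (one cluster above ~50%,
the rest at or below ~15% → a = 1) without hard-coding `a`; it is
configurable for ensembles with several comparably populated basins.  If
no cluster reaches the threshold, the largest is kept with a warning
rather than failing.

## Similarity score

For a variant simulated in `s` replicates of `m` analysed configurations
each, with `a` significant wild-type CMS and a strictly increasing
threshold vector `c` of `n` entries (default (0.05, 0.10, 0.15, 0.20) nm,
spanning tight agreement up to the clustering cutoff):

    score = 100 / (s·m·a) · Σ_i Σ_j Σ_k Σ_x  1[ RMSD(x_j, CMS_i) ≤ c_k ]

Each configuration is fitted onto each CMS on the fit region and the RMSD
taken over the RMSD region.  The normalization divides by `s·m·a` but not
by `n`, so the ceiling is `100·n`; a `score/n` column on the familiar
0–100 scale is emitted alongside.  When replicates have unequal lengths
the implementation averages per-replicate partial scores (each normalized
by its own `m_j`), which reduces exactly to the formula above for equal
`m_j` and weights replicates, not frames, equally.

Variants share the CDR sequence by construction, so the RMSD-region atom
sets must match the wild-type CMS exactly; a mismatch is a hard error
unless the variant is explicitly flagged as a CDR mutant, in which case
the comparison falls back to the shared atoms with a warning.  Fit-region
(backbone) atoms map by residue position and are insensitive to framework
substitutions.

## Affinity processing and cutoff training

Measured dissociation constants are converted to binding free energies
against a 1 M standard state, ΔG = k_B·T·ln(K_d), with k_B = 0.0083145
kJ/(mol·K) and a default temperature of 293 K.  Filtering proceeds in
order: (1) measurements with sensorgram-fit R² ≤ 0.8 are discarded (the
boundary value is excluded, not kept); (2) ΔG values deviating more than
5.6 kJ/mol from the mean of the current set — exactly the free-energy
equivalent of a tenfold K_d change at 293 K — are removed iteratively,
one at a time, always the largest deviator first (removing all deviators
at once can over-exclude when a single extreme value drags the mean; ties
go to input order), stopping when nothing deviates or fewer than two
values remain; (3) a mean is reported only if at least three measurements
survive, otherwise the variant is flagged insufficient-data rather than
silently averaged.  K_d input requires explicit units (M, mM, µM, nM,
pM); an empty or `ND` entry marks a below-detection measurement and such
variants become non-binders in training.

The cutoff model is deliberately simple: if binder and non-binder scores
separate, the cutoff is the midpoint of the gap; otherwise the cutoff
minimizing misclassifications is chosen (ties toward the lower cutoff)
and the misclassified variants — e.g. a variant that binds despite a low
similarity score, a known failure mode when alternative binding modes
exist — are surfaced as inconsistencies rather than hidden.  At
classification time a score exactly at the cutoff is called non-binder,
the conservative choice for immunogenicity-driven design.  Variants with
insufficient affinity data are left out of training with a warning:
neither class label is supportable from censored evidence.

## Synthetic ensembles (what the generator does and does not emulate)

The generator builds an idealized peptide-like loop (two framework flanks
with backbone atoms, a central CDR segment with a dummy side-chain atom
per residue), places `B` basin conformations whose pairwise CDR RMSD is
*exact* (displacement fields are scaled orthonormal directions in
conformation space), and samples frames by drawing a basin per frame,
adding isotropic per-coordinate Gaussian jitter (separately controllable
on CDR and framework atoms), and optionally applying a random global
rigid motion.  Ground-truth basin labels are always returned; tests never
re-infer the truth they check.  All generators take explicit seeds.

This emulates what the analysis machinery sees — multi-basin loop
ensembles with controllable populations, spread and global motion — and
nothing else: there is no Ramachandran validity, no force field, no
correlated atomic fluctuations, no binding physics.  Passing tests
therefore demonstrate that the pipeline recovers the parameters of this
generative model (basin count, populations, similarity ordering, planted
affinity outliers), not that any particular antibody scores any
particular value on real trajectories.

Default study conditions used in the recovery checks: 12-residue loop
(4-residue flanks), two basins at weights 0.7/0.3, basin separation 3×
the 0.2 nm cutoff, CDR jitter 0.05 nm (cutoff/4), 1000 pooled wild-type
frames, jitter ladder σ ∈ {0.01, 0.05, 0.1, 0.2} nm at 300 frames × 2
replicates.  These sizes make every stage's statistics well-resolved
(binomial s.e. on populations ≈ 1.4 percentage points) while the full
pipeline completes in well under a minute.

## Numerical choices and limitations

- Distance-matrix symmetry tolerance 1e-9 nm; rotation determinant checked
  to 1e-9; PDB round-trip precision 1e-4 nm (fixed-width format).
- Clustering and cutoff tie-breaks are documented above; they are the only
  order-sensitive points of the pipeline (property-tested).
- The threshold vector, significance threshold and analysis window are
  study-level configuration, not fitted quantities; changing them changes
  the score scale, so scores are only comparable within one configuration.
- Binary trajectory formats (XTC/TRR/DCD) are not read; convert to
  multi-model PDB upstream.  Sequence panels must be positionally aligned
  (no indel handling).  Secondary-structure QC and germline-frequency
  analyses are out of scope.
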