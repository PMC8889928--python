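# Methods

## Scope and model

`allocomm` quantifies conformational coupling between residue groups
("bodies") of a protein from coordinate ensembles. Three layers:

1. **Geometry** — Kabsch least-squares superposition, per-frame RMSD of a
   measured selection after fitting a core selection, structure-vs-structure
   RMSD over matched residues, and loop-centroid displacement metrics.
2. **Information theory** — quasi-harmonic configurational entropy, mutual
   information (MI) between a transmitter and receiver body, co-information
   CI(T;R;X) of candidate channel residues, and min–max-normalized
   per-residue CI profiles.
3. **Synthetic ensembles** — generators with analytically known covariance
   and MI, which serve as the validation harness for layers 1–2.

### Quasi-harmonic approximation

Equilibrium fluctuations of the selected Cartesian coordinates are modelled
as multivariate Gaussian. This is exact for harmonic systems and for the
synthetic generators; for real MD data it is the standard NbIT construction
and ignores anharmonic and multimodal effects (see Limitations). Entropy is
H = ½ ln[(2πe)^d det Σ]; MI and CI reduce to log-determinant ratios of
covariance blocks. All log-determinants are computed as sums of
log-eigenvalues of the symmetrized covariance — never as raw determinants —
with eigenvalues clipped at a floor.

The conditional MI inside CI is expressed through marginal entropies,
MI(T;R|X) = H(TX) + H(RX) − H(X) − H(TRX), which is algebraically identical
to the Schur-complement (conditional covariance) route but reuses the same
eigen-machinery as every other term; the equivalence with the seven-term
entropy-sum expansion is tested to 1e-9 on exact covariances.

## Residue bodies and numbering

Bodies are ordered atom-index selections built from residue lists with an
atom-name filter, default {Cα, Cβ} — glycine naturally contributes only its
Cα. Residue numbers carry an explicit convention: *nascent* (with signal
peptide) or *mature* (without). The mature frame is canonical internally;
nascent input is converted by subtracting the signal-peptide offset
(default 19, the HER3 value). Selections are deterministic (ascending atom
index); missing residues raise unless explicitly allowed, and a present
residue missing a requested atom (crystallographic disorder) warns and
proceeds with what exists, recording the count.

In per-residue CI scans a candidate residue inside the transmitter or
receiver body (opt-in) is evaluated against that body *minus* the
candidate's own atoms, so no coordinate is counted twice; a candidate that
would empty a body is rejected.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| temperature | 310 | K | physiological simulation temperature; sets the nats→kcal/mol factor k_B·T = 0.616 kcal/mol per nat |
| eigenvalue floor | 1e-8 | Å² | joint covariances of ≥18 atoms over finite frames are near-singular; the floor regularizes log-determinants without measurably biasing well-conditioned directions |
| shrinkage | 0 (off) | fraction | optional shrinkage toward the diagonal for frame-starved estimates; required to bypass the rank-deficiency guard when frames < dimensions |
| superposition passes | 2 | — | iterative mean-structure fit on the fit selection before covariance accumulation removes rigid-body motion that would inflate apparent correlations |
| stride | 1 | frames | subsampling for long trajectories; the frames actually used are recorded in provenance |
| block-bootstrap length | n/50 | frames | MD frames are autocorrelated, so MI standard errors come from moving-block resampling rather than i.i.d. formulas |

Replicate handling: MI is estimated per trajectory and averaged; the
reported spread is the cross-replica standard deviation. Pooling frames
across replicas is available but not the default, since replica-to-replica
variation is the more honest error estimate for ~μs trajectories.
Normalization of per-residue CI profiles uses the joint min and max over
every residue of every condition supplied in one call, so profiles from
different conditions (e.g. apo vs nucleotide-bound) are directly comparable.

## Synthetic generators

**Gaussian bodies.** A joint covariance is constructed with unit-free
correlation ρ between matched coordinate pairs of different bodies (all
shared coordinates by default, or a chosen count), scaled by a base variance
of 0.25 Å² — ~0.5 Å positional fluctuations, typical of a well-ordered
pocket. Frames are i.i.d. draws (or AR(1) in time with the same stationary
covariance, to exercise the bootstrap path). MI between bodies is analytic:
−½ Σ ln(1−ρ²) over coupled pairs. Positive definiteness is checked at build
time; seeds are mandatory and there is no global random state.

**Elastic network.** An isotropic Gaussian network on the structure's atoms:
unit-stiffness springs (1 kcal mol⁻¹ Å⁻²) between all pairs within an 8 Å
cutoff, per-axis covariance k_BT/γ × Kirchhoff⁺, Kronecker-expanded to 3N.
The isotropic network's Kirchhoff matrix has exactly one zero mode per
connected component (uniform translation; rotations are not zero modes of
the isotropic form), removed by eigenvalue thresholding before
pseudo-inversion; disconnected contact graphs are rejected. The isotropic
flavor was chosen over the anisotropic one because the tests need only the
covariance structure, not directional normal modes — a documented
simplification. Synthetic topologies use an ideal α-helical Cα trace
(2.3 Å radius, 1.5 Å rise, 100°/residue) so sequential neighbours fall
within the cutoff, with Cβ atoms 1.53 Å radially outward.

**What the generators do not emulate:** force-field anharmonicity,
conformational substates/multimodality, solvent damping, and the slow
autocorrelation structure of real MD (the AR(1) option is a caricature).
Passing the validation suite therefore demonstrates estimator correctness
under the Gaussian model, not robustness to non-Gaussian MD data; applying
the quasi-harmonic estimators to strongly multimodal trajectories will
overestimate entropies.

## Numerical choices and degenerate inputs

- Superposition requires ≥3 non-collinear paired atoms; collinearity is
  detected from the second singular value of the centered, weight-scaled
  coordinates. The optimal-rotation subproblem is solved by the closed-form
  SVD route (via `scipy.spatial.transform.Rotation.align_vectors`), which
  guarantees a proper rotation (det +1).
- Weights in superposition must be non-negative with positive sum;
  unweighted is the default, mass-weighting is the caller's choice.
- The covariance estimator divides by n−1 and raises a rank-deficiency
  error when frames−1 < dimensions unless shrinkage is enabled. The raw
  sample covariance is stored; the eigenvalue floor is applied where
  eigenvalues are consumed, so a frozen ensemble reports an exactly zero
  covariance while its entropy remains finite.
- Degenerate min=max in profile normalization yields an all-zero normalized
  profile with a warning rather than a division error.
- A documented independence bound accompanies small MI estimates: under
  independence 2n·MÎ is asymptotically χ²(d_T·d_R), so estimates below the
  0.999 quantile / 2n are indistinguishable from sampling noise.

## Validation harness and problem sizes

The accuracy suite (tests and `scripts/acceptance.py`) runs at 50,000 frames
— enough for the plug-in MI bias d_T·d_R/2n (~4·10⁻⁴ nats at d=6+6) and the
sampling noise to sit far below the 2–5% relative-error checks, while the
whole suite completes in well under a minute:

- two-body Gaussian MI at ρ ∈ {0, 0.3, 0.5, 0.8}: relative error < 5%
  (observed ≲1%), ρ=0 within the χ² independence bound;
- sampled isotropic entropy within 2% of (d/2)·ln(2πe·σ²);
- Markov-chain T–X–R: CI(T;R;X) = MI(T;R) to 1e-9 on exact covariances,
  sampled estimate within 5%; independent bodies |CI| < 0.01 nats;
- 20-atom elastic network: sampled covariance within 5% Frobenius relative
  error of the analytic pseudo-inverse; inter-pocket MI within 5%;
- superposition: rigid-transform residual ≤ 1e-9 Å, symmetry to 1e-9, and
  optimality against a rotation-search oracle to 1e-3 Å.

## Design decisions that were genuinely open

- **RMSD reference frame** for trajectory series: frame 0 by default (the
  natural reading of "stability over a simulation" against the starting
  structure), with a mean-structure reference available.
- **Structure-vs-structure comparison** uses Cα only by default — the
  standard convention for whole-domain conformational comparison; the atom
  filter is caller-overridable and the matched-residue list is reported so
  sensitivity to the choice can be inspected.
- **Loop metrics**: "collapse"/"shift" phenomena are quantified as the
  displacement of the loop's Cα centroid from its reference position after
  core superposition, optionally projected on a caller-supplied axis for a
  signed, directional reading; no single published scalar defines these
  phenomena, so the metric is deliberately simple and transparent.
- **Chain handling**: selections default to all chains of the topology (the
  simulated systems of interest contain a single chain); an explicit
  chain-id filter is available.
- **MI averaging vs pooling**: replicate-average is the default and pooled
  frames an option, since either reading is defensible when a single MI
  value is quoted for a set of replicate trajectories.

## Known limitations

- Quasi-harmonic entropies are upper bounds for multimodal ensembles;
  no anharmonic corrections are implemented.
- No dihedral-space information theory, transfer entropy, or directed
  information.
- PDB insertion codes are rejected rather than resolved; mmCIF writing is
  not supported.
- The binary-trajectory adapter trusts the topology file's atom ordering;
  it converts mdtraj's nm to Å and performs no further sanitation.
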