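# Methods

## The cascade

pacsfit implements experiment-targeted parallel cascade selection: cycles of
(1) many short independent simulations from the current seed structures,
(2) scoring of every sampled conformation against the target low-resolution
data, and (3) selection of the next cycle's seeds. Selection is two-staged:
among the M best-scoring frames of the cycle, the N frames with the largest
Cα RMSD to the initial structure (RMSD_ini) become seeds. The score term
pulls toward the data; the RMSD_ini term supplies outward pressure so the
search does not stall near the start. No biasing force ever enters the
sampling itself, which is what makes the protocol agnostic to both the data
type and the simulation engine.

Cycle 0 is a preliminary run from the initial structure. The seed pool of
each cycle is the current cycle's frames only (not cumulative), keeping
memory bounded. All RMSDs are computed over Cα atoms with positional residue
correspondence; superposition uses the closed-form Kabsch solution with
reflections excluded.

Defaults: M = 20, N = 10, 10 replicas per cycle, 20 frames per replica,
30 cycles per unit, at most 1 extension unit. M, N, the replica count and
the unit length follow the protocol this implementation reproduces; the
frame-saving interval is a free choice (see "Pool depth" below).

### Stopping and model picking

The per-cycle best score (minimize convention: chi as-is, −CC for maps) is
examined **only at unit boundaries** (cycle 30, 60): a unit is always run to
completion before saturation is judged. Saturation onset is the earliest
cycle c from which the *total remaining* relative improvement,
(trace[c] − min(trace[c:])) / |trace[c]|, stays below a tolerance (default
0.02), witnessed by at least `saturation_window` (default 5) subsequent
cycles. Anchoring the window to the end of the trace, rather than sliding
it, prevents a transient stall from masquerading as saturation when the
score later resumes improving — with per-cycle stochastic traces such stalls
are common. The final model is the best frame of the saturation-onset cycle;
picking at the plateau onset rather than at the global score minimum is a
deliberate guard against overfitting, because with low-information data the
score can keep creeping down while the structure moves *past* the state that
generated the data. If a run exhausts its units without saturating, the last
cycle's best frame is returned with an explicit overfitting warning.

A consequence worth knowing: with very low-information targets the
saturation pick can be an earlier, slightly worse model than the best one
visited later in the run. The per-cycle trace table that every run writes
makes this visible, and the cumulative best model remains available
(`PacsState.best_overall`).

## Scoring functions

### SAXS

Theoretical curves come from the orientationally averaged Debye double sum
I(q) = Σ_ij f_i f_j sin(q r_ij)/(q r_ij) over scattering centers, computed
directly on the target's q grid (no interpolation enters the score). The
default representation is one unit-weight dummy bead per Cα; an all-atom
mode with constant per-element electron counts is available. Hydration-shell
and excluded-volume corrections are deliberately not modeled: they shift
absolute chi values but hardly affect the *ranking* of conformations at low
q, which is all the selection uses. Consequently chi values here are not
numerically comparable with CRYSOL's.

The discrepancy is the reduced chi with a closed-form optimal scale factor
mu = [Σ I_t I_m/σ²]/[Σ I_m²/σ²] and 1/K normalization. Only scale is fitted
(no constant subtraction). The fitting range defaults to q ≤ 0.3 Å⁻¹.
Sigma values below 1e−6 × max(I) are floored to that value so simulated
targets with vanishing ensemble spread at some q (e.g. exactly at q = 0,
where the Debye sum is scale-fixed) remain usable.

Simulated target data is built the way validation studies build it: run an
ensemble of L = 100 frames around the target state, compute each frame's
theoretical curve, and use the per-q mean as the target intensity and the
per-q sample standard deviation (ddof = 1) as σ(q).

### EM

Simulated maps deposit one isotropic 3-D Gaussian per atom (unit weight by
default). The kernel width follows FWHM = resolution, i.e.
σ_kernel = resolution/(2√(2 ln 2)); a Situs-pdb2vol-style convention
σ = resolution/(2√3) is selectable. The convention shifts absolute CC
slightly but not the ranking of conformations. The score is the plain
normalized voxel dot product over the full lattice — no thresholding or
masking.

Placement: the initial structure is fitted into the map once by rigid-body
search (density-centroid translation seed, 60 quasi-uniform orientation
seeds plus the identity placement, then derivative-free refinement of the
six rigid parameters; the result never scores below the identity placement).
During a cascade every frame is then scored under a *constant* placement:
frames inherit their seed's coordinate frame, global rotational drift of the
ensemble is self-penalized by CC and deselected, and the placement is
re-refined locally (no orientation re-seeding) around each cycle's best
frame to absorb slow residual drift. An earlier design that Kabsch-superposed
every frame onto the previous cycle's best pose was abandoned: superposing
two conformationally different structures rotates the *matched* domain out
of the density, and the chained re-posing lets "the wrong domain moved"
conformations score as well as the true motion.

Target maps for the built-in benchmark are generated at 1.0 Å voxels and
5 Å resolution with a 25 Å pad. The generous pad matters: density deposited
outside the lattice is lost from the model-map norm, and clipped norm
*raises* normalized CC, so an under-padded map actively rewards pushing
mobile parts out of the box (with a 10 Å pad, 19% of the closed toy state's
density falls outside the open state's map).

### Composite scoring

For simultaneous SAXS+EM targeting, each component score is z-normalized
against its distribution over the preliminary cycle and combined as a
weighted sum; the normalization constants are frozen at calibration so all
cycles are scored on one scale. A component with zero variance in the
preliminary ensemble carries no selectable information and is dropped with a
warning.

## The built-in sampler

The desk-scale sampler is Metropolis Monte Carlo on Cα beads under a
harmonic elastic network built from the seed's contacts within 10 Å. Rest
lengths equal the seed's distances, so each new seed re-centers the energy
surface — this re-referencing is what lets selection ratchet the structure
far from where it started while every individual simulation only fluctuates
locally, mirroring how the cascade behaves with unbiased MD.

Spring constants are sequence-separation dependent (in units of the
long-range constant, 1 per Å²): i,i±1 virtual bonds ×200, pairs within 4
residues ×60, all other contacts ×1. The stiff local terms pin bond lengths
(within a few percent; the test suite asserts ±15%) and
secondary-structure-like local geometry, leaving inter-domain motion as the
soft subspace. Uniform springs were tried first and rejected: they let
helices unwind and twist — deformations that are invisible to a 5 Å density
map and weakly visible to low-q SAXS but large in RMSD — so cascades "fit
the data" without approaching the target structure.

Each sweep proposes one Gaussian displacement per bead (0.3 Å scale)
followed by two collective trials along the seed network's three softest
normal modes (amplitude 1.3), all Metropolis-accepted at kT = 3 (spring
units). The collective moves are essential: single-bead moves alone move a
quasi-rigid domain diffusively, far too slowly for a 30-cycle budget.

The preliminary run can prepend a *boost* phase — collective-mode Metropolis
at an effective temperature 25× kT on the mode subspace (200 steps, snapshots
retained) — the desk-scale analogue of mode-amplified enhanced sampling,
used to seed hard searches with far-from-start conformations. If the network
Hessian has more than six near-zero modes (degenerate geometry), the boost
and the collective moves are disabled with a warning and plain bead MC
proceeds.

The sampler never changes atom count, ordering or identity, and consumes
only the RNG seed handed to it: every replica's stream is derived from
(master seed, cycle, replica), which makes whole runs bit-reproducible and
resume-from-checkpoint exact.

External engines plug in through a command template
(`{input}`, `{output}`, `{seed}`, `{steps}`) exchanging multi-model PDB;
frame-count and exit-status violations preserve the scratch directory.

## The synthetic benchmark

The two-state system is a 60-bead two-domain hinge protein: two helical arms
(radius 2.3 Å, rise 1.5 Å per bead, Cα spacing 3.8 Å) whose common axis
curves by 40° in the hinge-bend plane, joined at a hinge bead; the closed
state has arm 2 rotated 45° about the hinge (open/closed Cα RMSD 4.8 Å).
Determinism: the geometry plus a small seeded jitter is fully fixed by the
spec's RNG seed.

Each geometric choice counters a specific degeneracy found during design:

* *slim arms* — with thick arms, bending barely changes the distance
  distribution and SAXS cannot tell the states apart; slim arms also keep
  helical-phase errors (invisible at 5 Å) small in RMSD terms;
* *in-plane axis curvature* — a straight rod's density is axially symmetric,
  so a 5 Å map cannot see *which plane* the hinge opens in, and with equal
  straight arms it cannot even see *which arm* moved; the banana shape
  breaks both symmetries (it retains an approximate in-plane two-fold, which
  is why pose-recovery tests use asymmetric point clouds instead);
* *45° default hinge* — large enough for an unambiguous two-state signal
  (RMSD > 3 Å is asserted at generation), small enough that the moving arm
  never fully leaves the target map's density envelope, so the correlation
  retains a usable gradient along the whole path.

What the toy does **not** emulate: side chains, realistic secondary
structure, solvent and hydration-shell scattering, experimental noise
statistics, map anisotropy or segmentation artifacts. Passing the toy
recovery tests therefore demonstrates the correctness of the cascade logic,
scoring functions and their coupling — not that any specific real system
will converge, which depends on the engine's sampling physics.

## Pool depth and run sizes

20 frames per replica × 5 sweeps between frames (400 frames per cycle)
gives deeper per-cycle selection at the same Monte-Carlo cost as fewer,
longer-spaced frames, and measurably steadier convergence on the benchmark.
The acceptance runs use a single 30-cycle unit (no extension) with three
master seeds per data type; a full SAXS run takes ~50 s and an EM run
~100 s on one CPU, so the complete recomputation stays under ten minutes.

## Numerical choices

* Debye sum: exact sinc limits at q = 0 and i = j; O(n²) pair distances via
  `scipy.spatial.distance.pdist`.
* Gaussian deposition: separable 1-D factors within a 4σ support cube;
  single-atom integral accurate to 0.5% whenever the pad exceeds ~3σ.
* Trilinear map resampling (`scipy.ndimage.map_coordinates`, order 1),
  exact on linear fields; out-of-extent voxels are zero.
* Kabsch superposition via SVD with determinant correction (reflections
  forbidden); collinear point sets are rejected.
* Selection tie-breaks are fully deterministic: score then conformation id,
  and within the top-M set −RMSD_ini, then score, then id.
* PDB I/O through gemmi: altlocs resolved to highest occupancy (ties →
  first listed), HETATM excluded by default, residue numbers above 9999
  rejected on write. Map I/O through gemmi's MRC/CCP4 2014 reader/writer
  with axis order normalized to x, y, z; orthogonal cells only.
* Checkpoints carry full-precision coordinates (the PDB files written
  alongside are for humans), so a resumed run reproduces the uninterrupted
  trace exactly.

## Known limitations

* The built-in sampler is a coarse harmonic model: no torsional chemistry,
  no excluded volume beyond the network springs, no solvent. It exists to
  exercise the protocol at desk scale and to generate benchmark ensembles.
* In-vacuo SAXS and unit-weight density kernels mean absolute chi / CC are
  not comparable with CRYSOL / Situs outputs; trends and rankings are.
* The EM score's constant-placement scheme assumes the engine does not
  translate/rotate the system wholesale between frames (true of the
  built-in sampler; an external engine wrapper should remove global motion
  or rely on the per-cycle local re-fit).
* CC at 5 Å resolution is insensitive to deviations below roughly 2 Å, and
  low-q SAXS to considerably more; final-model accuracy is bounded by the
  information content of the data, not by the optimizer.
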