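# Methods

## The fate-choice circuit

Each ICM cell is reduced to one dimensionless variable x, read as its NANOG
level.  Production is a product of cooperative self-activation and
repression by the neighborhood mean field ⟨x⟩ (the cell included), with
first-order decay:

    dx/dt = α (1 + x^n)^m / [ (1 + x^n)^m + (⟨x⟩/K)^(2m) ] − x

The mean field stands in for secreted FGF4: NANOG-high neighbors raise
local ligand, activate ERK in the receiving cell and push its NANOG down —
an indirect lateral inhibition.  Time is measured in units of the protein
lifetime, which the agent-based layer identifies with one hour; x is
bounded by α along any trajectory started in [0, α].

Assumptions: deterministic dynamics (variability enters only through
division timing, inheritance jitter and geometry); no explicit GATA6, FGF4
or ERK variables; no intrinsic chemical noise.

**Default parameters.** n = m = 2 are the smallest cooperativities that
give a robust double-well structure.  α and K were fixed once by scanning
the (α, K) plane for the regime where the two-cluster reduction has exactly
two stable states and one unstable symmetric state, with the stable
high:low ratio at least 5.  The chosen defaults α = 5, K = 1 give stable
states at (0.147, 4.696) and its mirror, a saddle at (2.799, 2.799), and a
high:low ratio of ~32.  Identity thresholds are derived from this portrait:
PrE below (x_low + x_saddle)/2 ≈ 1.47, epiblast above
(x_saddle + x_high)/2 ≈ 3.75, DP in between, so the thresholds always
bracket the saddle.

**Phase-plane tools.** `find_equilibria` scans a 200×200 grid of the
two-cluster system for cells where both components change sign, polishes
candidates with a Newton-type solver, de-duplicates, and classifies
stability from the Jacobian spectrum (central differences, eps = 1e-6).
Eigenvalues with |Re λ| < 1e-8 are labeled "marginal" rather than silently
classified.  Nullclines are traced by bisection in the partner coordinate,
which is monotone through the shared field, so each branch is a single
ordered polyline.

**Integration.** The population circuit uses explicit Euler.  The dynamics
are strongly contracting near the attractors, so a fixed step of 0.01
(hours) keeps trajectories within [0, 1.05 α]; any excursion outside that
band raises a step-size error rather than propagating garbage.  The
integrator was validated against an adaptive Runge-Kutta oracle (relative
error < 1e-4 on a 6-cell system at dt = 2e-4; at dt = 0.01 the error is at
the 1e-3 level during transients, which is far below the biological effect
sizes studied here).

## The agent-based substrate

Cells are soft spheres of unit radius in 3D (a 2D mode constrains motion
to a plane).  Forces are pairwise along center lines: a linear spring
repulsion proportional to overlap inside contact, and a weak tent-shaped
adhesion between contact and 1.5× contact distance, zero at both edges so
the law is continuous.  A weak spring toward the live-cell centroid keeps
the aggregate compact; it exerts no net force on a single cell and
preserves the centroid.  Dynamics are overdamped (drag = 1), standard for
tissue-scale models at these Reynolds numbers; a step that would move any
cell more than a tenth of a radius raises a step-size error.

Division is event-driven: each cell carries a clock drawn as
mean_cycle · (1 + U(−j, +j)) with mean_cycle = 10 h and jitter j = 0.3.
Daughters appear at ±0.25 radii along a uniformly random axis, redraw their
clocks, and inherit the mother's x with multiplicative jitter
exp(N(0, 0.05²)) clipped to [0, α] — the symmetry-breaking seed for the
lateral-inhibition instability.  The signaling graph connects cells whose
center distance is below 1.5× the summed radii (self-loops always
included); `"global"` substitutes the complete graph, the
widely-diffusing-ligand limit.

A wild-type run starts from 2 founders, switches the circuit on when the
live count first reaches 8 cells (progenitors are then initialized at the
saddle level with log-normal jitter, sd 0.1), grows to a 27-cell ICM, and
relaxes a further 6 h with divisions off so that late-born cells commit.
Runs are pure functions of (config, seed); per-component streams are
derived from the master seed by stable label hashing.

## In-silico experiments

*Scaling* multiplies the target size (0.5× → 14 cells, 2× → 54).
*Chimeras* aggregate n ESC agents at circuit activation: ESCs are frozen at
the high-NANOG equilibrium, enter their neighbors' mean field, divide like
host cells, and count toward the epiblast compartment of the total
composition (but not toward the host target size).  *Ablation* fires the
first time the live host count reaches the trigger size and removes
round-half-away-from-zero (minimum one) of the chosen lineage uniformly at
random; `all` removes the fraction from each class, `random` ignores
identity.  Removed cells are marked dead and leave the graph and field.

Staged-ablation arms fix an absolute end time,
mean_cycle · (log2(target/founders) + 0.5) + relax_hours ≈ 48.5 h, shared
with their control arm.  This represents the fixed implantation deadline:
a perturbation applied later genuinely leaves less recovery time, which is
what degrades recovery from 100% lineage loss at late stages while 30%
losses are still fully compensated.  Without a shared deadline the circuit
always re-balances, because in this model commitment is an attractor basin,
not an irreversible switch.

Batch sizes: simulation-heavy comparisons use 100 seeds for wild-type and
0.5× scaling, 60 for 2× scaling, 40 per ablation arm and 12 per chimera
dose — chosen so batch-mean standard errors (≈1–2.5 percentage points) sit
well inside the 5–10-point comparison bands while the whole suite runs in
minutes on one CPU.

## Classification pipeline

*Z-decay correction* fits log-intensity ~ z per embryo and channel and
subtracts the slope component about the embryo's mean depth.  In `eb` mode
per-embryo slopes are shrunk toward their litter mean with normal-normal
precision weights: embryo precision is the inverse squared standard error
of its OLS slope, and the between-embryo variance is estimated by method
of moments (floored at zero, which collapses to the litter mean).  The
step is idempotent to within refit noise.

*Antibody harmonization* is an affine map fitted by least squares on
double-stained records.  *Per-litter rescaling* divides each channel by its
litter maximum, because staining intensity varies litter to litter and
litters are the experimental unit.

*UPGMA classification* clusters rescaled (NANOG, GATA6) with average
linkage on Euclidean distance — the metric is a package choice; the linkage
is the method's defining feature — after setting aside double-negative
cells (both channels < 0.1; rare, usually mitotic or dying).  The tree is
cut at k = 4 and each cluster takes the label of the nearest archetype
point (EPI (0.55, 0.12), PrE (0.12, 0.55), DP (0.5, 0.5), NANOG-lo
(0.18, 0.08)).  Nearest-archetype mapping deliberately allows several
clusters to share a label, so over-cutting a tight class is harmless.  Rows
are sorted by cell id before linkage, making the result order-invariant.

*Track classification* smooths GFP with a centered 4-frame moving average
(window spans [i−2, i+1]; shrinks at edges), interpolates the start/end
thresholds linearly across frames, and applies two rules: committed
identities are permanent, and a DP cell switches at the first frame of the
earliest run of ≥ 8 consecutive frames (2 h at 15-min spacing) beyond a
threshold.  Stamping the switch at the run's first frame (not its end) is a
package choice, configurable via the persistence parameter.  A track whose
first frame already sits beyond a threshold is committed from the start.

*Survival* uses the product-limit (Kaplan-Meier) estimator; the half-life
is the first time S(t) ≤ 0.5 (undefined if never reached) and its CI is
the median's 95% confidence interval.

*ESC stratification* bins a final ESC count into dyadic epiblast
equivalents anchored at the 5–10-cell control epiblast: [5,10] → 1x,
(10,20] → 2x, and so on.

## Synthetic data

The embryo-table generator emulates segmented-nucleus tables: identities
multinomial at the configured composition (default 40% EPI / 60% PrE, the
late-blastocyst ratio), depths uniform over an 80 µm stack, and log-normal
intensities with identity-specific locations (≥ 2 noise sd apart,
sd = 0.25), a −0.01/µm Z-decay trend, and a shared per-litter scale factor
(log-sd 0.3) that makes per-litter rescaling meaningful.  The track
generator gives epiblast cells a low plateau, PrE cells an upward drift to
a high plateau, and DP cells a slower relaxation toward a randomly chosen
fate; targeted cells draw exponential death times (half-life 3.4 h,
memoryless — the simplest model consistent with a single half-life),
censored at the 18 h movie end, with the death recorded on the nearest
15-min frame (the unbiased discretization).

What the generators do not emulate: segmentation errors beyond i.i.d.
noise, intensity distribution shapes of real stains, spatial structure,
TE cells, division events within tracks, or stage-dependent composition
drift.  Passing recovery tests therefore demonstrates that the pipeline is
a consistent estimator of its own generative model, not that it is robust
to every artifact of real microscopy data.

## Numerical notes and limitations

- The Kaplan-Meier half-life of 200 exponential tracks has a sampling sd of
  ~0.35 h; single-batch estimates scatter accordingly around 3.4 h.
- Composition fractions fold ESCs into the epiblast compartment;
  `host_frac_epi` excludes them.  ln(PrE:EPI) is NaN when either count is
  zero rather than ±inf.
- The soft-sphere constants (stiffness 5, adhesion 0.5, confinement 0.3)
  are implementation-level choices tuned only for stable, compact
  aggregates under the 0.1-radius step cap; fate statistics are insensitive
  to them within ±50% (see the sensitivity sweep).
- Model time maps to hours through the assumed 1-hour protein lifetime and
  10-hour cycle; no attempt is made to anchor absolute hours
  post-fertilization.
- The wild-type attractor here is symmetric (~50:50), while late in-vivo
  ICMs sit near 40:60 EPI:PrE; the synthetic embryo tables use the in-vivo
  ratio, the simulator the symmetric one.
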