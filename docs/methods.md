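# Methods

This note documents the models, conventions, defaults and numerical
choices behind `nuctail`, and what the synthetic-data validation does
and does not establish about real data.

## Coordinate frame and topology

Base pairs are indexed by `bp_offset`, 0 at the dyad, negative upstream.
The default model is a 147-bp core with 20-bp linkers on each side
(offsets −93…+93). The superhelical location (SHL) label of a base pair
is `round(bp_offset / 10.4)`, using the canonical ~10.4 bp/turn helical
repeat; profile outputs carry both columns. Strand pairing is declared
explicitly in the topology config (one record per bp naming the residue
on each strand) — it is never inferred from geometry, because author
numbering conventions differ between deposited structures. Residue
numbers are taken from the structure file as-is.

Tails default to the canonical proteolytic clip sites: H3 1–36, H4 1–15,
H2A N-tail 1–11, H2A C-tail 119–C-terminus, H2B 1–23; two copies of
each. The core Cα selection used for superposition is part of the
topology and excludes all tail residues.

## Contacts

A contact is a pair of non-hydrogen atoms within 4.0 Å, *inclusive* at
the cutoff ("within" read inclusively; ties are measure-zero in real
coordinates). The engine uses a k-d tree but is contract-tested for
exact pair-set equality against an all-pairs oracle.

Two aggregation conventions, chosen deliberately:

- per **base pair**: the number of *distinct tail heavy atoms* within
  the cutoff of any heavy atom of either strand residue of the bp;
- per **tail residue**: the number of *distinct DNA heavy atoms*
  contacted by the residue. A residue is bound iff this is nonzero.

Profiles average over frames within each run first; the run × copy units
then give mean ± SEM (SEM over units, n reported; null when n = 1). Copy
2 is mapped through the dyad two-fold pseudo-symmetry (bp → −bp) before
pooling; `mirror_copy2=False` disables this. Preferred binding regions
use a strict `mean > 5` rule (at exactly 5.0 a bp is excluded).

Ensemble comparisons (e.g. modified vs unmodified tails) treat
independent runs as the statistical units, apply a Welch two-sample
t-test per item (residue, full tail, or bp) and Benjamini–Hochberg
adjustment at α = 0.05 across items within a level; BH is this
package's choice of multiple-testing control. With fewer than two runs per side, differences are
reported and the test is skipped with a warning.

## Kinetics

Full-tail state: bound iff the fraction of residues in contact strictly
exceeds `fraction_threshold` (default 0.10). A single threshold is used
in both directions — no hysteresis — because the threshold itself is a
config parameter meant to be swept. With a 36-residue tail, 3 contacting
residues (8.3%) ⇒ unbound, 4 (11.1%) ⇒ bound.

Events are maximal bound stretches on the analysis grid (default 1 ns);
`duration = end − start` with `end` exclusive. Dwells shorter than
`min_dwell` (default 10 ns — the time needed to establish stable
interactions) are ignored. Events truncated by *either* trajectory
boundary are flagged censored and excluded from residence-time means:
their true duration is unknown, and silently keeping them would bias τ
downward. τ_f defaults to long runs (≥ 4000 ns) only, because full-tail
unbinding is slow; residue-level τ_r applies no minimum-dwell filter by
default (the 10 ns rule is a full-tail concept).

Free energy from ensemble counting: ΔG = −RT ln(f/(1−f)) at T = 310 K,
R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹, with the bound-time fraction f pooled
over runs and copies. Estimates supported by fewer than 5
binding/unbinding events are reported but flagged invalid. An additive
standard-state correction hook exists (default 0): the estimate is a
site-occupancy equilibrium, not a volume-referenced standard state, and
any correction is deployment-specific.

ANOVA across tail types runs on log-transformed dwell times (dwells are
approximately exponential, so the log stabilises variance); Tukey HSD
gives the pairwise adjusted comparisons.

Competition model: with a tail occupying its DNA site with dimensionless
equilibrium constant K_tail·c_tail, a partner's effective association
constant for that site is K_eff = K_partner/(1 + K_tail·c_tail) and the
binding penalty is ΔΔG = RT ln(1 + K_tail·c_tail). This is the generic
site-competition algebra; system-specific derivations (e.g. for a
particular demethylase complex) are out of scope.

## SASA

Shrake–Rupley with a deterministic Fibonacci sphere lattice, 960 points
per atom, probe 1.4 Å. vdW radii: C 1.70, N 1.55, O 1.52, P 1.80,
S 1.80 Å (configurable; unknown elements fall back to 1.70 Å). A point
is buried if strictly inside a neighbour's inflated sphere; exact
duplicate atoms (same centre and radius) are collapsed so the first
carries the shared surface. The quadrature error of the 960-point
lattice is well under 1% for an isolated sphere; agreement with an
independent latitude–longitude quadrature oracle is contract-tested at
2% on random clusters.

DNA occlusion: per frame, DNA SASA is computed in the full system and
again with tail atoms deleted; histone cores are *retained* in the
reference, so ΔSASA isolates the tails' shadow (deleting whole histones
would inflate ΔSASA wherever DNA wraps the octamer). The percentage
change divides by the per-frame tail-free SASA (the unoccluded
reference); base pairs with zero reference SASA in a frame are excluded
and logged. Frames are sampled every 5 ns by default. The
occlusion-fraction track counts frames with a decrease above 20%.
Per-run means are averaged with SEM across runs.

## Dyad mapping

Only fragments of exactly 147 bp (the core-protected length) are used;
the midpoint of [start, start+147) is start+73, exact for the odd
length. Midpoint counts are convolved with a normalised discrete
tri-weight kernel w(d) ∝ (1 − (d/h)²)³, |d| ≤ h. The bandwidth "15 bp"
is read as the half-width (31-bp window); a `full_width` flag switches
the interpretation, since the upstream description is ambiguous. The
kernel is normalised to unit mass, so smoothed counts keep raw-count
units and total mass is conserved away from track edges (zero padding).

Candidates are strict local maxima; a flat plateau flanked by lower
values yields its leftmost position, and track-edge plateaus are not
maxima. Within any 30-bp interval (candidates closer than 30 bp), the
candidate with the highest *raw* midpoint count is kept — the protocol
wording says "highest number of counts", which we read as unsmoothed —
with ties broken by higher smoothed value, then leftmost position.
Coordinates are BED 0-based half-open internally; the human-readable CLI
report is 1-based.

## Partner interfaces

Partner chains are declared explicitly or inferred as "every chain that
is neither DNA nor octamer per the topology". Structures missing any
octamer or DNA chain are rejected with a reason rather than analysed in
a partial frame. A bp is contacted if either strand's residue has a
heavy-atom pair within 4 Å of the partner. Binding modes:
multivalent-tail (DNA + any tail), multivalent-core (DNA + core, no
tail), DNA-only, histone-only. Overlap fraction = shared bps between the
partner footprint and the tail preferred regions, divided by the
footprint size; one shared bp flags mutual exclusivity. Mapping a
complex onto the common bp frame requires a per-complex dyad
declaration in its topology config; automatic dyad inference from
heterogeneous deposited structures is deliberately out of scope.

## Synthetic data: what it emulates, and what it does not

The generators define the validation conditions:

- **Two-state kinetics** — exact continuous-time Gillespie per residue;
  rates in ns⁻¹; initial states drawn from the stationary distribution;
  the discretisation grid must satisfy dt ≤ 1/(10·max rate). The
  optional shared-latent coupling is a tail-level two-state chain that
  multiplies residue on-rates by a small factor (default 0.02) while the
  latent is unbound — it mimics cooperative full-tail binding so the 10%
  rule produces realistic event statistics. Ground-truth bound intervals
  are emitted alongside the discretised series. Parameter-recovery
  checks use τ = 500 ns (k_off = 0.002 ns⁻¹) over 20 × 5 µs series,
  sizes at which the estimator's sampling error is well inside the 20%
  recovery band.
- **Toy nucleosome** — DNA as one pseudo-atom per strand per bp on a
  continuous superhelical path (radius 41.9 Å, pitch 25.9 Å, 1.65 turns
  over the core; the same path continues through the linkers — straight
  linker geometry would not change any contact or SASA logic being
  tested). Tails are one-bead-per-residue chains (C, 1.7 Å). Bound beads
  sit 3.5 Å from their target bp's strand-I atom; unbound beads 30 Å
  radially out, with a per-tail z-offset so beads of different tail
  instances never coincide; the builder verifies bound beads are within
  4 Å of their target and unbound beads ≥ 8 Å from all DNA, so contact
  analysis recovers the planted state matrix *exactly*. Default target
  centres place H3 near the linker/SHL ∓7, H4 at SHL ±2, H2A-N at
  SHL ∓4, H2A-C at SHL ±7, H2B at SHL ∓2, copy 2 mirrored (a
  `mirror_copy2_targets=False` variant and a `copy_symmetric_states`
  replay exist for symmetry tests).
- **MNase fragments** — 147-bp fragments whose midpoints mix planted
  dyads (discretised normal spread, sd 4 bp, truncated at ±12 bp — a
  realistic nuclease-cut jitter) with a uniform background fraction
  (default 10%). Recovery studies use 100 midpoints per dyad.
- **Toy complexes** — partner pseudo-atoms placed 3.5 Å from footprint
  bps and, when flagged, from tail or core beads.

Every generator is deterministic under a fixed seed.

What passing these tests shows: the *computational contract* — contact
definitions, event bookkeeping, estimators, smoothing, selection rules —
is implemented correctly and recovers known truth at realistic problem
sizes. What it does not show: anything about force fields, sampling
convergence of real MD, side-chain-level contact geometry (the bead
model has one heavy atom per residue, so absolute contact counts are
~an order of magnitude below all-atom values and the default
5-contact preferred-region threshold only becomes meaningful on all-atom
input), sequence-dependent DNA structure, or experimental MNase biases.

## Numerical details and degenerate inputs

- Superposition: Kabsch via SVD; a reflection optimum is always folded
  back to the proper-rotation branch (logged). Fewer than 3 selection
  atoms or a collinear selection is an error. RMSD is reported over the
  selection only; all atoms are transformed.
- Equilibration trim: 200 ns for runs ≥ 4000 ns, 50 ns for ≥ 800 ns,
  otherwise floor(6.25% of the run length) for short toy runs.
  Trimming is idempotent (a trimmed run carries a flag) and keeps
  absolute frame times.
- Event parity: within one series, the number of binding and unbinding
  transitions differs by at most 1 by construction.
- f_bound of exactly 0 or 1 gives an infinite ΔG, flagged invalid with a
  warning rather than raised, so pooled tables survive degenerate tails.
- Zero-variance profiles make the copy-symmetry correlation undefined:
  NaN with a warning.
- Dyad calling on an empty candidate set returns empty calls; a
  `min_height` (default 0 = off) suppresses background-noise maxima.

## Problem sizes used in the shipped validation

The validation suite and `scripts/acceptance.py` run at: 100 random
300-atom boxes (contact oracle), 20 × 5 µs two-state series (kinetics),
20 random 50-atom clusters (SASA oracle), 50 seeds × 2 planted dyads
(dyad recovery), and one 2 copies × 5 tails × 2000-frame toy trajectory
through the full contacts → kinetics → SASA → profile chain. These sizes
keep each stage's sampling error comfortably inside its tolerance while
the whole validation completes in minutes on a single CPU.
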