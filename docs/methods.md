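# Methods

## The model

A molecular system is an attributed graph: nodes are atoms (atomic number,
formal charge, π-electron count, hybridisation, Cartesian coordinates),
edges are covalent bonds whose sole attribute is an integer order.  A
fragmentation is a binary vector over the *allowed edges* — order-1 bridge
bonds whose removal leaves both components with at least `ceil(0.6·n_t)`
atoms, where `n_t` is the target fragment size.  Restricting to bridges
keeps hydrogen-capping semantics well defined (cutting a ring bond changes
no connectivity, so "the two fragments" would not exist) and automatically
keeps aromatic ring bonds out of the solution space.

### Perception

Bonds are perceived geometrically: a bundled element-pair × order table of
typical equilibrium lengths; a bond exists when the interatomic distance is
within the longest reference for that pair plus 0.25 Å, and the order is
the reference with the smallest absolute deviation.  Pairs absent from the
table fall back to the sum of Cordero covalent radii (order 1); noble gases
never bond.  Distances below 0.3 Å are a hard error.

Hybridisation follows multiple-bond counts (triple or two doubles → sp, one
double → sp², otherwise sp³ for polyvalent atoms), with a promotion pass:
N/O/S atoms (and anionic carbons) without multiple bonds adjacent to a
multiply-bonded atom are promoted to sp² — their lone pair enters the π
path.  This reproduces the classic pyrrole picture: the nitrogen is sp² and
contributes two π electrons, each ring carbon one, giving a conjugation
score `cs = (1/N_A) Σ_i N_e^i/N_A = 6/25`.

Conjugated systems are maximal connected sp²/sp components with ≥ 3 atoms.
Hyperconjugated pairs couple a σ group (C–H or C–halogen bond) with a π
group (isolated multiple bond, lone-pair N/O, charged sp² carbon, or a
whole conjugated system) on disjoint atom sets at a graph separation of 1–3
bonds.  Two enumeration choices were genuinely open and are ours: (i) C–H
bonds on a halogen-bearing carbon are excluded entirely — the polarised C–X
bond dominates that centre, which yields exactly one pair for
3-chloroprop-1-ene (C=C donor, C–Cl acceptor) while keeping the propene
C=C ↔ allylic C–H pairs; (ii) when both direction assignments are
admissible the π group is taken as donor.  σ/π groups are enumerated per
bond (three allylic C–H bonds give three pairs).

### Scoring

The score is a weighted sum of six penalties, each in [0, 1]:

* **Energy gap** `p_pe`: mirrored logistics in Δ_pe = E_tot − E_MBE1
  (kJ/mol), steepness λ = 1.963 and offset d = 6, rescaled by
  γ = √N_f·N_A^min/n_t.  N_A^min counts bare atoms (caps are artefacts of
  the cut, not of the target size).
* **Conjugation** `p_conj`: mean over *disrupted* systems (a broken bond
  with both endpoints inside the system) of S(Δ_conj), with
  Δ_conj = (1/cs)[(1/N_A)Σ_i N_e^i/N_A^i − cs] and the odd sigmoid
  S(Δ) = tanh(λΔ/2).  λ is fixed per system by requiring S = 0.95 at the
  maximal disruption Δ_max = N_A − 1, i.e. λ = ln 39 / Δ_max (the
  "within 5 % of the asymptote" convention used throughout).
* **Hyperconjugation** `p_hyper`: mean over disrupted pairs (a broken bond
  on the donor–acceptor path or inside either group) of S(Δ_hyper)/γ_k,
  γ_k the donor–acceptor bond separation.  A fragment holding the intact
  donor contributes the full donated-electron count; a split donor, or an
  acceptor orphaned from its donor, contributes zero.
* **Volume** `p_vol`: logistic of 14.654·Δ_vol² where Δ_vol is the mean
  relative deviation of fragment volumes from `V_ref`.  The printed
  per-fragment average has a fragment-independent summand, so it is
  implemented as the single algebraically identical sigmoid.  Volumes are
  hard-sphere sums minus pairwise Gaussian overlaps over *all* intra-
  fragment atom pairs (amplitude 2√2, Bondi/Alvarez van der Waals radii);
  the per-element characteristic volume behind `V_ref` subtracts only the
  mean overlap with bonded neighbours, as its definition states.
* **Fragment count** `p_comp` = 1/N_f: retired (weight 0 by default) after
  its tuned weight proved statistically insignificant; available behind
  the weight.
* **Volume range** `p_vrange`: logistic (λ = 11.78, offset −0.25) of the
  relative deviation of max−min fragment volume from `V_ref`.

Default weights are the published tuned set with the count term removed:
(0.136010, 0.146151, 0.313773, 0.109573, 0, 0.294494).  They sum to
1.000001 — six-decimal rounding in the source — so the normalisation check
tolerates 1e-5.  Two printed constants are knowingly inconsistent with
their prose derivations (λ_pe vs the 10/40 kJ/mol boundary points; the
0.95-at-|Δ_vol|=0.5 claim evaluates to 0.975 with exponent 14.654); the
printed constants are shipped verbatim.

### Hydrogen capping and energies

A severed bond i–j is capped on i's side by a hydrogen at
`x(i) + (r_i + r_H)/(r_i + r_j)·(x(j) − x(i))` (Cordero radii): collinear
with the bond, at a covalently sensible distance.  Energy backends consume
the capped geometry plus its bonded topology and return single-point
energies in kJ/mol (kcal/mol backends convert at 4.184): UFF via RDKit for
production, and closed-form toy Hamiltonians for analysis.  The bonded toy
model (per-atom + per-bond, optionally per-angle terms over the topology)
is deliberately sized so a hydrogen cap nearly restores the severed bond's
contribution, leaving a few kJ/mol of residual per cut — the same scale
UFF shows for a mid-chain C–C cut (≈ 6 kJ/mol).  Note that an *all-pairs*
distance-based 2-body energy is **not** exactly assembled by the two-body
expansion once caps exist (cap–foreign-fragment pairs survive with
coefficient one); topology-based bond/angle Hamiltonians telescope exactly
at MBE2/MBE3, which the tests exploit, and the all-pairs backends are
reserved for bond-free atom clusters where the textbook exactness holds.

### Optimiser

Genes are the allowed edges.  The initial population comes from inertia-
frame guesses: the bounding box in the principal-axis frame is split into
`ceil(N_A/n_t)` equal intervals along the axis of largest extent; from the
primitive monomer (all allowed edges cut) nearest each interval midpoint,
fragments grow breadth-first until ≥ 90 % of n_t.  One individual per
reference point, padded to population 16 with mutated copies (per-gene
flip 0.1).  Iterations use tournament selection (size 3; 2 parents when
the population ≤ 8, else ⌊0.25·pop⌋), single-point crossover, per-gene
replacement mutation at 1/|genes|, elitism of one, plus two diversity
safeguards that are ours: distinct crossover parents where possible and
one uniform-random immigrant per generation (small landscapes otherwise
collapse prematurely).  During the first ten iterations every broken edge's
dimer correction ΔE_IJ = E_IJ − E_I − E_J is screened (memoised per edge
and neighbouring-cut context); edges above 10 kJ/mol are blacklisted and
forced intact everywhere.  Termination: 100 iterations or 50 without
improvement.

One design decision deserves emphasis: **a recursion stage never returns
the uncut state**.  With the published penalty structure, any cut that
touches a conjugated or hyperconjugated region pays a flat β·S ≈ 0.12–0.30
while the size terms can repay at most ≈ 0.05, so for a sub-target
subsystem "no cuts" is the literal score minimum — yet the method's whole
point is to partition.  The stage optimiser therefore treats the all-zero
vector as infeasible; the score ranks the *cut* states.

### Recursive driver

A stage on N atoms targets N/m with m = max(2, ceil(N/(2·n_t))) parts (a
174-atom system at n_t = 20 gives five first-stage parts of ≈ 35 atoms);
fragments still above n_t recurse on their bare atoms — caps are stripped
and re-applied at the end, so cap hydrogens can never become cut sites.
Each stage draws its RNG from the master seed via spawned seed sequences
keyed by the recursion path, making full runs bit-reproducible.  A
fragment with no allowed edges is reported as-is with a warning.

### Many-body expansion

All C(N_f,2) dimers (and at level 3 all trimers) are included, with no
distance screening.  An n-mer geometry is the union of its member
fragments with every cut bond internal to the union restored and caps only
on cuts crossing the union boundary — the convention required for the
correction terms to telescope.  E_tot for the fragmentation error
ΔE = E_tot − E_f comes from the same backend as the fragments.  Externally
computed n-mer energies (e.g. ab initio) can be assembled through the same
bookkeeping via an energy table.

### Weight tuning

The tuning objective averages, over a dataset, the volume penalty and a
normalised MBE2 error, f = α·mean(p_vol) + (1−α)·mean(S(|ΔE|)), α = 0.5,
with S a mirrored logistic whose boundary points sit at 1 and 4 kJ/mol
(applied to the error magnitude; the sign carries no quality information).
A Gaussian-process surrogate (scikit-learn, RBF kernel, noise variance and
length scale 1.0) starts from the 16 published grid rows (0.1-step grid,
energy and volume weights floored at 0.2) and proposes new weight vectors
by maximising expected improvement over 4096 Dirichlet samples of the
simplex per iteration; the loop stops after 200 iterations without
improvement.  The expensive ab initio inner objective is out of scope; the
loop accepts any deterministic dataset objective, and the tests drive it
with toy backends and synthetic functions.

## Synthetic data

The fixture registry provides idealised worked-example molecules (pyrrole,
methanol, 3-chloroprop-1-ene with the conventional atom numbering,
propene, butadiene, alkanes, a stearic-acid-like C18 chain) and seeded
chain builders: alkanes CnH2n+2 and extended glycine/alanine/serine
peptides with an N-terminal NH2 and C-terminal COOH, plus a 174-atom
24-residue peptide at the scale of a small protein fragment.  Geometries
are idealised — planar rings solved for target bond lengths, tetrahedral
zig-zag backbones, ≤ 0.02 Å seeded jitter — because only the bonded
topology and approximate distances matter to perception and scoring.  Two
deliberate idealisation artefacts: the amide C–N is drawn at a single-bond
length (1.45 Å) so geometric perception classifies it as cuttable, and
all coordinates are mechanically generated rather than experimental.
Consequently passing tests demonstrate the algorithmic contracts
(perception rules, score algebra, optimiser and expansion exactness,
reproducibility), not chemical accuracy on real protein structures, which
additionally face protonation, non-ideal geometry and real force-field
noise.

## Problem sizes and numerics

Tests run the full pipeline on systems of 9–182 atoms with the toy
backends (the scale at which exhaustive enumeration and closed-form oracles
exist) and exercise UFF on single-point evaluations; the optimiser-quality
check enumerates all 2^|edges| states on chains with ≤ 12 allowed edges.
Logistics are evaluated in overflow-safe form; volume sums are vectorised
over full pair matrices; tie-breaks are deterministic everywhere (lowest
atom index for monomer selection, sorted edge order, fixed RNG streams).

## Known limitations

Ring single bonds are never cut (bridges only).  Formal charges are
trusted from input, not perceived, so charged-group chemistry (Table-style
C⁺/C⁻ classes) activates only when the input declares it.  The reference
volume systematically exceeds the actual volume of a target-sized fragment
(its per-element characteristic volume ignores non-bonded overlaps), so
the volume sigmoid discriminates oversized fragments far better than
undersized ones — combined with the flat disruption penalties this drives
stages toward uniform fragments somewhat below the target, and mean
fragment sizes land under n_t.  Kekulisation, tautomers, metal centres and
protonation-state assignment are out of scope.
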