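# Methods

## The hydrogen-bond model of degeneracy

The model scores the stability of the Watson–Crick (WC) geometry of the
second anticodon–codon base pair (N35–N2) during tRNA sampling, because
that geometry is what the ribosomal decoding center monitors before
committing to a tRNA. Three structural parameters contribute hydrogen
bonds:

* **P1** — WC bonds of the first base pair N36–N1 (2 for A–U, 3 for G–C);
* **P2** — WC bonds of N35–N2 itself;
* **P3** — the U33 2′OH → N35 bond, present only when N35 is a purine,
  i.e. when the second codon base is a pyrimidine.

Their sum **S = P1 + P2 + P3 ∈ [4, 7]** classifies each of the 16 N1N2
codon doublets: **S ≤ 5 → two-fold degenerate box** (the box splits into
a purine-ending and a pyrimidine-ending family; only classic wobble is
tolerated at the third position), **S > 5 → four-fold box** (superwobble
possible: a single U34 tRNA can read all four third-position bases). The
threshold is a sharp inequality; there is no tolerance band at S = 5.

On top of the Lagerkvist sum, the decoding-center adenosine A1493 docks
into the minor groove of N36–N1 as a type-I A-minor motif, contributing
**3 hydrogen bonds on an A–U first pair and 4 on a G–C first pair**. The
total stabilizing count T = S + A-minor therefore spans 7–11 across the
doublets, and the stability ladder (level = S − 3, values 1–4) steps by
either one *local* bond (P2 or P3) or two bonds on the *neighboring*
triple base pair (one WC + one A-minor) — the structural reason the
three parameters are interchangeable. Levels 2 and 3 each admit three
(P1, P2, P3) configurations; levels 1 and 4 are unique. The doublet
histogram over levels is {1: 2, 2: 6, 3: 6, 4: 2}.

Assumptions and exclusions:

* The A1492 type-II A-minor contacts are **excluded from all counts**:
  that residue is engaged only about half the time during sampling and
  is treated qualitatively.
* The C36–G1 A-minor count of 4 is an inference by symmetry of the
  guanine amino group (no deposited structure shows this
  configuration); `DegeneracyTable.assumed_flags()` surfaces which rows
  rest on it (the four G-starting boxes).
* Stacking (N37, base modifications) carries no numeric term. The
  high bond counts are assumed to dominate stacking variability.
* The model is box-level. Split-box singularities of the standard
  nuclear code (AUG, UGA) are outside its scope; the built-in reference
  is the yeast/human mitochondrial code, which is singularity-free at
  box level. The AG box annotation follows the yeast variant (Ser/Arg);
  the human variant (Ser/stop) differs only in labeling, not family.

Family accounting counts 2 families per split box and 1 per four-fold
box: 24 for the canonical alphabet (23 encodable amino acids with one
family reserved for stop). Re-applying the rule with every WC pair
carrying 2 bonds (an all-weak alphabet of A, U and two orthogonal
2-bond-pairing bases) makes every box two-fold: 32 families, 31 amino
acids. With every pair at 3 bonds all boxes are four-fold (16 families).

## Early-translation kinetics

The elementary scheme has tRNA arrival at rate `k_arr`, dissociation at
`k_minus`, peptide-bond formation at `k_pep`, and P-site release of the
spent tRNA at the same `k_minus`. The exact historical scheme is not
published; this package adopts the minimal renewal scheme consistent
with the qualitative statements: memoryless arrival, competing
exponential exit from the bound state, geometric retry until the first
successful reaction, then P-site release. The per-codon mean time is

    T(k-) = (1/p) (1/k_arr + 1/(k- + k_pep)) + 1/k-,
    p = k_pep / (k- + k_pep),

with closed-form optimum **k-\* = sqrt(k_arr · k_pep)**; the ancestral
"k- ≈ k_pep" matching is recovered exactly when arrival is not limiting
relative to the chemistry (k_arr = k_pep). The scheme expression is
isolated in `mean_elongation_time` so alternatives can be swapped. The
dependence of the optimum on `k_arr` is reported, not hidden. A
per-event stochastic simulator (competing exponentials, Bernoulli
channel choice) provides an independent cross-check of the closed form.

The modern scheme inserts a committed accommodation step of mean
duration `1/k_acc` between selection and (PTC-levelled) peptide bond
formation; it adds exactly `1/k_acc` to the renewal mean and reduces to
the early scheme as `k_acc → ∞`.

Mappings: `k- = k0_off · exp(ΔG0/RT)` with RT = 0.616 kcal/mol (310 K)
and `k_pep = k0_pep · exp(−β·V)`; the prefactors default to 1/s because
only proportionality is asserted. The volume-correlation statistic
reports Spearman and Pearson correlation between −ΔG0 and van der Waals
volume, with declared outlier species (e.g. asn, arg, trp) excluded and
reported separately; zero variance on either axis flags the result
degenerate rather than raising.

## Decoding-regime simulator

Three rule-based regimes (allowed/stalled, no rate numbers exist for the
early stages):

* **stage0-gnc** — no decoding center. Default tolerance is strict WC at
  all three positions; a selectable `one-gu` variant accepts a single
  G·U pair at any one position. How permissive the pre-h44 ribosome was
  is a free parameter, not a fact; strict WC is the conservative
  default.
* **transition1-superwobble** — h44 present: WC at positions 1–2, any
  pair at position 3.
* **modern** — WC at positions 1–2; the third position follows the
  doublet's family: WC plus G34·U3/U34·G3 wobble in two-fold boxes, any
  pair in four-fold boxes.

The regimes are nested per tRNA (strict-WC ⊆ modern ⊆ superwobble), so
processivity — the translated prefix fraction before the first codon
with no admissible tRNA — is monotone across regimes for any fixed
message and tRNA set. Decoding ties are broken by WC-position count
(exact WC beats wobble) then tRNA input order. Miscoding is scored when
the decoding tRNA's assigned doublet differs from the codon's doublet;
stop/function semantics are out of scope. Messages stall at the first
undecodable codon (no skip model).

Mutated messages: ancestors are drawn uniformly from a source repertoire
(default the primordial GNC codons GUC/GCC/GAC/GGC); each position
mutates independently (third positions at rate `m3`, optionally all
positions at `m_all`), the substituted base uniform over the three
alternatives — the simplest null model, with no transition/transversion
bias. Confidence intervals use the normal approximation to the binomial
for message-level rates and the sample SEM for processivity.

Default study sizes (1000 messages × 100 codons at m3 = 0.2, 20-seed
sweeps for regime comparisons) make the stochastic checks run in
seconds because decodability is precomputed as a 64-codon lookup per
(regime, tRNA set).

## Structure geometry

Hydrogen bonds are proxied by heavy-atom donor–acceptor distances.
Contacts are data (`ContactSpec`, packaged YAML maps), not code; the
built-in maps for the cited decoding-center structures (5wfk, 5uyp,
5uyl, 1xnq) encode the canonical type-I A-minor contacts but the exact
atom identities behind the published bond labels 1/1′/2/3 are **not
printed anywhere** — the maps are reconstructions, flagged as such, and
meant to be edited against a local copy of each entry. The 5wfk map is
intentionally empty (no first-position base pair forms, so no A-minor
bond exists) and carries an advisory note.

Policies: one model selected (1-based index, default first); altlocs
resolved to the highest-occupancy copy with ties toward 'A'; no
distance/angle hydrogen-bond validity cutoff is applied by default (a
published bond of 4.5 Å is counted as a bond). Reported distances keep
two decimals internally and one decimal in reports, rounded half away
from zero to match the source precision; the mean is the arithmetic
mean over listed contacts.

## Synthetic data

Coordinate fixtures are geometric scaffolds: one donor/acceptor pair per
contact placed at the exact target distance, 20 Å between pairs, decoy
atoms rejected within 1.5 Å of any placed atom, and an optional seeded
rigid-body transform (Haar-random rotation + translation) that leaves
all distances invariant. They are *not* stereochemically valid
nucleotides and exercise distance logic only — a pass on fixtures
validates atom resolution, policy handling and arithmetic, not the
correctness of any particular contact map against a real structure.

Energy/volume tables draw volumes uniformly on 60–230 Å³ (the amino-acid
van der Waals range) and set −ΔG0 = intercept + slope·V + Gaussian
noise, defaults slope 0.01 kcal/mol/Å³ and intercept 0.5 kcal/mol,
putting duplex stabilities on the 1–3 kcal/mol scale of trinucleotide
anticodon–codon duplexes. What the generators do **not** emulate:
realistic replication error spectra, sequence-dependent nearest-neighbor
energetics, or modified bases — so passing tests demonstrate internal
consistency of the model and pipeline, not agreement with measured
mitochondrial kinetics.

All generators are pure functions of their spec including the seed.

## Numerical choices

* The numeric optimum check uses Brent minimization on log k− with
  xtol 1e-12, compared to the closed form at 1e-6 relative tolerance.
* Degenerate correlation inputs (zero variance) are flagged, not raised;
  insufficient overlap (< 3 shared species) raises.
* Stochastic tests are seeded and compare against analytic expectations
  within 3 SEM (or a 99% band for the exhaustive-enumeration check,
  pooled over 10 seeded replicates).

## Known limitations

* No free energies of base pairs are computed; bond counts are integers.
* The early-regime predicates are rules, not kinetics; Table-level
  statements about k− shifts are qualitative in the source analysis and
  are not parameterized here.
* The geometry module does not place hydrogens, classify base-pair
  geometries, or model the state dependence of A-minor bond lengths
  (A1492-bound versus free).
* Frameshifting, translocation kinetics and fitness dynamics are out of
  scope.
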