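# Methods

## The screening model

The pipeline scores each avenanthramide on three axes and intersects them:

1. **Physicochemical plausibility.** Open-formula descriptors feed five
   drug-likeness rule systems (Lipinski, Ghose, Veber, Egan, Muegge), a
   lead-likeness window, a rule-based bioavailability score, and the
   BOILED-Egg absorption/permeation classifier. Everything here is
   recomputed from structure.
2. **Predicted bioactivity.** Six per-target-class scores (GPCRL, ICHM,
   KI, NRL, PI, EI) aggregate into `final = max + mean`. The max rewards a
   compound's best target class; the mean penalises broad inactivity. The
   scores themselves come from an external trained model and are ingested
   as columns.
3. **Safety/overall desirability.** Four semaphore toxicity endpoints and
   a composite drug score, likewise ingested; a reference implementation of
   the drug-score combination (sigmoid desirabilities × toxicity
   multipliers {none, medium, high} → {1.0, 0.8, 0.6}) is provided for
   tables that carry components but no score.

The cascade is two set reductions followed by a ranking intersection:
sub-collection 1 = lead-likeness "Y"; sub-collection 2 = final score
strictly > 0 ("positive" is read as > 0; no collection member scores
exactly 0, so the boundary choice is benign); the perspective set is the
intersection of the top-k (default k = 3, matching the three-name shortlists
the workflow is built to produce) by final score and by drug score within
sub-collection 2. Ties break by code ascending and are logged.

## The compound collection

42 members: 25 one-double-bond (monoene) members, 14 two-double-bond
(diene) members, and 3 standards (Tranilast, dihydroavenanthramide D,
AVN A2). The packaged grid encodes each code as scaffold + substituent map;
ring-A series 1/2/3/4/5 = H, 5-OH, 4-OH, 4-OCH3, 4,5-diOH; ring-B letters
a/p/c/f/s/m/h = cinnamoyl, p-coumaroyl (4-OH), caffeoyl (3,4-diOH),
feruloyl (4-OH/3-OCH3), sinapoyl (4-OH/3,5-diOCH3), 4-OCH3, and mono-OH
positional isomers; suffix "d" switches to the diene scaffold. Linker
double bonds are fixed E; no other stereocentres exist. The grid file is
the source of truth and is *labelled a reconstruction*: the code convention
is established, but no machine-readable per-code table was available, so
the patterns were rebuilt to satisfy every published collection-level
constraint simultaneously (roster size 42; monoene H-bond donor/acceptor
ranges 2–6 / 4–9 and diene ranges 3–6 / 5–8; rotatable-bond floors 4 and 5
with the sinapoyl diene at 7; MW ceiling 385.37 realised by 2sd; exactly 15
members carrying an aromatic vicinal diol; a single unsubstituted member
inside the egg yolk; GI-absorption failures exactly {5c, 5s, 5cd}). The
series-4 assignment is 4-OCH3 *without* a 5-OH: adding the hydroxyl would
push the 4-series caffeoyl member past the Egan TPSA bound, contradicting
its published standing as a top candidate.

## The synthetic score table

`data/appendix_scores_synthetic.csv` stands in for the per-compound output
of three proprietary predictors. It is synthetic by necessity and by label.
Its values are pinned so that every published aggregate is reproduced
exactly: the four headline rows (2c max 0.17 / avg −0.05, 2cd 0.18 / 0.01,
2pd 0.18 / 0.00, Tranilast −0.02 / −0.16; drug scores 0.61 / 0.60 / 0.52 /
0.51; drug-likeness −0.58 / −0.38 / −1.15 / 2.74), |sub-collection 1| = 22,
|sub-collection 2| = 12, top-3 sets {5pd, 2pd, 2cd} and {4c, 2c, 2cd} with
intersection {2cd}, the seven-member drug-likeness exception set, 17
members with a medium reproductive/irritancy risk, one high-irritancy
member (2ad), and universal Pgp non-substrate flags. Unconstrained entries
are deterministic fillers. A green test against this table establishes
that the *pipeline arithmetic* reproduces the published selection from the
published flags — not that the proprietary predictors were reproduced.

The seeded generator (`generate_synthetic_scores`) emulates the same schema
distributionally for property testing: six uniform category scores over
(−1.0, 0.5), uniform drug score, normal drug-likeness (mean 0, sd 2,
matching the spread of the published values), categorical toxicity with
P(high) = 0.1, Bernoulli lead-likeness. It does not emulate inter-column
correlations (e.g. polar compounds scoring lower), so distribution-level
tests only check marginals and determinism.

## Numerical choices

- **Descriptors** delegate to RDKit: average-mass MW, Ertl N/O TPSA
  (S/P contributions unnecessary for this chemistry), Wildman–Crippen
  WLOGP/MR, strict rotatable-bond counting (amide C–N excluded; N–aryl
  counts). H-bond counts use the Lipinski convention (N+O; NH+OH) because
  the rule definitions are phrased in it; external predictors may count
  differently and their columns can be ingested for comparison.
- **MLOGP** implements the published 13-parameter regression with simple
  topological surrogates for the structural parameters (proximity = N/O
  pairs at graph distance ≤ 2; unsaturation on the Kekulé structure; an
  ortho donor/acceptor SMARTS for the intramolecular H-bond flag). It is a
  secondary estimator; WLOGP is primary. The consensus logP is the mean of
  whatever estimators are available (internal two plus any external
  columns), since three of the five published flavours are proprietary.
- **ESOL / skin permeation / bioavailability score** use the pinned
  literature coefficients in `config.py`; solubility classes from cut
  points (−10, −6, −4, −2, 0). All rule bounds are inclusive at equality.
- **BOILED-Egg** defaults to ellipse mode with the published best-fit
  ellipses (white: centre (71.051, 2.292), axes 142.081 × 8.740, rotation
  −1.03°; yolk: centre (38.117, 3.177), axes 82.061 × 5.557, rotation
  −0.17°). Rectangle mode implements the two scalar thresholds
  (WLOGP ≤ 5.88, TPSA ≤ 131.6). The modes disagree for points with TPSA
  between 131.6 and the ellipse's reach (~142): on this collection the
  feruloyl catechol members 5f/5fd fall in that band, which is why ellipse
  mode — not the rectangle — reproduces the published GI-absorption set.
  Disagreements are logged, never raised.
- **Degenerate inputs**: empty rosters yield empty tables; missing
  descriptor rows are flagged, not dropped; k larger than the candidate
  set is clamped with a warning; zero logP estimates raise.
- **Determinism**: one named PRNG (`numpy.random.default_rng`) per
  synthetic table, seed recorded in the CSV header; machine outputs are
  byte-stable for a fixed config, and each report carries a hash of the
  scientific configuration (output paths excluded).

## Known limitations

- Computing the five rule systems from structure flags
  {5c, 5s, 5f, 5cd, 5fd} as drug-likeness exceptions — a strict subset of
  the published seven-member list. The two extra published members (3c,
  3fd) pass every pinned inequality on every descriptor this package can
  compute (TPSA 127.1 / 116.1, HBD 5 / 4, MW well inside all windows), so
  their published failure must stem from a proprietary descriptor value;
  the exception set is therefore taken from the ingested flags, and the
  computed set is asserted only as a subset.
- RDKit's curated Brenk set lets the `hydroquinone` pattern co-fire on
  aromatic ortho-diols, so catechol-bearing members can show 4 alert types
  where the original report counts 1–3; alert-type counts are asserted
  with that ceiling.
- Lead-likeness computed from structure marks more members "Y" than the
  published 22 (the published flags used a proprietary logP); the cascade
  therefore consumes the ingested flag column, with the computed verdict
  available per compound for comparison.
- The MW floor printed for the collection (326.59 g/mol) matches no
  plausible member composition (the smallest member computes to 267.28)
  and is ignored; the ceiling (385.37, the sinapoyl diene 2sd) is
  reproduced exactly.
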