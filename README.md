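# avnscreen

In-silico screening pipeline for **avenanthramides** (AVNs) — the phenolic
amide secondary metabolites of oat (*Avena* spp.), conjugates of an
anthranilate-derived ring and a hydroxycinnamate-derived ring joined by an
acyl linker with zero, one or two E-configured double bonds. The package
answers the question a discovery chemist would ask of this family: which
members look most like viable drug leads, judging from open physicochemical
descriptors, drug-likeness filters, structural alerts, an
absorption/permeation model, and bioactivity/toxicity predictor columns?

## What it computes

**Descriptors** (RDKit-backed, open formulas only): MW, heavy/aromatic atom
counts, fraction Csp3, Lipinski-convention H-bond donors (O–H + N–H) and
acceptors (N + O), rotatable bonds (single acyclic bonds between
non-terminal heavy atoms, amide C–N excluded), Ertl fragment-contribution
TPSA, Wildman–Crippen WLOGP, Moriguchi MLOGP, a consensus logP, molar
refractivity, ESOL solubility `logS = 0.16 − 0.63·clogP − 0.0062·MW +
0.066·RB − 0.74·AP` with its qualitative class, and Potts–Guy skin
permeation `log Kp = −2.74 + 0.71·logP − 0.0061·MW`.

**Rule systems**: Lipinski (≤1 violation tolerated), Ghose, Veber, Egan
(WLOGP ≤ 5.88, TPSA ≤ 131.6), Muegge, lead-likeness (250 ≤ MW ≤ 350,
logP ≤ 3.5, ≤7 rotatable bonds) and the Abbott bioavailability score. All
bounds inclusive; all constants pinned in `avnscreen.config`.

**Structural alerts**: PAINS and Brenk substructure catalogs (curated sets
shipped with RDKit), with per-compound alert-type counts.

**BOILED-Egg**: classification in the (TPSA, WLOGP) plane — the "white"
region predicts passive gastrointestinal absorption, the "yolk" passive
blood–brain-barrier permeation — in ellipse mode (published best-fit
ellipses) or rectangle mode (the two scalar thresholds).

**Selection cascade**: the per-compound bioactivity category scores (GPCR
ligand, ion-channel modulator, kinase inhibitor, nuclear-receptor ligand,
protease inhibitor, other enzyme inhibitor) aggregate into a *final* score
`final = max + mean` over the six. The collection reduces to
sub-collection 1 (lead-likeness "Y"), then sub-collection 2 (final score
> 0); the "most perspective" set is the intersection of the top-k by final
bioactivity score and the top-k by overall drug score within
sub-collection 2.

The six category scores, the OSIRIS-style drug-likeness/toxicity values and
the Pgp/CYP flags come from proprietary predictors and are **ingested as
data**, never recomputed. The packaged
`data/appendix_scores_synthetic.csv` is a labelled synthetic stand-in
constrained to the published summary figures; swap in a real export with
`--scores`.

## Worked example

```sh
avnscreen report --out-dir out
```

logs `sub1=22 sub2=12 perspective=['2cd']` and writes `out/report.json`:

```json
"cascade": {
  "perspective_set": ["2cd"],
  "top_bioactivity": ["5pd", "2cd", "2pd"],
  "top_drugscore": ["4c", "2c", "2cd"],
  ...
},
"egg": {
  "yolk_positive": ["1a"],
  "white_negative": ["5c", "5cd", "5s"]
}
```

Reading: of the 42-member collection, 22 are lead-like, 12 of those carry a
positive final bioactivity score, and caffeoyl-diene **2cd** is the single
compound ranked top-3 by both the bioactivity and the drug-score criterion —
the best lead of the family. Only the fully unsubstituted member **1a**
falls in the egg's yolk (predicted BBB-permeant); the three most polar
members (5c, 5s, 5cd) miss passive GI absorption.

Library use:

```python
>>> import avnscreen as avn
>>> d = avn.compute_all(avn.build_structure("monoene", {}))
>>> d.n_rotatable, d.hbd, d.hba, round(d.tpsa, 2)
(4, 2, 4, 66.4)
```

Other subcommands: `enumerate` (write the roster as SMILES/SDF/CSV),
`screen` (descriptor/verdict/alert/egg tables), `egg` (optionally with
`--plot`), `cascade`, `synth-scores` (seeded synthetic predictor tables).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, by running the package end to end, the final bioactivity scores
of the four headline compounds (2c, 2cd, 2pd, Tranilast) from the packaged
score table and the rotatable-bond count of the unsubstituted one-double-
bond scaffold, and writes them as JSON.

## Layout

```
src/avnscreen/
  config.py       pinned thresholds/coefficients with citations
  registry.py     scaffolds, collection grid, roster I/O, synthetic scores
  descriptors.py  descriptor engine
  rules.py        five rule systems, lead-likeness, bioavailability score
  alerts.py       PAINS/Brenk screening
  egg.py          BOILED-Egg classification and plot data
  cascade.py      score aggregation and the selection cascade
  cli.py          command-line interface
  data/           packaged collection grid and synthetic score table
docs/methods.md   model assumptions, defaults and limitations
```
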