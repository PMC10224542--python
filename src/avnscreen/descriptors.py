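"""Physicochemical descriptors.

All open-formula descriptors consumed by the screening workflow: average
molecular weight, Lipinski-convention hydrogen-bond counts, rotatable bonds
(amide C-N excluded), Ertl fragment-contribution TPSA, Wildman-Crippen
atom-contribution logP (WLOGP), an optional Moriguchi logP estimate (MLOGP),
a consensus logP, the ESOL solubility model with its qualitative class, and
Potts-Guy skin permeation.

Standard descriptor primitives are delegated to RDKit; the proprietary logP
flavours used alongside these in the original workflow (iLOGP, XLOGP3,
SILICOS-IT) are accepted as external columns only and never re-implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Optional

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .config import DEFAULT_CONFIG, EsolModel, SkinPermeationModel


def _as_mol(mol: Chem.Mol | str) -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    m = Chem.MolFromSmiles(mol)
    if m is None:
        raise ValueError(f"unparseable SMILES: {mol!r}")
    return m


@dataclass
class DescriptorSet:
    """Computed descriptors for one compound.

    Note that ``hba >= hbd`` is *not* an invariant under the Lipinski
    counting convention (a molecule of N-H groups only would violate it).
    ``solubility_class`` is monotone in ``esol_logs`` by construction.
    """
    mw: float                    # g/mol, average isotopic masses
    n_heavy: int
    n_atoms_total: int           # hydrogens included
    n_aromatic_heavy: int
    n_carbons: int
    n_heteroatoms: int
    n_rings: int
    fraction_csp3: float
    hbd: int                     # O-H + N-H bonds
    hba: int                     # N + O atoms
    n_rotatable: int
    tpsa: float                  # Angstrom^2
    wlogp: float
    mlogp: float
    consensus_logp: float
    molar_refractivity: float
    has_carboxylic_acid: bool
    esol_logs: float             # log10(mol/L)
    solubility_class: str
    logkp_skin: float            # log10(cm/s)

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# elementary counts
# ---------------------------------------------------------------------------

def molecular_weight(mol: Chem.Mol | str) -> float:
    """Average molecular weight (implicit hydrogens included), g/mol."""
    return Descriptors.MolWt(_as_mol(mol))


def count_hbd(mol: Chem.Mol | str) -> int:
    """H-bond donors, Lipinski convention: number of O-H and N-H bonds."""
    return Lipinski.NHOHCount(_as_mol(mol))


def count_hba(mol: Chem.Mol | str) -> int:
    """H-bond acceptors, Lipinski convention: number of N and O atoms."""
    return Lipinski.NOCount(_as_mol(mol))


def count_rotatable_bonds(mol: Chem.Mol | str) -> int:
    """Rotatable bonds: single acyclic bonds between two non-terminal heavy
    atoms, excluding amide C-N bonds (high rotational barrier)."""
    return rdMolDescriptors.CalcNumRotatableBonds(
        _as_mol(mol), rdMolDescriptors.NumRotatableBondsOptions.Strict)


# ---------------------------------------------------------------------------
# surface / lipophilicity
# ---------------------------------------------------------------------------

def tpsa(mol: Chem.Mol | str) -> float:
    """Topological polar surface area from Ertl's N/O fragment
    contributions, in Angstrom^2. Sulfur/phosphorus contributions are not
    included (no roster member carries them)."""
    return Descriptors.TPSA(_as_mol(mol))


def wlogp(mol: Chem.Mol | str) -> float:
    """Wildman-Crippen atom-contribution logP (the BOILED-Egg abscissa)."""
    return Crippen.MolLogP(_as_mol(mol))


def molar_refractivity(mol: Chem.Mol | str) -> float:
    return Crippen.MolMR(_as_mol(mol))


# -- Moriguchi logP ---------------------------------------------------------

_HALOGEN_WEIGHT = {9: 0.5, 17: 1.0, 35: 1.5, 53: 2.0}
_QN = Chem.MolFromSmarts("[NX4,NX4+]")
_NO2 = Chem.MolFromSmarts("[N+](=O)[O-]")
_NCS = Chem.MolFromSmarts("N=C=S")
_BLM = Chem.MolFromSmarts("C1(=O)NCC1")
_AMP = Chem.MolFromSmarts("[NX3;H2,H1;!$(NC=O)][CX4][CX3](=O)[OX2H1]")
_HBPAT = Chem.MolFromSmarts("[O,N;!H0]-[a]:[a]-[CX3]=[OX1]")


def mlogp(mol: Chem.Mol | str) -> float:
    """Moriguchi logP: the published 13-parameter regression.

    Structural parameters are derived with simple topological rules
    (proximity = N/O pairs at graph distance 1 or 2; unsaturation counted
    on the Kekule structure; the intramolecular H-bond flag from an
    ortho donor/acceptor aryl pattern). Adequate as a secondary estimate;
    WLOGP remains the primary internal lipophilicity descriptor.
    """
    m = _as_mol(mol)
    cx = sum(1.0 if a.GetAtomicNum() == 6 else _HALOGEN_WEIGHT.get(a.GetAtomicNum(), 0.0)
             for a in m.GetAtoms())
    no = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() in (7, 8))

    # proximity of N/O: X-Y pairs score 2, X-C-Y pairs score 1
    hetero = [a.GetIdx() for a in m.GetAtoms() if a.GetAtomicNum() in (7, 8)]
    dmat = Chem.GetDistanceMatrix(m) if hetero else None
    prx = 0.0
    for i, ai in enumerate(hetero):
        for aj in hetero[i + 1:]:
            d = dmat[ai][aj]
            if d == 1:
                prx += 2.0
            elif d == 2:
                prx += 1.0

    km = Chem.Mol(m)
    Chem.Kekulize(km, clearAromaticFlags=True)
    ub = sum(1 for b in km.GetBonds()
             if b.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)
             and not _in_nitro(b))
    hb = 1.0 if m.HasSubstructMatch(_HBPAT) else 0.0
    pol = sum(1 for a in m.GetAtoms()
              if a.GetAtomicNum() in (7, 8) and not a.GetIsAromatic()
              and any(n.GetIsAromatic() for n in a.GetNeighbors()))
    amp = 1.0 if m.HasSubstructMatch(_AMP) else 0.0
    alk = 1.0 if (all(a.GetAtomicNum() in (1, 6) for a in m.GetAtoms())
                  and ub == 0 and m.GetRingInfo().NumRings() == 0) else 0.0
    # rings other than carbocyclic aromatics count
    rng = 0.0
    for ring in m.GetRingInfo().AtomRings():
        if not all(m.GetAtomWithIdx(i).GetIsAromatic()
                   and m.GetAtomWithIdx(i).GetAtomicNum() == 6 for i in ring):
            rng = 1.0
            break
    qn = float(len(m.GetSubstructMatches(_QN)))
    no2 = float(len(m.GetSubstructMatches(_NO2)))
    ncs = float(len(m.GetSubstructMatches(_NCS)))
    blm = float(len(m.GetSubstructMatches(_BLM)) > 0)
    return (-1.014
            + 1.244 * cx ** 0.6
            - 1.017 * no ** 0.9
            + 0.406 * prx
            - 0.145 * ub ** 0.8
            + 0.511 * hb
            + 0.268 * pol
            - 2.215 * amp
            + 0.912 * alk
            - 0.392 * rng
            - 3.684 * qn
            + 0.474 * no2
            + 1.582 * ncs
            + 0.773 * blm)


def _in_nitro(bond: Chem.Bond) -> bool:
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    for x, y in ((a, b), (b, a)):
        if x.GetAtomicNum() == 7 and y.GetAtomicNum() == 8 and x.GetFormalCharge() == 1:
            return True
    return False


def consensus_logp(values: Mapping[str, float]) -> float:
    """Arithmetic mean of the available labelled logP estimates.

    The original workflow averages five estimators; here the internal
    WLOGP/MLOGP are always available and external iLOGP/XLOGP3/SILICOS-IT
    columns join the mean when provided.
    """
    vals = [v for v in values.values() if v is not None and not math.isnan(v)]
    if not vals:
        raise ValueError("consensus logP needs at least one estimate")
    return sum(vals) / len(vals)


# ---------------------------------------------------------------------------
# solubility and permeation
# ---------------------------------------------------------------------------

def esol_logs(clogp: float, mw: float, n_rotatable: int,
              aromatic_proportion: float,
              model: EsolModel | None = None) -> tuple[float, str]:
    """Delaney ESOL estimate of aqueous solubility.

    Returns ``(logS, solubility_class)`` with logS in log10(mol/L) and the
    class from the pinned cut points (monotone in logS).
    """
    model = model or DEFAULT_CONFIG.esol
    logs = (model.intercept
            + model.coef_clogp * clogp
            + model.coef_mw * mw
            + model.coef_rotb * n_rotatable
            + model.coef_aromatic_proportion * aromatic_proportion)
    return logs, solubility_class(logs, model)


def solubility_class(logs: float, model: EsolModel | None = None) -> str:
    model = model or DEFAULT_CONFIG.esol
    for bound, name in zip(model.class_bounds, model.class_names):
        if logs <= bound:
            return name
    return model.class_names[-1]


def skin_permeation_logkp(logp: float, mw: float,
                          model: SkinPermeationModel | None = None) -> float:
    """Potts-Guy skin permeation coefficient, log10(Kp / (cm/s))."""
    model = model or DEFAULT_CONFIG.skin
    return model.intercept + model.coef_logp * logp + model.coef_mw * mw


# ---------------------------------------------------------------------------
# aggregate
# ---------------------------------------------------------------------------

_ACID = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")


def compute_all(mol: Chem.Mol | str,
                external_logp: Mapping[str, float] | None = None) -> DescriptorSet:
    """Fill a full :class:`DescriptorSet` for one molecule.

    Deterministic for a fixed canonical structure: every member descriptor
    is invariant under atom reordering.
    """
    m = _as_mol(mol)
    n_heavy = m.GetNumHeavyAtoms()
    n_aromatic = sum(1 for a in m.GetAtoms() if a.GetIsAromatic())
    n_carbons = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 6)
    w = wlogp(m)
    ml = mlogp(m)
    logp_estimates = {"WLOGP": w, "MLOGP": ml}
    if external_logp:
        logp_estimates.update(external_logp)
    clogp = consensus_logp(logp_estimates)
    nrot = count_rotatable_bonds(m)
    mw = molecular_weight(m)
    ap = n_aromatic / n_heavy if n_heavy else 0.0
    logs, sclass = esol_logs(w, mw, nrot, ap)
    return DescriptorSet(
        mw=mw,
        n_heavy=n_heavy,
        n_atoms_total=m.GetNumAtoms() + sum(a.GetTotalNumHs() for a in m.GetAtoms()),
        n_aromatic_heavy=n_aromatic,
        n_carbons=n_carbons,
        n_heteroatoms=n_heavy - n_carbons,
        n_rings=rdMolDescriptors.CalcNumRings(m),
        fraction_csp3=rdMolDescriptors.CalcFractionCSP3(m),
        hbd=count_hbd(m),
        hba=count_hba(m),
        n_rotatable=nrot,
        tpsa=tpsa(m),
        wlogp=w,
        mlogp=ml,
        consensus_logp=clogp,
        molar_refractivity=molar_refractivity(m),
        has_carboxylic_acid=m.HasSubstructMatch(_ACID),
        esol_logs=logs,
        solubility_class=sclass,
        logkp_skin=skin_permeation_logkp(w, mw),
    )


def compute_table(entries: Iterable, external: Optional[pd.DataFrame] = None
                  ) -> pd.DataFrame:
    """Descriptor table for a roster, one row per compound code.

    ``external`` may carry per-code logP columns (``ilogp``, ``xlogp3``,
    ``silicos_it``) that join the consensus mean.
    """
    rows = []
    for e in entries:
        ext = None
        if external is not None and e.code in external.index:
            ext = {k: float(external.loc[e.code, k])
                   for k in ("ilogp", "xlogp3", "silicos_it")
                   if k in external.columns}
        d = compute_all(e.mol(), ext).as_dict()
        d["code"] = e.code
        d["scaffold"] = e.scaffold_id
        rows.append(d)
    df = pd.DataFrame(rows)
    cols = ["code", "scaffold"] + [c for c in df.columns
                                   if c not in ("code", "scaffold")]
    return df[cols].set_index("code", drop=False)


def write_descriptor_table(df: pd.DataFrame, path, report: bool = False) -> None:
    """CSV writer: full precision for machine output, 2 decimals in reports."""
    out = df.copy()
    if report:
        for c in out.columns:
            if out[c].dtype.kind == "f":
                out[c] = out[c].map(lambda v: f"{v:.2f}")
    out.to_csv(path, index=False)
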