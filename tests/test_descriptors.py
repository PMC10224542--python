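"""Descriptor engine: frozen expected values, fragment-table oracles and
representation-invariance properties."""

import math
import random

import pytest
from rdkit import Chem

import avnscreen as avn

MONOENE = "OC(=O)c1ccccc1NC(=O)/C=C/c1ccccc1"


class TestElementaryCounts:
    @pytest.mark.parametrize("smiles,mw", [
        ("Nc1ccccc1C(O)=O", 137.14),               # anthranilic acid
        ("OC(=O)c1ccccc1NC(=O)/C=C/c1ccc(OC)c(OC)c1", 327.33),  # Tranilast
        ("C", 16.04),
    ])
    def test_molecular_weight(self, smiles, mw):
        assert avn.molecular_weight(smiles) == pytest.approx(mw, abs=0.02)

    def test_hbd_hba_monoene_core(self):
        # acid OH + amide NH; 1 N + 3 O
        assert avn.count_hbd(MONOENE) == 2
        assert avn.count_hba(MONOENE) == 4

    def test_hbd_hba_benzene(self):
        assert avn.count_hbd("c1ccccc1") == 0
        assert avn.count_hba("c1ccccc1") == 0

    def test_substituent_increments(self):
        """Each OH adds one donor and one acceptor; each OCH3 adds one
        acceptor only."""
        base = avn.compute_all(MONOENE)
        oh = avn.compute_all(avn.build_structure("monoene", {"B4": "OH"}))
        ome = avn.compute_all(avn.build_structure("monoene", {"B4": "OCH3"}))
        assert (oh.hbd, oh.hba) == (base.hbd + 1, base.hba + 1)
        assert (ome.hbd, ome.hba) == (base.hbd, base.hba + 1)

    @pytest.mark.parametrize("smiles,n", [
        (MONOENE, 4),                     # scaffold floor of the monoene range
        ("CC", 0),                        # both atoms terminal
        ("OC(=O)c1ccccc1NC(=O)/C=C/C=C/c1ccccc1", 5),   # diene floor
    ])
    def test_rotatable_bonds(self, smiles, n):
        assert avn.count_rotatable_bonds(smiles) == n

    def test_diene_with_two_methoxy_reaches_seven(self):
        smi = avn.build_structure(
            "diene", {"B3": "OCH3", "B4": "OH", "B5": "OCH3"})
        assert avn.count_rotatable_bonds(smi) == 7


# Ertl N/O fragment contributions needed for the roster chemistry;
# an independent re-coding of the published table used as an oracle.
_TPSA_FRAGMENTS = {
    "hydroxyl": 20.23,        # [OX2H]
    "ether": 9.23,            # [OX2H0]
    "carbonyl": 17.07,        # [OX1]=C
    "amide_nh": 12.03,        # [NX3H1]
}


def tpsa_oracle(mol: Chem.Mol) -> float:
    total = 0.0
    for a in mol.GetAtoms():
        z = a.GetAtomicNum()
        if z == 8:
            if a.GetTotalNumHs() == 1:
                total += _TPSA_FRAGMENTS["hydroxyl"]
            elif a.GetDegree() == 2:
                total += _TPSA_FRAGMENTS["ether"]
            else:
                total += _TPSA_FRAGMENTS["carbonyl"]
        elif z == 7:
            assert a.GetTotalNumHs() == 1 and a.GetDegree() == 2
            total += _TPSA_FRAGMENTS["amide_nh"]
    return total


class TestTPSA:
    @pytest.mark.parametrize("smiles,expected", [
        ("c1ccccc1", 0.0),
        ("OC(=O)c1ccccc1", 37.30),   # carboxylic acid: 17.07 + 20.23
        (MONOENE, 66.40),            # + secondary amide 12.03 + 17.07
    ])
    def test_frozen_values(self, smiles, expected):
        assert avn.tpsa(smiles) == pytest.approx(expected, abs=0.01)

    def test_matches_fragment_oracle_on_roster(self, roster):
        """Fragment-additive oracle recomputed independently for the N/O
        environments present in the collection."""
        for e in roster:
            m = e.mol()
            assert avn.tpsa(m) == pytest.approx(tpsa_oracle(m), abs=0.01), e.code

    def test_hydroxyl_additivity(self):
        base = avn.tpsa(MONOENE)
        plus = avn.tpsa(avn.build_structure("monoene", {"B4": "OH"}))
        assert plus - base == pytest.approx(_TPSA_FRAGMENTS["hydroxyl"], abs=0.01)


class TestWLOGP:
    def test_benzene_hand_summed(self):
        # 6 aromatic CH carbons (C18: 0.1581) + 6 H on carbon (H: 0.1230)
        assert avn.wlogp("c1ccccc1") == pytest.approx(6 * (0.1581 + 0.1230),
                                                      abs=1e-4)

    def test_methoxy_delta_constant_across_sites(self):
        """Adding an aromatic OCH3 shifts WLOGP by a site-independent
        atom-contribution delta."""
        base = avn.wlogp(MONOENE)
        deltas = {round(avn.wlogp(avn.build_structure("monoene", {p: "OCH3"}))
                        - base, 6)
                  for p in ("B2", "B3", "B4", "A4", "A5")}
        assert len(deltas) == 1


class TestMLOGP:
    def test_hexane_closed_form(self):
        # carbon parameter 6, alkane indicator, no heteroatom terms
        expected = -1.014 + 1.244 * 6 ** 0.6 + 0.912
        assert avn.mlogp("CCCCCC") == pytest.approx(expected, abs=1e-6)

    def test_monotone_in_alkane_series(self):
        vals = [avn.mlogp("C" * n) for n in range(2, 9)]
        assert vals == sorted(vals)

    def test_invariant_under_canonicalisation(self):
        smi = "OC(=O)c1ccccc1NC(=O)/C=C/c1ccc(O)c(O)c1"
        assert avn.mlogp(smi) == avn.mlogp(Chem.CanonSmiles(smi))


class TestConsensusLogP:
    def test_mean_and_passthrough(self):
        assert avn.consensus_logp({"a": 2.0, "b": 3.0}) == 2.5
        assert avn.consensus_logp({"WLOGP": 1.7}) == 1.7
        assert avn.consensus_logp({k: 4.2 for k in "abcde"}) == pytest.approx(4.2)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            avn.consensus_logp({})


class TestSolubilityAndSkin:
    def test_esol_term_by_term(self):
        logs, cls = avn.esol_logs(clogp=2, mw=300, n_rotatable=5,
                                  aromatic_proportion=0.5)
        assert logs == pytest.approx(
            0.16 - 0.63 * 2 - 0.0062 * 300 + 0.066 * 5 - 0.74 * 0.5, abs=1e-9)
        assert logs == pytest.approx(-3.00, abs=1e-9)
        assert cls == "soluble"

    def test_esol_intercept_and_class_monotonicity(self):
        logs, _ = avn.esol_logs(0, 0, 0, 0)
        assert logs == pytest.approx(0.16)
        order = [avn.solubility_class(x)
                 for x in (-12, -8, -5, -3, -1, 1)]
        assert order == ["insoluble", "poorly soluble", "moderately soluble",
                         "soluble", "very soluble", "highly soluble"]

    def test_skin_permeation_pinned_model(self):
        assert avn.skin_permeation_logkp(2, 300) == pytest.approx(
            -2.74 + 0.71 * 2 - 0.0061 * 300)
        assert avn.skin_permeation_logkp(0, 0) == pytest.approx(-2.74)
        assert (avn.skin_permeation_logkp(2, 400)
                < avn.skin_permeation_logkp(2, 300))


class TestComputeAll:
    def test_monoene_core_descriptor_set(self):
        d = avn.compute_all(MONOENE)
        assert (d.hbd, d.hba, d.n_rotatable) == (2, 4, 4)
        assert d.tpsa == pytest.approx(66.40, abs=0.01)
        assert d.has_carboxylic_acid
        assert 0.0 <= d.fraction_csp3 <= 1.0

    def test_invariant_under_atom_reordering(self):
        rng = random.Random(3)
        mol = Chem.MolFromSmiles(MONOENE)
        order = list(range(mol.GetNumAtoms()))
        rng.shuffle(order)
        shuffled = Chem.RenumberAtoms(mol, order)
        a, b = avn.compute_all(mol).as_dict(), avn.compute_all(shuffled).as_dict()
        for key, va in a.items():
            if isinstance(va, float):
                assert b[key] == pytest.approx(va, abs=1e-9), key
            else:
                assert b[key] == va, key

    def test_invariant_under_sdf_round_trip(self, roster, tmp_path):
        path = tmp_path / "r.sdf"
        avn.write_roster(roster[:6], path)
        back = avn.read_roster(path)
        for orig, rt in zip(roster[:6], back):
            assert avn.compute_all(orig.mol()) == avn.compute_all(rt.mol())

    def test_roster_hbond_ranges_by_scaffold(self, roster, descriptors_by_code):
        """Printed collection-wide ranges: one-double-bond members span
        HBD 2-6 / HBA 4-9, two-double-bond members HBD 3-6 / HBA 5-8."""
        mono = [descriptors_by_code[e.code] for e in roster
                if e.scaffold_id == "monoene" and not e.is_standard]
        di = [descriptors_by_code[e.code] for e in roster
              if e.scaffold_id == "diene"]
        assert min(d.hbd for d in mono) == 2 and max(d.hbd for d in mono) == 6
        assert min(d.hba for d in mono) == 4 and max(d.hba for d in mono) == 9
        assert min(d.hbd for d in di) == 3 and max(d.hbd for d in di) == 6
        assert min(d.hba for d in di) == 5 and max(d.hba for d in di) == 8

    def test_solubility_class_monotone_in_logs(self, descriptors_by_code):
        classes = list(avn.DEFAULT_CONFIG.esol.class_names)
        for d in descriptors_by_code.values():
            assert classes.index(d.solubility_class) == classes.index(
                avn.solubility_class(d.esol_logs))
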