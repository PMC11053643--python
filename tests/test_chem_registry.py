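"""Chemical registry: roster loading, formula weights, unit conversion, chain length."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfas_bcbcr.chem_registry import (
    ChemicalRecord,
    SchemaError,
    ValidationError,
    chain_length,
    load_roster,
    mass_to_molar,
    molar_to_mass,
    molecular_weight,
    packaged_roster_path,
)

# Hand-summed 2021 IUPAC atomic weights, computed independently before the
# formula parser existed: 8*12.011 + 1.008 + 15*18.998403163 + 2*15.999
PFOA_MW_HAND = 414.070047445
# 8*12.011 + 1.008 + 17*18.998403163 + 3*15.999 + 32.06
PFOS_MW_HAND = 500.125853771


class TestRoster:
    def test_packaged_roster_has_31_chemicals(self, roster):
        assert len(roster) == 31

    def test_roster_dtxsids_unique_and_populated(self, roster):
        ids = [r.dtxsid for r in roster]
        assert len(set(ids)) == 31
        assert all(r.casrn and r.name and r.abbreviation for r in roster)

    def test_empty_file_with_header_gives_empty_roster(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("dtxsid,casrn,name,abbreviation\n")
        assert load_roster(p) == []

    def test_duplicate_dtxsid_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "dtxsid,casrn,name,abbreviation\n"
            "DTXSID8031865,335-67-1,Perfluorooctanoic acid,PFOA\n"
            "DTXSID8031865,335-67-1,Perfluorooctanoic acid,PFOA\n"
        )
        with pytest.raises(ValidationError, match="DTXSID8031865"):
            load_roster(p)

    def test_missing_required_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("dtxsid,casrn,name\nX,1,foo\n")
        with pytest.raises(SchemaError, match="abbreviation"):
            load_roster(p)

    def test_nonpositive_rb2p_rejected(self):
        with pytest.raises(ValidationError):
            ChemicalRecord("X", "1", "n", "a", rb2p_predicted=-0.5)

    def test_measured_rb2p_takes_precedence_over_predicted(self):
        chem = ChemicalRecord("X", "1", "n", "a", rb2p_predicted=0.6, rb2p_measured=0.9)
        assert chem.effective_rb2p() == (0.9, "measured_in_vivo")
        chem2 = ChemicalRecord("X", "1", "n", "a", rb2p_predicted=0.6)
        assert chem2.effective_rb2p() == (0.6, "in_vitro_predicted")


class TestMolecularWeight:
    @pytest.mark.parametrize(
        "formula,expected,tol",
        [
            ("H2O", 18.015, 0.01),
            ("C8HF15O2", PFOA_MW_HAND, 1e-9),
            ("C8HF17O3S", PFOS_MW_HAND, 1e-9),
        ],
    )
    def test_hand_summed_weights(self, formula, expected, tol):
        assert molecular_weight(formula) == pytest.approx(expected, abs=tol)

    def test_agrees_with_rdkit_on_whole_roster(self, roster):
        """Independent cross-check: rdkit's average MW from the structure."""
        from rdkit import Chem
        from rdkit.Chem import Descriptors

        for rec in roster:
            mol = Chem.MolFromSmiles(rec.smiles)
            assert mol is not None, rec.abbreviation
            assert molecular_weight(rec.formula) == pytest.approx(
                Descriptors.MolWt(mol), abs=0.05
            ), rec.abbreviation

    def test_salt_formula_with_dot_component(self):
        # ammonium perfluorooctanoate = anion + NH4
        assert molecular_weight("C8F15O2.H4N") == pytest.approx(
            molecular_weight("C8F15O2") + molecular_weight("H4N"), abs=1e-9
        )

    @pytest.mark.parametrize("bad", ["Xx2O", "C8H?", "", "c8"])
    def test_unparseable_formula_raises(self, bad):
        with pytest.raises(ValueError):
            molecular_weight(bad)


class TestUnitConversion:
    def test_unit_identity(self):
        assert molar_to_mass(1.0, 1000.0) == 1000.0
        assert molar_to_mass(0.0, 123.4) == 0.0

    def test_pfoa_micromolar_in_ngml(self):
        assert molar_to_mass(1.0, PFOA_MW_HAND) == pytest.approx(414.06, abs=0.05)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            molar_to_mass(-1.0, 100.0)
        with pytest.raises(ValueError):
            mass_to_molar(-1.0, 100.0)

    @settings(deadline=None, derandomize=True)
    @given(
        x=st.floats(min_value=0, max_value=1e9, allow_nan=False),
        mw=st.floats(min_value=1e-3, max_value=1e4, allow_nan=False),
    )
    def test_round_trip_and_linearity(self, x, mw):
        assert mass_to_molar(molar_to_mass(x, mw), mw) == pytest.approx(x, rel=1e-12)
        assert molar_to_mass(3 * x, mw) == pytest.approx(3 * molar_to_mass(x, mw), rel=1e-12)
        assert molar_to_mass(x, 2 * mw) == pytest.approx(2 * molar_to_mass(x, mw), rel=1e-12)


class TestChainLength:
    @pytest.mark.parametrize(
        "abbr,expected",
        [
            ("PFOA", 7),  # carboxyl carbon carries no F, excluded
            ("PFOS", 8),
            ("PFBS", 4),
            ("PFHxS", 6),
            ("PFTeDA", 13),
            ("5:3 PFOA", 5),  # telomer: only the perfluorinated block counts
        ],
    )
    def test_known_pfas_counts(self, roster_idx, abbr, expected):
        rec = next(r for r in roster_idx.values() if r.abbreviation == abbr)
        assert chain_length(rec.smiles) == expected

    def test_no_fluorine_means_zero(self):
        assert chain_length("CC") == 0
        assert chain_length("OC(=O)CCCCC") == 0

    def test_missing_structure_gives_missing_marker_not_zero(self):
        assert chain_length(None) is None

    def test_unparseable_structure_raises(self):
        with pytest.raises(ValueError):
            chain_length("not-a-structure(((")

    def test_invariant_under_smiles_rewriting(self, roster):
        """Canonicalization must not change the count (structure property)."""
        from rdkit import Chem

        for rec in roster[:8]:
            mol = Chem.MolFromSmiles(rec.smiles)
            canonical = Chem.MolToSmiles(mol)
            randomized = Chem.MolToSmiles(mol, doRandom=False, rootedAtAtom=mol.GetNumAtoms() - 1)
            assert chain_length(canonical) == chain_length(rec.smiles)
            assert chain_length(randomized) == chain_length(rec.smiles)

    @pytest.mark.parametrize("n", range(4, 13))
    def test_perfluoro_acid_chain_is_n_minus_1_vs_bruteforce(self, n):
        """A fully fluorinated n-carbon acid has chain length n-1; checked
        against an independent brute-force path enumeration over all carbons."""
        smiles = "OC(=O)" + "C(F)(F)" * (n - 2) + "C(F)(F)F"
        assert chain_length(smiles) == n - 1

        # brute-force oracle: enumerate all simple paths over CF-qualifying
        # carbons using networkx, independent of the implementation's DFS
        import networkx as nx
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        g = nx.Graph()
        qual = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetSymbol() == "C"
            and a.GetTotalNumHs() == 0
            and any(nb.GetSymbol() == "F" for nb in a.GetNeighbors())
        ]
        g.add_nodes_from(qual)
        for b in mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i in g and j in g:
                g.add_edge(i, j)
        longest = max(
            (len(path) for src in g for dst in g
             for path in nx.all_simple_paths(g, src, dst)),
            default=1 if qual else 0,
        )
        assert chain_length(smiles) == longest
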