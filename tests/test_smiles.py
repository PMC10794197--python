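import pytest
from rdkit import Chem

from tadfminer.errors import ConfigurationError, SmilesParseError
from tadfminer.smiles import (LookupBackend, count_aromatic_rings,
                              count_carbons, get_backend, name_to_smiles,
                              passes_structure_filter)

# 50-molecule oracle fixture: aromatic-form SMILES written with one ring
# closure per ring (the supported writing for closure-pair counting).
ORACLE_SMILES = [
    "c1ccccc1", "Cc1ccccc1", "c1ccc2ccccc2c1", "c1ccc2cc3ccccc3cc2c1",
    "c1cc2ccc3cccc4ccc(c1)c2c34", "c1ccc2c(c1)[nH]c1ccccc12",
    "c1ccc(N(c2ccccc2)c3ccccc3)cc1", "c1ccc(-c2ccccc2)cc1",
    "CCO", "CC(C)=O", "ClC(Cl)=O", "CCN(CC)CC", "C1CCCCC1", "C1CCOC1",
    "Cc1ccccc1C", "COc1ccccc1", "Nc1ccccc1", "Oc1ccccc1", "Clc1ccccc1",
    "Brc1ccccc1", "Sc1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
    "c1cnc2ccccc2c1", "N#Cc1ccccc1", "O=C(O)c1ccccc1",
    "CC(=O)Oc1ccccc1C(=O)O", "c1ccc(-c2ccc(-c3ccccc3)cc2)cc1",
    "c1ccc(N(c2ccccc2)c2ccc(-c3ccccc3)cc2)cc1",
    "N#Cc1c(n2c3ccccc3c3ccccc32)c(n2c3ccccc3c3ccccc32)c(C#N)"
    "c(n2c3ccccc3c3ccccc32)c1n1c2ccccc2c2ccccc21",
    "N#Cc1ccc(n2c3ccccc3c3ccccc32)c(n2c3ccccc3c3ccccc32)c1C#N",
    "CN1c2ccccc2C(C)(C)c2ccc(-c3ccc4ccccc4c3)cc21",
    "O=S(=O)(c1ccccc1)c1ccccc1", "FC(F)(F)c1ccccc1",
    "c1ccc(Oc2ccccc2)cc1", "c1ccc(Sc2ccccc2)cc1", "c1ccc(Cc2ccccc2)cc1",
    "CC1(C)c2ccccc2Oc2ccccc21", "c1ccc2oc3ccccc3c2c1", "c1ccc2sc3ccccc3c2c1",
    "c1ccc2c(c1)oc1ccccc12", "Cn1c2ccccc2c2ccccc21", "O=c1c2ccccc2oc2ccccc12",
    "c1ccc(-n2c3ccccc3c3ccccc32)cc1", "CC(C)(c1ccccc1)c1ccccc1",
    "N#Cc1cc(C#N)cc(C#N)c1", "c1cnc2[nH]c3ccccc3c2c1", "CSc1ccccc1",
]


def rdkit_counts(smi):
    mol = Chem.MolFromSmiles(smi)
    assert mol is not None, smi
    n_carbons = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
    ring_info = mol.GetRingInfo()
    n_aromatic = sum(
        1 for ring in ring_info.BondRings()
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring))
    return n_carbons, n_aromatic


class TestCounting:
    @pytest.mark.parametrize("smi,carbons", [
        ("c1ccccc1", 6), ("CCO", 2), ("ClC(Cl)=O", 1), ("[CH4]", 1),
        ("[13CH4]", 1), ("[Si](C)(C)C", 3),
    ])
    def test_carbon_examples(self, smi, carbons):
        assert count_carbons(smi) == carbons

    @pytest.mark.parametrize("smi,rings", [
        ("c1ccccc1", 1), ("c1ccc2ccccc2c1", 2), ("CCO", 0),
        ("C1CCCCC1", 0),  # aliphatic ring is not aromatic
        ("c1ccc(-c2ccccc2)cc1", 2),
    ])
    def test_aromatic_ring_examples(self, smi, rings):
        assert count_aromatic_rings(smi) == rings

    def test_fifty_molecule_oracle_agreement(self):
        assert len(ORACLE_SMILES) == 50
        for smi in ORACLE_SMILES:
            assert (count_carbons(smi), count_aromatic_rings(smi)) \
                == rdkit_counts(smi), smi

    @pytest.mark.parametrize("bad", ["c1ccccc", "C(C", "[C", "c1ccccc1c2"])
    def test_malformed_smiles_raise(self, bad):
        with pytest.raises(SmilesParseError):
            count_carbons(bad) if "[" in bad or "(" in bad else count_aromatic_rings(bad)


class TestStructureFilter:
    def test_benzene_dropped(self):
        assert passes_structure_filter("c1ccccc1") is False

    def test_large_polycycle_kept(self):
        # 4CzIPN: 56 carbons, 13 aromatic rings
        smi = ORACLE_SMILES[31]
        assert count_carbons(smi) >= 24 and count_aromatic_rings(smi) >= 5
        assert passes_structure_filter(smi) is True

    def test_conjunctive_keeps_single_criterion_molecules(self):
        # 30 carbons but only 2 aromatic rings: kept under the AND reading
        smi = "C" * 18 + "c1ccc(-c2ccccc2)cc1"  # 18 chain C + biphenyl (12 C)
        assert count_carbons(smi) == 30 and count_aromatic_rings(smi) == 2
        assert passes_structure_filter(smi, conjunctive=True) is True
        assert passes_structure_filter(smi, conjunctive=False) is False

    def test_monotone_in_counts(self):
        # appending carbons to a dropped molecule never re-drops a kept one
        base = "c1ccccc1"
        assert not passes_structure_filter(base)
        grown = "C" * 24 + base
        assert passes_structure_filter(grown)


class TestNameResolution:
    def test_lookup_examples(self):
        backend = LookupBackend()
        assert name_to_smiles("benzene", backend).text == "c1ccccc1"
        assert name_to_smiles("toluene", backend).text == "Cc1ccccc1"

    def test_unresolvable_name_is_none(self):
        assert name_to_smiles("blue emitter 3a", LookupBackend()) is None

    def test_missing_backend_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            name_to_smiles("benzene", None)
        with pytest.raises(ConfigurationError):
            get_backend("opsin-cloud")

    def test_determinism(self):
        backend = LookupBackend()
        assert (name_to_smiles("carbazole", backend)
                == name_to_smiles("carbazole", backend))

    def test_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "table.tsv"
        path.write_text("benzene\tc1ccccc1\n", encoding="utf-8")
        assert LookupBackend.from_tsv(path).resolve("Benzene") == "c1ccccc1"
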