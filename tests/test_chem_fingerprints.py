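"""Standardization and base-fingerprint behavior."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from ppb import (
    BASE_SCHEMES,
    SCHEME_DIMS,
    ChemError,
    Scheme,
    StandardizationOptions,
    compute_apfp,
    compute_ecfp4,
    compute_mqn,
    compute_profile,
    compute_profiles,
    compute_sfp,
    compute_smifp,
    compute_xfp,
    standardize,
)
from ppb.chem_fingerprints import tokenize_smiles

NO_ION = StandardizationOptions(ionize=False)


class TestStandardize:
    def test_stereo_markers_removed(self):
        mol = standardize("C[C@H](N)C(=O)O")
        assert "@" not in mol.canonical_smiles
        assert "/" not in mol.canonical_smiles

    def test_kekule_and_aromatic_benzene_agree(self):
        # oracle: both spellings canonicalize to RDKit's aromatic form
        expected = Chem.MolToSmiles(Chem.MolFromSmiles("c1ccccc1"))
        assert standardize("C1=CC=CC=C1").canonical_smiles == expected
        assert standardize("c1ccccc1").canonical_smiles == expected

    def test_canonicalization_idempotent(self):
        for smi in ["CC(=O)O", "CCN", "NC(=N)N", "c1ccc2[nH]ccc2c1", "OC(=O)c1ccccc1O"]:
            once = standardize(smi).canonical_smiles
            assert standardize(once).canonical_smiles == once

    def test_ph74_ionization_rules(self):
        assert standardize("CC(=O)O").canonical_smiles == "CC(=O)[O-]"
        assert standardize("CCN").canonical_smiles == "CC[NH3+]"
        # amide N is not a basic amine, aromatic N untouched
        assert "+" not in standardize("CC(=O)NC").canonical_smiles
        assert "+" not in standardize("c1ccncc1").canonical_smiles

    def test_ionization_off(self):
        assert standardize("CC(=O)O", NO_ION).canonical_smiles == "CC(=O)O"

    @pytest.mark.parametrize("bad", ["not_a_smiles", "", "   ", "C1CC"])
    def test_invalid_input_raises(self, bad):
        with pytest.raises(ChemError):
            standardize(bad)


def _brute_force_apfp(smiles: str) -> np.ndarray:
    """Independent oracle: all-pairs shortest paths by BFS on the bond graph."""
    mol = Chem.MolFromSmiles(smiles)
    n = mol.GetNumAtoms()
    adj = {i: [] for i in range(n)}
    for b in mol.GetBonds():
        adj[b.GetBeginAtomIdx()].append(b.GetEndAtomIdx())
        adj[b.GetEndAtomIdx()].append(b.GetBeginAtomIdx())
    counts = np.zeros(21, dtype=int)
    for src in range(n):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for tgt, d in dist.items():
            if tgt > src and d >= 1:
                counts[min(d, 21) - 1] += 1
    return counts


class TestAPfp:
    def test_methane_all_zero(self):
        assert compute_apfp(standardize("C")).values.sum() == 0

    def test_ethane_single_pair(self):
        v = compute_apfp(standardize("CC")).values
        assert v[0] == 1 and v.sum() == 1

    @pytest.mark.parametrize(
        "smiles", ["CCCCCC", "c1ccccc1", "CC(C)CC1CCCCC1", "O=C(O)c1ccccc1OC(C)=O"]
    )
    def test_matches_bfs_oracle(self, smiles):
        mol = standardize(smiles, NO_ION)
        assert np.array_equal(
            compute_apfp(mol).values, _brute_force_apfp(mol.canonical_smiles)
        )

    def test_hexane_explicit(self):
        v = compute_apfp(standardize("CCCCCC")).values
        assert list(v[:5]) == [5, 4, 3, 2, 1] and v[5:].sum() == 0


class TestXfp:
    def test_methane_all_zero(self):
        assert compute_xfp(standardize("C")).values.sum() == 0

    def test_ethanol_channels(self):
        # hand enumeration: pairs (C,C)=d1, (C,O)=d1,d2; O is HBA and HBD but
        # has no same-category partner
        v = compute_xfp(standardize("CCO", NO_ION)).values
        assert list(v[:2]) == [2, 1] and v[2:11].sum() == 0
        assert v[11:22].sum() == 0  # HBA-HBA
        assert v[22:33].sum() == 0  # HBD-HBD

    def test_benzene_aromatic_channel_equals_any(self):
        v = compute_xfp(standardize("c1ccccc1")).values
        assert np.array_equal(v[:11], v[44:])

    @pytest.mark.parametrize("smiles", ["CCCCCC", "c1ccc2[nH]ccc2c1", "CC(=O)Nc1ccccc1"])
    def test_any_channel_matches_apfp(self, smiles):
        mol = standardize(smiles, NO_ION)
        assert np.array_equal(
            compute_xfp(mol).values[:10], compute_apfp(mol).values[:10]
        )


class TestMQN:
    def test_methane_semantics(self):
        v = compute_mqn(standardize("C")).values
        assert v.shape == (42,)
        assert v[0] == 1  # carbon count
        assert v[-10:].sum() == 0  # ring-feature block empty for methane

    def test_spelling_invariance(self):
        a = compute_mqn(standardize("OCC")).values
        b = compute_mqn(standardize("CCO")).values
        assert np.array_equal(a, b)


class TestSMIfp:
    def test_single_carbon(self):
        v = compute_smifp(standardize("C")).values
        assert v.sum() == 1 and v[0] == 1

    def test_acetic_acid_counts(self):
        from ppb.chem_fingerprints import SMIFP_ALPHABET

        mol = standardize("CC(=O)O", NO_ION)
        assert mol.canonical_smiles == "CC(=O)O"
        v = compute_smifp(mol).values
        idx = {s: i for i, s in enumerate(SMIFP_ALPHABET)}
        expected = {"C": 2, "O": 2, "(": 1, ")": 1, "=": 1}
        for sym, n in expected.items():
            assert v[idx[sym]] == n
        assert v.sum() == sum(expected.values())

    def test_chlorine_tokenized_before_carbon(self):
        assert tokenize_smiles("CCl") == ["C", "Cl"]
        v = compute_smifp(standardize("CCl"))
        assert v.values[0] == 1  # one aliphatic C, not two


class TestBinaryFingerprints:
    def test_sfp_binary_and_deterministic(self):
        mol = standardize("CC(=O)Nc1ccc(O)cc1")
        a, b = compute_sfp(mol).values, compute_sfp(mol).values
        assert np.array_equal(a, b)
        assert set(np.unique(a)) <= {0, 1}

    def test_sfp_path_count_grows_with_size(self):
        small = compute_sfp(standardize("C")).values.sum()
        large = compute_sfp(standardize("CCCCCCCC")).values.sum()
        assert small < large

    def test_ecfp4_benzene_symmetry(self):
        # one unique atom environment per radius 0..2
        assert compute_ecfp4(standardize("c1ccccc1")).values.sum() <= 3

    def test_ecfp4_deterministic(self):
        mol = standardize("CN1CCC[C@H]1c1cccnc1")
        assert np.array_equal(compute_ecfp4(mol).values, compute_ecfp4(mol).values)


class TestProfile:
    def test_dimensions(self):
        prof = compute_profile(standardize("CC(=O)Nc1ccc(O)cc1"))
        for scheme in BASE_SCHEMES:
            assert len(prof[scheme]) == SCHEME_DIMS[scheme]

    def test_methane_profile(self):
        prof = compute_profile(standardize("C"))
        assert prof[Scheme.APfp].values.sum() == 0
        assert prof[Scheme.Xfp].values.sum() == 0
        assert prof[Scheme.MQN].values[0] == 1

    def test_spelling_invariance_all_schemes(self):
        a = compute_profile(standardize("c1ccccc1CO"))
        b = compute_profile(standardize("OCc1ccccc1"))
        for scheme in BASE_SCHEMES:
            assert np.array_equal(a[scheme].values, b[scheme].values), scheme

    def test_batch_preserves_order(self):
        mols = [standardize(s, mol_id=s) for s in ("C", "CC", "CCC")]
        profs = compute_profiles(mols)
        assert [p.molecule_id for p in profs] == ["C", "CC", "CCC"]

    def test_zero_heavy_atom_molecule_rejected(self):
        with pytest.raises(ChemError):
            compute_apfp(standardize("[H][H]", NO_ION))
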