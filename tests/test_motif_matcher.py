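import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pdbinder.library_builder import ResidueLibrary
from pdbinder.motif_matcher import (ParamConfig, enumerate_triplets,
                                    kabsch_rmsd, match_structure,
                                    write_matches_tsv)
from pdbinder.structure_model import ensure_representations
from tests.conftest import brute_force_matches, grid_search_rmsd, make_residue


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


class TestKabschRmsd:
    def test_identity_is_zero(self):
        a = np.random.default_rng(0).uniform(-5, 5, size=(4, 3))
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(-5, 5, size=(6, 3))
        b = a @ _random_rotation(rng).T + rng.uniform(-20, 20, size=3)
        assert kabsch_rmsd(a, b) < 1e-9

    def test_reflection_not_superposable(self):
        # a chiral point set and its mirror image cannot superpose with a
        # proper rotation
        a = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]])
        b = a.copy()
        b[:, 2] *= -1
        assert kabsch_rmsd(a, b) > 0.5

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.uniform(-4, 4, size=(4, 3))
            b = rng.uniform(-4, 4, size=(4, 3))
            assert kabsch_rmsd(a, b) == pytest.approx(
                grid_search_rmsd(a, b), abs=1e-3)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_collinear_points_handled(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        rng = np.random.default_rng(3)
        b = a @ _random_rotation(rng).T + [4, 5, 6]
        assert kabsch_rmsd(a, b) < 1e-9

    @given(st.integers(0, 1000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        a = rng.uniform(-5, 5, size=(n, 3))
        b = rng.uniform(-5, 5, size=(n, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-9)


class TestEnumerateTriplets:
    def test_single_clique(self):
        residues = [make_residue("A", i + 1, "ALA", [4.0 * i, 0, 0])
                    for i in range(3)]
        assert len(enumerate_triplets(residues)) == 1

    def test_path_connectivity_suffices(self):
        # A-B-C with d(A,B)=d(B,C)=6 but d(A,C)=11: connected via the path
        residues = [make_residue("A", 1, "ALA", [0, 0, 0]),
                    make_residue("A", 2, "GLY", [6.0, 0, 0]),
                    make_residue("A", 3, "SER", [6.0 + np.sqrt(36 - 11), 0, 0])]
        d_ac = np.linalg.norm(residues[2].ca - residues[0].ca)
        assert d_ac > 7.5
        assert len(enumerate_triplets(residues)) == 1

    def test_disconnected_pair_rejected(self):
        residues = [make_residue("A", 1, "ALA", [0, 0, 0]),
                    make_residue("A", 2, "GLY", [6.0, 0, 0]),
                    make_residue("A", 3, "SER", [30.0, 0, 0])]
        assert enumerate_triplets(residues) == []

    def test_matches_brute_force_over_random_box(self):
        from itertools import combinations
        rng = np.random.default_rng(9)
        residues = [make_residue("A", i + 1, "ALA",
                                 rng.uniform(0, 30, size=3), rng=rng)
                    for i in range(10)]
        got = {t.keys for t in enumerate_triplets(residues)}
        expected = set()
        for combo in combinations(residues, 3):
            cas = [r.ca for r in combo]
            edges = sum(np.linalg.norm(cas[i] - cas[j]) < 7.5
                        for i in range(3) for j in range(i + 1, 3))
            if edges >= 2:
                expected.add(tuple(r.key for r in combo))
        assert got == expected


def _library_of(triplet_coord_sets, aa_types, binding=True):
    """Each entry: a (3, CA-position) list; residues get noise-free atoms."""
    lib = ResidueLibrary()
    for idx, cas in enumerate(triplet_coord_sets):
        residues = []
        for k, (aa, ca) in enumerate(zip(aa_types, cas)):
            r = make_residue("L", k + 1, aa, ca)
            r.is_binding = binding
            residues.append(r)
        ensure_representations(residues)
        lib.add_chain(f"lib{idx}", f"cl{idx}", residues)
    return lib


class TestMatchStructure:
    def _query(self, aa_types=("ALA", "GLY", "SER")):
        residues = [make_residue("A", i + 1, aa, [4.0 * i, 0.5 * i, 0])
                    for i, aa in enumerate(aa_types)]
        ensure_representations(residues)
        return residues

    def test_self_similarity(self):
        query = self._query()
        lib = _library_of([[r.ca for r in query]], [r.aa_type for r in query])
        matches = match_structure(query, lib)
        assert len(matches) == 1
        assert matches[0].rmsd == pytest.approx(0.0, abs=1e-9)

    def test_cluster_exclusion(self):
        query = self._query()
        lib = _library_of([[r.ca for r in query]], [r.aa_type for r in query])
        assert match_structure(query, lib, exclusion={"cl0"}) == []

    def test_planted_two_of_four(self):
        rng = np.random.default_rng(4)
        query = self._query()
        q_cas = [r.ca for r in query]
        sets = [
            [c + rng.normal(0, 0.05, 3) for c in q_cas],   # close copy
            [c + rng.normal(0, 0.08, 3) for c in q_cas],   # close copy
            [c + np.array([0, 0, 3.0]) * (i == 1) for i, c in enumerate(q_cas)],
            [c + np.array([3.0, -3.0, 2.0]) * (i % 2) for i, c in enumerate(q_cas)],
        ]
        lib = _library_of(sets, [r.aa_type for r in query])
        # independent verification of which candidates are under the cutoff
        cfg = ParamConfig()
        q_rep = np.concatenate([r.rep_coords for r in query])
        under = []
        for chain_key, (_, lres) in lib.chains().items():
            l_rep = np.concatenate([r.rep_coords for r in lres])
            under.append(grid_search_rmsd(q_rep, l_rep) < cfg.rmsd_max)
        assert sum(under) == 2
        matches = match_structure(query, lib, cfg)
        assert len(matches) == 2

    def test_repeated_types_single_match_per_pair(self):
        query = self._query(("GLY", "GLY", "THR"))
        lib = _library_of([[r.ca for r in query]], ["GLY", "GLY", "THR"])
        matches = match_structure(query, lib)
        assert len(matches) == 1
        assert matches[0].rmsd == pytest.approx(0.0, abs=1e-9)
        assert all(a.aa_type == b.aa_type for a, b in matches[0].residue_pairing)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(8)
        query = self._query()
        q_cas = [r.ca for r in query]
        sets = [[c + rng.normal(0, s, 3) for c in q_cas]
                for s in (0.02, 0.1, 0.2, 0.3, 0.5)]
        lib = _library_of(sets, [r.aa_type for r in query])
        tight = {(m.query_triplet.keys, m.library_triplet.keys)
                 for m in match_structure(query, lib, ParamConfig(rmsd_max=0.5))}
        loose = {(m.query_triplet.keys, m.library_triplet.keys)
                 for m in match_structure(query, lib, ParamConfig(rmsd_max=0.7))}
        assert tight <= loose

    def test_deterministic_serialization(self, tmp_path):
        rng = np.random.default_rng(5)
        query = [make_residue("A", i + 1, aa, rng.uniform(0, 12, 3), rng=rng)
                 for i, aa in enumerate(["ALA", "GLY", "SER", "ALA", "THR"])]
        ensure_representations(query)
        sets = [[r.ca + rng.normal(0, 0.1, 3) for r in query[:3]]]
        lib = _library_of(sets, [r.aa_type for r in query[:3]])
        texts = []
        for run in range(2):
            out = tmp_path / f"m{run}.tsv"
            write_matches_tsv(match_structure(query, lib), out)
            texts.append(out.read_bytes())
        assert texts[0] == texts[1]


def test_matches_equal_brute_force_oracle():
    """Random small instances: matcher output equals exhaustive search."""
    cfg = ParamConfig()
    alphabet = ["ALA", "GLY", "SER", "THR", "VAL"]
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(8, 13))
        query = [make_residue("Q", i + 1, alphabet[rng.integers(len(alphabet))],
                              rng.uniform(0, 25, 3), rng=rng) for i in range(n)]
        ensure_representations(query)
        lib = ResidueLibrary()
        lres = []
        for i in range(n):
            src = query[rng.integers(n)]
            r = make_residue("L", i + 1, src.aa_type,
                             src.ca + rng.normal(0, 0.4, 3), rng=rng)
            r.is_binding = bool(rng.integers(2))
            lres.append(r)
        ensure_representations(lres)
        lib.add_chain("libchain", "c0", lres)
        got = {(m.query_triplet.keys, m.library_triplet.keys): m.rmsd
               for m in match_structure(query, lib, cfg)}
        expected = brute_force_matches(query, lib, cfg)
        assert set(got) == set(expected)
        for k in got:
            assert got[k] == pytest.approx(expected[k], abs=1e-9)
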