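"""Path fingerprints: generation conditions, Tanimoto laws, index search."""

import itertools

import numpy as np
import pytest

from drift.chemio import read_molecule
from drift.fingerprint2d import (
    IGNORED_SINGLETONS,
    MAX_PATH_ATOMS,
    N_BITS,
    Fingerprint2D,
    SimilarityHit,
    _ring_systems,
    build_index,
    enumerate_paths,
    fingerprint,
    hash_fragment,
    path_descriptor,
    search_2d,
    tanimoto,
)


def oracle_paths(mol, ring_termination="ring-system"):
    """Independent enumerator: generate ALL simple paths of <= 7 heavy atoms,
    then filter post-hoc.

    Ring-system rule checked as a whole-path property: the positions of each
    ring system's atoms must be contiguous along the path.  Closure rule:
    no atom may be bonded to a non-adjacent path member.
    """
    heavy = [i for i in range(mol.n_atoms) if mol.atoms[i].element != "H"]
    adj = {i: [j for j in mol.neighbors(i) if j in heavy] for i in heavy}
    systems = _ring_systems(mol)

    def all_simple_paths():
        out = []

        def rec(path):
            out.append(tuple(path))
            if len(path) == MAX_PATH_ATOMS:
                return
            for nxt in adj[path[-1]]:
                if nxt not in path:
                    path.append(nxt)
                    rec(path)
                    path.pop()

        for s in heavy:
            rec([s])
        return out

    def valid(path):
        if len(path) == 1 and mol.atoms[path[0]].element in IGNORED_SINGLETONS:
            return False
        if ring_termination == "ring-system":
            for sysid in {systems.get(a) for a in path} - {None}:
                pos = [k for k, a in enumerate(path) if systems.get(a) == sysid]
                if pos != list(range(pos[0], pos[-1] + 1)):
                    return False
            return True
        for k, a in enumerate(path):
            for later in path[k + 2 :]:
                if later in adj[a]:
                    return False
        return True

    return {path_descriptor(mol, p) for p in all_simple_paths() if valid(p)}


class TestEnumerationConditions:
    def test_methane_single_carbon_ignored(self):
        assert enumerate_paths(read_molecule("C")) == []

    def test_sulfur_singleton_kept(self):
        paths = enumerate_paths(read_molecule("S"))
        assert len(paths) == 1

    def test_ethanol_paths(self, ethanol):
        descs = {path_descriptor(ethanol, p) for p in enumerate_paths(ethanol)}
        assert descs == {"C|[1]|C", "C|[1]|O", "C|[1]|C|[1]|O"}

    @pytest.mark.parametrize("ring_termination", ["ring-system", "closure"])
    def test_matches_independent_enumerator(self, random_molecules, ring_termination):
        for mol in random_molecules:
            got = {
                path_descriptor(mol, p)
                for p in enumerate_paths(mol, ring_termination=ring_termination)
            }
            assert got == oracle_paths(mol, ring_termination), mol.mol_id

    def test_no_path_exceeds_seven_atoms(self, random_molecules):
        for mol in random_molecules:
            fp = fingerprint(mol)
            assert all(1 <= len(p) <= 7 for p, _ in fp.fragments)

    def test_duplicate_descriptors_reported_once(self, benzene):
        descs = [path_descriptor(benzene, p) for p, _ in fingerprint(benzene).fragments]
        assert len(descs) == len(set(descs))


class TestHashing:
    def test_deterministic(self):
        assert hash_fragment("C|[1]|O") == hash_fragment("C|[1]|O")

    def test_reverse_direction_same_descriptor(self, ethanol):
        p = (0, 1, 2)
        assert path_descriptor(ethanol, p) == path_descriptor(ethanol, p[::-1])

    def test_hash_in_range(self):
        for desc in ("C", "S|[2]|C", "N|[aromatic]|C|[1]|O"):
            assert 0 <= hash_fragment(desc) < N_BITS

    def test_distinct_descriptors_for_distinct_bonds(self):
        d1 = path_descriptor(read_molecule("CC"), (0, 1))
        d2 = path_descriptor(read_molecule("C=C"), (0, 1))
        assert d1 != d2


class TestFingerprint:
    def test_length_is_1024(self, caffeine):
        assert len(fingerprint(caffeine).bits) == 1024

    def test_methane_all_zero(self):
        assert fingerprint(read_molecule("C")).n_set == 0

    def test_deterministic(self, caffeine):
        np.testing.assert_array_equal(
            fingerprint(caffeine).bits, fingerprint(caffeine).bits
        )

    def test_invariant_to_atom_permutation(self):
        # same molecule written with different atom orders
        a = fingerprint(read_molecule("OCC"))
        b = fingerprint(read_molecule("CCO"))
        np.testing.assert_array_equal(a.bits, b.bits)

    def test_hex_round_trip(self, caffeine):
        fp = fingerprint(caffeine)
        back = Fingerprint2D.from_hex(fp.hex(), fp.build_params)
        np.testing.assert_array_equal(fp.bits, back.bits)


class TestTanimoto:
    def test_self_similarity_is_one(self, caffeine):
        fp = fingerprint(caffeine)
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_fingerprints_are_zero(self):
        a = np.zeros(N_BITS, np.uint8)
        b = np.zeros(N_BITS, np.uint8)
        a[:4] = 1
        b[10:16] = 1
        assert tanimoto(Fingerprint2D(bits=a), Fingerprint2D(bits=b)) == 0.0

    def test_direct_formula(self):
        # a=4, b=6, c=3 -> 3/7
        a = np.zeros(N_BITS, np.uint8)
        b = np.zeros(N_BITS, np.uint8)
        a[[0, 1, 2, 3]] = 1
        b[[1, 2, 3, 10, 11, 12]] = 1
        assert tanimoto(Fingerprint2D(bits=a), Fingerprint2D(bits=b)) == pytest.approx(3 / 7)

    def test_symmetry_and_bounds(self, random_molecules):
        fps = [fingerprint(m) for m in random_molecules[:12]]
        for fa, fb in itertools.combinations(fps, 2):
            t1, t2 = tanimoto(fa, fb), tanimoto(fb, fa)
            assert t1 == t2
            assert 0.0 <= t1 <= 1.0

    def test_empty_vs_empty_is_one_with_warning(self):
        empty = Fingerprint2D(bits=np.zeros(N_BITS, np.uint8))
        with pytest.warns(UserWarning):
            assert tanimoto(empty, empty) == 1.0

    def test_mismatched_params_rejected(self, caffeine, ethanol):
        fa = fingerprint(caffeine)
        fb = fingerprint(ethanol, ring_termination="closure")
        with pytest.raises(ValueError):
            tanimoto(fa, fb)


class TestTanimotoProperties:
    """Algebraic laws over arbitrary bit sets."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    bitsets = st.sets(st.integers(min_value=0, max_value=N_BITS - 1), max_size=64)

    @staticmethod
    def fp(positions):
        bits = np.zeros(N_BITS, np.uint8)
        bits[list(positions)] = 1
        return Fingerprint2D(bits=bits)

    @given(a=bitsets, b=bitsets)
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_bounds_symmetry_identity(self, a, b):
        import warnings

        fa, fb = self.fp(a), self.fp(b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = tanimoto(fa, fb)
            assert 0.0 <= t <= 1.0
            assert t == tanimoto(fb, fa)
            assert tanimoto(fa, fa) == 1.0
            if a and b and not (a & b):
                assert t == 0.0


class TestIndex:
    def test_build_and_size(self, random_molecules):
        idx = build_index(random_molecules)
        assert len(idx) == len(random_molecules)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            build_index([])

    def test_duplicate_ids_rejected(self, ethanol):
        dup = read_molecule("CCO", mol_id="ethanol")
        with pytest.raises(ValueError, match="duplicate"):
            build_index([ethanol, dup])

    def test_save_load_round_trip(self, random_molecules, tmp_path):
        idx = build_index(random_molecules)
        path = str(tmp_path / "lib.fpidx")
        idx.save(path)
        from drift.fingerprint2d import FastIndex

        back = FastIndex.load(path)
        q = fingerprint(random_molecules[3])
        assert [(h.mol_id, h.tc) for h in search_2d(q, idx, 0.0)] == [
            (h.mol_id, h.tc) for h in search_2d(q, back, 0.0)
        ]


class TestSearch:
    def brute_force(self, query, mols, tc_min):
        hits = []
        for m in mols:
            tc = tanimoto(query, fingerprint(m))
            if tc >= tc_min:
                hits.append(SimilarityHit(mol_id=m.mol_id, tc=tc))
        hits.sort(key=lambda h: (-h.tc, h.mol_id))
        return hits

    @pytest.mark.parametrize("tc_min", [0.0, 0.3, 0.85, 1.0])
    def test_equals_brute_force_scan(self, random_molecules, tc_min):
        idx = build_index(random_molecules)
        for q in random_molecules[:8]:
            qfp = fingerprint(q)
            got = search_2d(qfp, idx, tc_min)
            want = self.brute_force(qfp, random_molecules, tc_min)
            assert [(h.mol_id, pytest.approx(h.tc)) for h in got] == [
                (h.mol_id, h.tc) for h in want
            ]

    def test_identical_query_ranks_first(self, random_molecules):
        idx = build_index(random_molecules)
        q = fingerprint(random_molecules[0])
        hits = search_2d(q, idx, 0.85)
        assert hits[0].tc == 1.0

    def test_tc_min_zero_returns_everything(self, random_molecules):
        idx = build_index(random_molecules)
        assert len(search_2d(fingerprint(random_molecules[0]), idx, 0.0)) == len(idx)
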