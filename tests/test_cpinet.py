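"""Interaction network: encodings, gradients, invariances, training."""

import numpy as np
import pytest

from drift.chemio import ProteinSeq, read_molecule
from drift.cpinet import (
    CPIModel,
    CPIPrediction,
    ModelConfig,
    TrainConfig,
    attention_fragments,
    encode_compound,
    encode_protein,
    train,
)
from drift.cpinet.encoding import BLOSUM_SCALE, positional_encoding
from drift.fragmenter import FragmentPartition, fragment

TINY = ModelConfig(hidden=16, pe_dim=8, seed=1)


def encode_pair(smiles, seq, mol_id="m", pe_dim=8):
    mol = read_molecule(smiles, mol_id=mol_id)
    part = fragment(mol)
    return encode_protein(ProteinSeq("p", seq), pe_dim=pe_dim), encode_compound(mol, part), mol, part


class TestEncodeProtein:
    def test_alanine_diagonal_value(self):
        enc = encode_protein(ProteinSeq("p", "A"))
        assert enc.matrix.shape[0] == 1
        assert enc.matrix[0, 0] == pytest.approx(4 * BLOSUM_SCALE)  # A->A diagonal

    def test_nonstandard_residue_zero_substitution(self):
        enc = encode_protein(ProteinSeq("p", "X"))
        assert np.all(enc.matrix[0, :20] == 0)
        assert np.any(enc.matrix[0, 20:] != 0)  # positional channels stay real

    def test_positional_channels_distinguish_order(self):
        ac = encode_protein(ProteinSeq("p", "AC"))
        ca = encode_protein(ProteinSeq("p", "CA"))
        sub_ac = {tuple(r) for r in ac.matrix[:, :20]}
        sub_ca = {tuple(r) for r in ca.matrix[:, :20]}
        assert sub_ac == sub_ca
        assert not np.allclose(ac.matrix, ca.matrix)

    def test_positional_encoding_shape_and_range(self):
        pe = positional_encoding(30, 8)
        assert pe.shape == (30, 8)
        assert np.all(np.abs(pe) <= 1.0)


class TestEncodeCompound:
    def test_ethanol_heavy_atom_fragments(self):
        _, enc, _, part = encode_pair("CCO", "MKV")
        assert enc.atom_features.shape[0] == 3
        assert enc.n_fragments == 3
        assert sorted(enc.fragment_map) == [0, 1, 2]

    def test_unknown_element_maps_to_other_slot(self):
        mol = read_molecule("[SiH4]", mol_id="silane")
        enc = encode_compound(mol, fragment(mol))
        assert enc.atom_features[0, 10] == 1.0  # "other" element slot

    def test_partition_mismatch_rejected(self, ethanol, benzene):
        part = fragment(benzene)
        with pytest.raises(ValueError):
            encode_compound(ethanol, part)

    def test_permuted_atom_order_permutes_encoding(self):
        a = read_molecule("OCC", mol_id="m")
        b = read_molecule("CCO", mol_id="m")
        ea = encode_compound(a, fragment(a))
        eb = encode_compound(b, fragment(b))
        # same multiset of atom rows
        assert sorted(map(tuple, ea.atom_features)) == sorted(map(tuple, eb.atom_features))


class TestForward:
    def test_attention_rows_normalized(self):
        p, c, _, _ = encode_pair("CC(=O)Oc1ccccc1C(=O)O", "MKVLAWHG" * 4)
        pred = CPIModel(TINY).forward(p, c)
        np.testing.assert_allclose(pred.attention.sum(axis=1), 1.0, atol=1e-5)
        assert np.all(pred.attention >= 0)

    def test_inference_deterministic(self):
        p, c, _, _ = encode_pair("CCO", "MKVLAW")
        model = CPIModel(TINY)
        assert model.forward(p, c).affinity == model.forward(p, c).affinity

    def test_score_in_unit_interval(self):
        p, c, _, _ = encode_pair("CCO", "MKVLAW")
        pred = CPIModel(TINY).forward(p, c)
        assert 0.0 <= pred.score <= 1.0

    def test_fragment_order_invariance_residue_order_sensitivity(self):
        model = CPIModel(TINY)
        mol = read_molecule("CCOc1ccccc1CN", mol_id="m")
        part = fragment(mol)
        p = encode_protein(ProteinSeq("p", "MKVLAWHGFE" * 3), pe_dim=8)
        c = encode_compound(mol, part)
        base = model.forward(p, c).affinity

        # permute fragment order (relabel fragments)
        rng = np.random.default_rng(3)
        perm = rng.permutation(c.n_fragments)
        c_perm = encode_compound(mol, FragmentPartition(
            mol_id=mol.mol_id,
            clusters=[part.clusters[i] for i in perm],
            cut_bonds=part.cut_bonds,
        ))
        assert model.forward(p, c_perm).affinity == pytest.approx(base, rel=1e-12)

        # permute residue order
        seq = list("MKVLAWHGFE" * 3)
        rng.shuffle(seq)
        p_perm = encode_protein(ProteinSeq("p", "".join(seq)), pe_dim=8)
        assert model.forward(p_perm, c).affinity != pytest.approx(base, rel=1e-9)

    def test_dimension_mismatch_raises(self):
        p, c, _, _ = encode_pair("CCO", "MKVLAW", pe_dim=16)
        with pytest.raises(ValueError, match="width"):
            CPIModel(TINY).forward(p, c)


class TestGradients:
    def test_numeric_vs_analytic(self):
        p, c, _, _ = encode_pair("CC(=O)NC", "MKVLAWHG" * 2)
        model = CPIModel(ModelConfig(hidden=8, pe_dim=8, seed=2))
        _, cache = model.forward(p, c, with_cache=True)
        grads = model.backward(1.0, cache)
        rng = np.random.default_rng(0)
        for name in sorted(model.params):
            flat = model.params[name].ravel()
            for _ in range(3):
                i = int(rng.integers(flat.size))
                eps, old = 1e-6, flat[i]
                flat[i] = old + eps
                up = model.forward(p, c).affinity
                flat[i] = old - eps
                dn = model.forward(p, c).affinity
                flat[i] = old
                num = (up - dn) / (2 * eps)
                ana = grads[name].ravel()[i]
                # 1e-4 relative with an absolute floor for near-zero gradients
                assert abs(num - ana) <= 1e-4 * max(abs(num), abs(ana)) + 1e-6, name


class TestTraining:
    def small_dataset(self, n=48, seed=0):
        from drift.synthdata import (
            SynthConfig,
            gen_affinity_data,
            gen_compound_library,
            gen_proteins,
        )

        cfg = SynthConfig(
            n_compounds=24, n_proteins=6, similarity_clusters=3, seed=seed, n_affinity=n
        )
        lib = gen_compound_library(cfg)
        prots, _ = gen_proteins(cfg)
        return gen_affinity_data(cfg, lib, prots)

    def test_loss_decreases(self):
        data = self.small_dataset()
        _, log = train(
            data,
            TrainConfig(batch_size=8, learning_rate=1e-3, epochs=8, seed=0),
            model_config=TINY,
        )
        assert log[-1].train_mse < log[0].train_mse

    def test_overfits_duplicated_example(self):
        data = self.small_dataset(n=4)
        dup = [data[0]] * 32
        _, log = train(
            dup,
            TrainConfig(batch_size=8, learning_rate=3e-3, epochs=30, seed=0),
            model_config=TINY,
        )
        assert log[-1].train_mse < 1e-2

    def test_split_ratio(self):
        from drift.benchmarks import split

        train_set, test_set = split(list(range(100)), ratio=0.8, seed=0)
        assert (len(train_set), len(test_set)) == (80, 20)

    def test_too_small_dataset_rejected(self):
        data = self.small_dataset(n=4)
        with pytest.raises(ValueError):
            train(data[:4], TrainConfig(batch_size=8, epochs=1))

    def test_nonfinite_affinity_rejected(self):
        data = self.small_dataset(n=20)
        mol, prot, _ = data[0]
        bad = data + [(mol, prot, float("nan"))]
        with pytest.raises(ValueError, match="finite"):
            train(bad, TrainConfig(batch_size=8, epochs=1))

    def test_checkpoint_round_trip(self, tmp_path):
        data = self.small_dataset()
        model, _ = train(
            data, TrainConfig(batch_size=8, epochs=1, seed=0), model_config=TINY
        )
        path = str(tmp_path / "model.npz")
        model.save(path)
        back = CPIModel.load(path)
        mol, prot, _ = data[0]
        assert back.predict(mol, prot).affinity == model.predict(mol, prot).affinity


class TestAttentionRanking:
    def planted_prediction(self, F, L, motif_frag, rng, peak=8.0):
        """Noisy attention map in which one fragment attends sharply to a
        high-salience residue block; the others are near-uniform."""
        attn = rng.uniform(0.5, 1.5, size=(F, L))
        sal = np.abs(rng.normal(1.0, 0.1, size=L))
        block = slice(L // 3, L // 3 + 4)
        attn[motif_frag, block] += peak
        sal[block] *= 2.0
        attn /= attn.sum(axis=1, keepdims=True)
        return CPIPrediction(affinity=7.0, score=0.7, attention=attn, residue_salience=sal)

    def partition(self, F):
        return FragmentPartition(
            mol_id="m", clusters=[frozenset([i]) for i in range(F)], cut_bonds=[]
        )

    def test_single_fragment_gets_weight_one(self):
        pred = CPIPrediction(
            affinity=5.0, score=0.3, attention=np.ones((1, 10)) / 10,
            residue_salience=np.ones(10),
        )
        assert attention_fragments(pred, self.partition(1)) == [(0, 1.0)]

    def test_uniform_attention_falls_back_to_index_order(self):
        pred = CPIPrediction(
            affinity=5.0, score=0.3, attention=np.ones((4, 10)) / 10,
            residue_salience=np.ones(10),
        )
        ranked = attention_fragments(pred, self.partition(4), statistic="uniform")
        assert [i for i, _ in ranked] == [0, 1, 2, 3]

    def test_planted_salient_fragment_recovered(self):
        rng = np.random.default_rng(21)
        hits = 0
        trials = 25
        for _ in range(trials):
            F, L = 6, 40
            motif = int(rng.integers(F))
            pred = self.planted_prediction(F, L, motif, rng)
            ranked = attention_fragments(pred, self.partition(F))
            if motif in [i for i, _ in ranked[:2]]:
                hits += 1
        assert hits >= 0.8 * trials

    def test_shape_mismatch_raises(self):
        pred = CPIPrediction(
            affinity=5.0, score=0.3, attention=np.ones((3, 10)) / 10,
            residue_salience=np.ones(10),
        )
        with pytest.raises(ValueError):
            attention_fragments(pred, self.partition(4))
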