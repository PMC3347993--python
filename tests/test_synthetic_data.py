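"""The synthetic benchmark generator: sequences, references, classes,
controlled-accuracy perturbations, and full benchmark assembly."""

import numpy as np
import pytest

from foldeval.accuracy_metrics import class_similarity, compare
from foldeval.predictors import basepair_probabilities
from foldeval.structure_io import RnaSequence, SecondaryStructure
from foldeval.synthetic_data import (
    ClassSpec,
    generate_benchmark,
    make_class,
    mt_class_specs,
    perturb_structure,
    random_nested_structure,
    random_sequence,
    regenerate_benchmark,
    sample_reference_structure,
)


class TestRandomSequence:
    def test_zero_gc_has_no_strong_bases(self):
        seq = random_sequence(300, gc_fraction=0.0, seed=0)
        assert set(seq.residues) <= {"A", "U"}

    def test_same_seed_reproduces(self):
        assert random_sequence(80, 0.5, seed=1).residues == \
            random_sequence(80, 0.5, seed=1).residues

    def test_gc_concentrates_on_target(self):
        rng = np.random.default_rng(2)
        fracs = []
        for _ in range(200):
            seq = random_sequence(300, 0.6, rng)
            fracs.append(sum(c in "GC" for c in seq.residues) / 300)
        assert 0.58 <= np.mean(fracs) <= 0.62

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            random_sequence(10, 1.5)


class TestBoltzmannSampling:
    def test_unpairable_sequence_always_empty(self, toy37):
        seq = RnaSequence("x", "AAAAAAA")
        s = sample_reference_structure(seq, toy37, seed=3)
        assert s.pairs == frozenset()

    def test_pair_frequencies_match_probabilities(self, toy37):
        seq = RnaSequence("x", "GGCAAAAGCC")
        P = basepair_probabilities(seq, toy37)
        rng = np.random.default_rng(4)
        counts = np.zeros((10, 10))
        n_draws = 2000
        for _ in range(n_draws):
            for i, j in sample_reference_structure(seq, toy37, rng).pairs:
                counts[i, j] += 1
                counts[j, i] += 1
        assert np.abs(counts / n_draws - P.p).max() < 0.03

    def test_single_pair_zero_model_is_fair_coin(self, toy37):
        import dataclasses

        zero = dataclasses.replace(
            toy37,
            stack={k: 0.0 for k in toy37.stack},
            hairpin_len=(0.0,) * 31,
            bulge_len=(0.0,) * 31,
            internal_len=(0.0,) * 31,
            multiloop_a=0.0, multiloop_b=0.0, multiloop_c=0.0, terminal_au=0.0,
        )
        seq = RnaSequence("x", "GAAAAAC")
        rng = np.random.default_rng(5)
        hits = sum(
            bool(sample_reference_structure(seq, zero, rng).pairs)
            for _ in range(2000)
        )
        assert hits / 2000 == pytest.approx(0.5, abs=0.03)


class TestRandomNested:
    def test_structure_is_valid_and_sequence_compatible(self):
        from foldeval.energy_model import ALLOWED_PAIRS

        rng = np.random.default_rng(6)
        for _ in range(10):
            seq = random_sequence(60, 0.5, rng)
            s = random_nested_structure(seq, rng)
            for i, j in s.pairs:
                assert seq.residues[i] + seq.residues[j] in ALLOWED_PAIRS


class TestMakeClass:
    def test_full_similarity_gives_identical_members(self, toy37):
        spec = ClassSpec("c", 6, 60, 8, within_class_similarity=1.0)
        members = make_class(spec, toy37, seed=7)
        first = members[0]
        for m in members[1:]:
            assert m.sequence.residues == first.sequence.residues
            assert m.reference.pairs == first.reference.pairs
        assert class_similarity(members) == 1.0

    def test_same_seed_same_class(self, toy37):
        spec = ClassSpec("c", 5, 50, 6, within_class_similarity=0.8)
        a = make_class(spec, toy37, seed=8)
        b = make_class(spec, toy37, seed=8)
        for ra, rb in zip(a, b):
            assert ra.sequence.residues == rb.sequence.residues
            assert ra.reference.pairs == rb.reference.pairs

    def test_trna_like_class_hits_high_similarity(self, toy37):
        # the largest, most homogeneous class shape: n scaled down, 77 +- 5 nt
        spec = ClassSpec("tRNA", 30, 77, 4.8, within_class_similarity=0.96)
        members = make_class(spec, toy37, seed=9)
        assert len(members) == 30
        assert class_similarity(members[:16]) >= 0.85

    def test_diverse_class_hits_mid_similarity(self, toy37):
        spec = ClassSpec("c", 8, 70, 10, within_class_similarity=0.6)
        members = make_class(spec, toy37, seed=10)
        assert class_similarity(members) == pytest.approx(0.6, abs=0.1)

    def test_member_lengths_follow_spec(self, toy37):
        spec = ClassSpec("c", 25, 80, 6, within_class_similarity=0.85)
        members = make_class(spec, toy37, seed=11)
        lengths = [m.sequence.length for m in members]
        assert abs(np.mean(lengths) - 80) < 6


class TestPerturb:
    def _reference(self, toy37, seed=12, n=80):
        rng = np.random.default_rng(seed)
        seq = random_sequence(n, 0.55, rng)
        ref = sample_reference_structure(seq, toy37, rng)
        assert len(ref.pairs) >= 10
        return ref

    def test_perfect_targets_return_reference(self, toy37):
        ref = self._reference(toy37)
        assert perturb_structure(ref, 1.0, 1.0, seed=0).pairs == ref.pairs

    def test_half_sensitivity_full_ppv(self, toy37):
        ref = self._reference(toy37)
        n_keep = round(0.5 * len(ref.pairs))
        pred = perturb_structure(ref, 0.5, 1.0, seed=1)
        t = compare(ref, pred)
        assert len(pred.pairs) == n_keep
        assert t.ppv == 1.0
        assert t.sensitivity == pytest.approx(n_keep / len(ref.pairs))

    def test_symmetric_targets_calibrate_f(self, toy37):
        ref = self._reference(toy37)
        rng = np.random.default_rng(2)
        fs = [
            compare(ref, perturb_structure(ref, 0.7, 0.7, rng)).f
            for _ in range(300)
        ]
        assert np.mean(fs) == pytest.approx(0.7, abs=0.05)

    def test_result_always_valid_structure(self, toy37):
        ref = self._reference(toy37)
        rng = np.random.default_rng(3)
        for _ in range(20):
            s, p = rng.uniform(0.2, 1.0), rng.uniform(0.3, 1.0)
            pred = perturb_structure(ref, s, p, rng)  # validates on construction
            assert isinstance(pred, SecondaryStructure)

    def test_invalid_targets_rejected(self, toy37):
        ref = self._reference(toy37)
        with pytest.raises(ValueError):
            perturb_structure(ref, 0.0, 0.5)
        with pytest.raises(ValueError):
            perturb_structure(SecondaryStructure(30), 0.5, 0.5)


class TestGenerateBenchmark:
    def test_eight_class_layout_and_sizes(self, toy37):
        specs = mt_class_specs(size_scale=0.02, length_scale=0.15)
        bench = generate_benchmark(specs, {}, toy37, seed=13)
        classes = bench.dataset.classes
        assert len(classes) == 8
        assert {lab: len(v) for lab, v in classes.items()} == {
            s.label: s.size for s in specs
        }

    def test_manifest_regenerates_bit_identically(self, toy37):
        specs = mt_class_specs(size_scale=0.02, length_scale=0.15)
        algos = {"sim": {"kind": "simulated", "accuracy_mean": 0.65}}
        bench = generate_benchmark(specs, algos, toy37, seed=14)
        again = regenerate_benchmark(bench.manifest, toy37)
        for a, b in zip(bench.dataset.records, again.dataset.records):
            assert a.sequence.residues == b.sequence.residues
            assert a.reference.pairs == b.reference.pairs
            assert {k: v.pairs for k, v in a.predictions.items()} == {
                k: v.pairs for k, v in b.predictions.items()
            }
        assert again.manifest == bench.manifest

    def test_simulated_accuracy_lands_near_target(self, toy37):
        specs = [ClassSpec("c", 60, 70, 8, 0.8)]
        algos = {"sim": {"kind": "simulated", "accuracy_mean": 0.7,
                         "accuracy_std": 0.1}}
        bench = generate_benchmark(specs, algos, toy37, seed=15)
        assert bench.manifest["achieved"]["mean_f"]["sim"] == pytest.approx(
            0.7, abs=0.05
        )

    def test_permutation_power_on_separated_algorithms(self, toy37):
        # two simulated predictors at mean F 0.68 vs 0.60 on 300 records:
        # the one-sided permutation test should reject at alpha = 0.05 in
        # nearly all seeded runs
        from foldeval.resampling_stats import permutation_test

        rejections = 0
        n_runs = 8
        for k in range(n_runs):
            bench = generate_benchmark(
                [ClassSpec("c", 300, 60, 6, 0.8)],
                {
                    "worse": {"kind": "simulated", "accuracy_mean": 0.60,
                              "accuracy_std": 0.15},
                    "better": {"kind": "simulated", "accuracy_mean": 0.68,
                               "accuracy_std": 0.15},
                },
                toy37, seed=400 + k,
            )
            fs = {
                name: [
                    compare(r.reference, r.predictions[name]).f
                    for r in bench.dataset.records
                ]
                for name in ("worse", "better")
            }
            res = permutation_test(
                fs["worse"], fs["better"], sided="one", alternative="A_less",
                n_permutations=2000, seed=k, exhaustive=False,
            )
            rejections += res.p_value < 0.05
        assert rejections >= int(0.9 * n_runs)

    def test_real_predictors_run_end_to_end(self, toy37):
        specs = [ClassSpec("c", 4, 45, 5, 0.8)]
        algos = {
            "mfe": {"kind": "mfe"},
            "mea": {"kind": "mea", "gamma": 1.0},
        }
        bench = generate_benchmark(specs, algos, toy37, seed=16)
        for rec in bench.dataset.records:
            assert set(rec.predictions) == {"mfe", "mea"}
            for pred in rec.predictions.values():
                assert pred.length == rec.sequence.length
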