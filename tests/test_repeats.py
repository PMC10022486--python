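import numpy as np
import pytest

from myrtle.io import SequenceRecord
from myrtle import repeats
from myrtle.simulate import GenomeSimParams, simulate_genome


def _random_seq(rng, n, bases="ACGT"):
    return "".join(np.array(list(bases))[rng.integers(0, len(bases), n)])


class TestTelomeres:
    def test_planted_five_prime_array_exact_count(self):
        rng = np.random.default_rng(0)
        seq = "CCCTAAA" * 150 + _random_seq(rng, 30_000)
        calls = repeats.find_telomeres(SequenceRecord("c", seq))
        assert len(calls) == 1
        c = calls[0]
        assert (c.end, c.start, c.stop, c.copies, c.motif) == \
            ("five_prime", 0, 1050, 150, "CCCTAAA")

    def test_planted_three_prime_array(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 30_000) + "TTTAGGG" * 150
        calls = repeats.find_telomeres(SequenceRecord("c", seq))
        assert len(calls) == 1
        assert calls[0].end == "three_prime"
        assert calls[0].motif == "TTTAGGG"

    def test_random_sequence_yields_nothing(self):
        rng = np.random.default_rng(2)
        seq = _random_seq(rng, 40_000)
        assert repeats.find_telomeres(SequenceRecord("c", seq)) == []

    def test_diverged_units_tolerated_within_limit(self):
        rng = np.random.default_rng(3)
        units = ["CCCTAAA"] * 50
        units[10] = "CCCTATA"  # one diverged unit inside the run
        seq = "".join(units) + _random_seq(rng, 30_000)
        calls = repeats.find_telomeres(SequenceRecord("c", seq))
        assert len(calls) == 1
        assert calls[0].copies == 49
        assert calls[0].stop - calls[0].start == 350

    def test_reverse_complement_mirrors_calls(self):
        rng = np.random.default_rng(4)
        seq = "CCCTAAA" * 80 + _random_seq(rng, 30_000) + "TTTAGGG" * 60
        fwd = repeats.find_telomeres(SequenceRecord("c", seq))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        rev = repeats.find_telomeres(SequenceRecord("c", rc))
        L = len(seq)
        mirrored = sorted((L - c.stop, L - c.start, c.copies) for c in rev)
        original = sorted((c.start, c.stop, c.copies) for c in fwd)
        assert mirrored == original


class TestTandemArrays:
    def test_planted_422bp_satellite_recovered(self):
        rng = np.random.default_rng(5)
        monomer = _random_seq(rng, 422)
        array = list(monomer * 100)
        for i in range(len(array)):  # 2% divergence
            if rng.random() < 0.02:
                array[i] = "ACGT"[rng.integers(0, 4)]
        seq = _random_seq(rng, 50_000) + "".join(array) + _random_seq(rng, 50_000)
        found = repeats.find_tandem_arrays(SequenceRecord("c", seq))
        big = max(found, key=lambda a: a.length)
        assert abs(big.period - 422) <= 2
        assert abs(big.copies - 100) / 100 <= 0.05
        assert big.identity >= 0.9

    def test_planted_153bp_satellite_recovered(self):
        rng = np.random.default_rng(6)
        monomer = _random_seq(rng, 153)
        seq = _random_seq(rng, 20_000) + monomer * 200 + _random_seq(rng, 20_000)
        found = repeats.find_tandem_arrays(SequenceRecord("c", seq))
        big = max(found, key=lambda a: a.length)
        assert abs(big.period - 153) <= 2

    def test_dinucleotide_shuffle_negative_control(self):
        rng = np.random.default_rng(7)
        monomer = _random_seq(rng, 422)
        seq = monomer * 50
        # dinucleotide-preserving shuffle destroys the tandem structure
        for trial in range(5):
            pairs = [seq[i:i + 2] for i in range(0, len(seq) - 1, 2)]
            rng.shuffle(pairs)
            shuffled = "".join(pairs)
            found = repeats.find_tandem_arrays(SequenceRecord("c", shuffled))
            assert not [a for a in found if a.copies >= 10]


class TestMonomerClustering:
    def test_rotations_join_one_family(self):
        rng = np.random.default_rng(8)
        monomer = _random_seq(rng, 100)
        rot = monomer[37:] + monomer[:37]
        arrays = [
            repeats.TandemArray("c1", 0, 1000, monomer, 100, 10, 1.0),
            repeats.TandemArray("c2", 0, 900, rot, 100, 9, 1.0),
        ]
        repeats.cluster_monomers(arrays)
        assert arrays[0].family == arrays[1].family

    def test_different_lengths_split_families(self):
        rng = np.random.default_rng(9)
        arrays = [
            repeats.TandemArray("c1", 0, 4220, _random_seq(rng, 422), 422, 10, 1.0),
            repeats.TandemArray("c2", 0, 1530, _random_seq(rng, 153), 153, 10, 1.0),
        ]
        repeats.cluster_monomers(arrays)
        assert arrays[0].family != arrays[1].family

    def test_mutated_copies_cluster_together(self):
        rng = np.random.default_rng(10)
        base = _random_seq(rng, 200)
        arrays = []
        for i in range(20):
            m = list(base)
            for j in range(len(m)):
                if rng.random() < 0.05:
                    m[j] = "ACGT"[rng.integers(0, 4)]
            arrays.append(repeats.TandemArray(
                f"c{i}", 0, 2000, "".join(m), 200, 10, 1.0))
        repeats.cluster_monomers(arrays, identity_threshold=0.8)
        assert len({a.family for a in arrays}) == 1

    def test_circular_identity_detects_rotation(self):
        assert repeats.circular_identity("ACGTAC", "TACACG") == 1.0
        assert repeats.circular_identity("AAAAAA", "CCCCCC") == 0.0


class TestCentromeres:
    def test_planted_genome_recovery(self):
        records, truth = simulate_genome(GenomeSimParams(
            n_chromosomes=2, chromosome_length=500_000,
            centromere_copies=200, seed=11))
        arrays = []
        for rec in records:
            arrays.extend(repeats.find_tandem_arrays(rec))
        repeats.cluster_monomers(arrays)
        calls = repeats.call_centromeres(arrays)
        assert len(calls) == 2
        for call, planted in zip(calls, truth.centromeres):
            inter = min(call.stop, planted.end) - max(call.start, planted.start)
            union = max(call.stop, planted.end) - min(call.start, planted.start)
            assert inter / union >= 0.9

    def test_telomere_only_chromosome_gets_no_call(self):
        rng = np.random.default_rng(12)
        seq = "CCCTAAA" * 100 + _random_seq(rng, 100_000)
        arrays = repeats.find_tandem_arrays(SequenceRecord("c", seq))
        # only the telomeric harmonic (if any) is present; no centromere span
        if arrays:
            repeats.cluster_monomers(arrays)
            calls = repeats.call_centromeres(arrays, min_span=5000)
            assert calls == []

    def test_requires_family_assignment(self):
        arr = repeats.TandemArray("c", 0, 1000, "ACGT" * 25, 100, 10, 1.0)
        with pytest.raises(ValueError, match="cluster_monomers"):
            repeats.call_centromeres([arr])
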