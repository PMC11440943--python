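"""Allele matrix, SNP window filter and recursive bipartition."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smncall import (
    SMN1,
    SMN2,
    apply_variants,
    build_allele_matrix,
    call_snps,
    partition_reads,
    simulate_ccs,
)
from smncall.haplotyper import consensus
from smncall.simulate import SampleSpec, parse_haplotype_string


def _matrix(model, seqs):
    return build_allele_matrix([(f"r{i}", s) for i, s in enumerate(seqs)], model)


def _mutate(seq, pos, base):
    return seq[: pos - 1] + base + seq[pos:]


class TestAlleleMatrix:
    def test_reference_read_is_the_reference_row(self, model):
        mat = _matrix(model, [model.smn1_ref])
        assert mat.matrix[0].tobytes().decode() == model.smn1_ref

    def test_paralog_read_differs_only_at_the_psvs(self, model):
        mat = _matrix(model, [model.smn2_ref])
        ref = np.frombuffer(model.smn1_ref.encode(), dtype="S1")
        diffs = np.nonzero(mat.matrix[0] != ref)[0] + 1
        assert list(diffs) == list(model.psv_positions)

    def test_single_substitution_is_localised(self, model):
        read = _mutate(model.smn1_ref, 777, "A" if model.smn1_ref[776] != "A" else "C")
        mat = _matrix(model, [read])
        ref = np.frombuffer(model.smn1_ref.encode(), dtype="S1")
        diffs = np.nonzero(mat.matrix[0] != ref)[0] + 1
        assert list(diffs) == [777]

    def test_unalignable_reads_are_dropped_and_counted(self, model):
        junk = "ACGT" * (len(model.smn1_ref) // 4)
        mat = build_allele_matrix(
            [("good", model.smn1_ref), ("junk", junk[::-1])], model
        )
        assert mat.read_ids == ["good"]
        assert mat.dropped_ids == ["junk"]
        with pytest.raises(ValueError):
            build_allele_matrix([("junk", junk[::-1])], model)


class TestCallSnps:
    @pytest.mark.parametrize("n_alt, retained", [(5, True), (1, False), (9, False), (2, True), (8, True)])
    def test_frequency_window_is_inclusive(self, model, n_alt, retained):
        pos = 100
        alt = "A" if model.smn1_ref[pos - 1] != "A" else "G"
        seqs = [_mutate(model.smn1_ref, pos, alt)] * n_alt
        seqs += [model.smn1_ref] * (10 - n_alt)
        sites = call_snps(_matrix(model, seqs))
        assert (pos in [s.position for s in sites]) is retained

    def test_sites_sorted_by_position(self, model):
        seq = _mutate(_mutate(model.smn1_ref, 2000, "-" if False else "A" if model.smn1_ref[1999] != "A" else "C"), 50,
                      "A" if model.smn1_ref[49] != "A" else "C")
        sites = call_snps(_matrix(model, [seq] * 5 + [model.smn1_ref] * 5))
        assert [s.position for s in sites] == sorted(s.position for s in sites)
        assert all(0 < s.minor_frequency < 1 for s in sites)


class TestPartition:
    def test_identical_reads_emit_one_haplotype(self, model):
        haps, discarded = partition_reads(_matrix(model, [model.smn1_ref] * 100), model)
        assert len(haps) == 1 and haps[0].read_count == 100 and not discarded
        assert haps[0].consensus == model.smn1_ref
        assert haps[0].defining_alleles == {}

    def test_two_linked_haplotypes_split_by_support(self, model):
        seqs = [model.smn1_ref] * 30 + [model.smn2_ref] * 70
        haps, _ = partition_reads(_matrix(model, seqs), model)
        assert sorted(h.read_count for h in haps) == [30, 70]
        assert {h.consensus for h in haps} == {model.smn1_ref, model.smn2_ref}

    def test_three_haplotypes_nested_split(self, model):
        hyb = apply_variants(SMN2, ["c.*239A>G"], model)
        seqs = [model.smn1_ref] * 40 + [model.smn2_ref] * 30 + [hyb] * 30
        haps, _ = partition_reads(_matrix(model, seqs), model)
        assert sorted(h.read_count for h in haps) == [30, 30, 40]
        assert {h.consensus for h in haps} == {model.smn1_ref, model.smn2_ref, hyb}

    def test_small_input_rejected(self, model):
        with pytest.raises(ValueError):
            partition_reads(_matrix(model, [model.smn1_ref] * 5), model)

    def test_conservation_of_reads_under_noise(self, model):
        spec = SampleSpec(
            sample_id="S",
            haplotypes=parse_haplotype_string("SMN1*2 + SMN2*1"),
            substitution_error=0.01,
            seed=13,
        )
        records = simulate_ccs(spec, model)
        mat = build_allele_matrix(records, model)
        haps, discarded = partition_reads(mat, model)
        emitted = [rid for h in haps for rid in h.read_ids]
        assert sorted(emitted + discarded) == sorted(mat.read_ids)
        assert len(emitted) + len(discarded) + len(mat.dropped_ids) == len(records)

    def test_widening_the_window_never_loses_haplotypes(self, model):
        seqs = [model.smn1_ref] * 150 + [model.smn2_ref] * 50  # minor at 25%
        mat = _matrix(model, seqs)
        narrow, _ = partition_reads(mat, model, min_freq=0.30, max_freq=0.70)
        wide, _ = partition_reads(mat, model, min_freq=0.20, max_freq=0.80)
        assert len(wide) >= len(narrow)


class TestConsensus:
    def test_majority_vote_corrects_sequencing_errors(self, model):
        rng = np.random.default_rng(4)
        bases = "ACGT"
        seqs = []
        for _ in range(50):
            arr = list(model.smn2_ref)
            for p in np.nonzero(rng.random(len(arr)) < 0.01)[0]:
                arr[p] = bases[(bases.index(arr[p]) + rng.integers(1, 4)) % 4]
            seqs.append("".join(arr))
        mat = _matrix(model, seqs)
        seq, defining = consensus(mat.matrix, model)
        assert seq == model.smn2_ref
        assert set(defining) == set(model.psv_positions)

    def test_single_read_group_is_returned_verbatim(self, model):
        mat = _matrix(model, [model.smn2_ref])
        seq, _ = consensus(mat.matrix, model)
        assert seq == model.smn2_ref


def _oracle_grouping(seqs):
    """Independent oracle: group error-free reads by their full string."""
    return sorted(Counter(seqs).values())


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.data())
def test_partition_matches_full_string_oracle(model, data):
    """On error-free reads the recursive bipartition reproduces exact grouping."""
    variants_pool = [
        (SMN1, []),
        (SMN2, []),
        (SMN2, ["c.*239A>G"]),
        (SMN1, ["c.*239G>A"]),
        (SMN2, ["c.*3+100A>C", "c.*3+215A>G", "c.*239A>G"]),
        (SMN1, ["c.*237_*238del"]),
    ]
    k = data.draw(st.integers(1, 4))
    chosen = data.draw(
        st.lists(st.sampled_from(range(len(variants_pool))), min_size=k, max_size=k, unique=True)
    )
    # counts in [40, 50] keep every haplotype's frequency above the 20%
    # retention window at every nesting level, so exact grouping is expected
    counts = data.draw(st.lists(st.integers(40, 50), min_size=k, max_size=k))
    seqs = []
    for idx, n in zip(chosen, counts):
        base, labels = variants_pool[idx]
        seqs.extend([apply_variants(base, labels, model)] * n)
    haps, discarded = partition_reads(_matrix(model, seqs), model)
    assert not discarded
    assert sorted(h.read_count for h in haps) == _oracle_grouping(seqs)
    assert sorted(h.consensus for h in haps) == sorted(set(seqs))
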