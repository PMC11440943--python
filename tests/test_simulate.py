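"""Read-set generator and MLPA/qPCR assay simulators."""

import io
import math

import numpy as np
import pytest

from smncall import (
    AssayNoise,
    HaplotypeSpec,
    SampleSpec,
    cq_to_cn,
    simulate_ccs,
    simulate_mlpa,
    simulate_qpcr,
)
from smncall.datasets import sample_spec_from_row
from smncall.simulate import (
    dosage_call,
    format_haplotype_string,
    parse_haplotype_string,
    write_fastq,
)


def _spec(haps, **kwargs):
    defaults = dict(sample_id="S", depth_per_copy=100.0, substitution_error=0.0, seed=5)
    defaults.update(kwargs)
    return SampleSpec(haplotypes=parse_haplotype_string(haps), **defaults)


class TestSimulateCcs:
    def test_invalid_specs_rejected(self, model):
        with pytest.raises(ValueError):
            simulate_ccs(_spec("SMN1*1", depth_per_copy=0.0), model)
        with pytest.raises(ValueError):
            simulate_ccs(_spec("SMN1*1", substitution_error=0.05), model)
        with pytest.raises(ValueError):
            simulate_ccs(SampleSpec(sample_id="S", haplotypes=[]), model)

    def test_zero_error_reads_match_source(self, model):
        records = simulate_ccs(_spec("SMN1*1"), model)
        assert records and all(str(r.seq) == model.smn1_ref for r in records)

    def test_per_haplotype_counts_follow_the_seeded_poisson_draws(self, model):
        # oracle: regenerate the counts from the stated seeded distribution
        spec = _spec("SMN1*1 + SMN2*2", seed=42)
        records = simulate_ccs(spec, model)
        oracle = np.random.default_rng(42)
        expected = [int(oracle.poisson(1 * 100.0)), int(oracle.poisson(2 * 100.0))]
        n_smn1 = sum(str(r.seq) == model.smn1_ref for r in records)
        n_smn2 = sum(str(r.seq) == model.smn2_ref for r in records)
        assert [n_smn1, n_smn2] == expected
        assert len(records) == sum(expected)

    def test_reproducible_byte_identical_fastq(self, model):
        spec = _spec("SMN1*2 + SMN2*1", substitution_error=0.01, seed=9)
        buffers = []
        for _ in range(2):
            buf = io.StringIO()
            write_fastq(simulate_ccs(spec, model), buf)
            buffers.append(buf.getvalue())
        assert buffers[0] == buffers[1]

    def test_read_order_carries_no_origin_information(self, model):
        records = simulate_ccs(_spec("SMN1*1 + SMN2*1", seed=3), model)
        assert all(r.id.startswith("read") for r in records)
        smn1_positions = [
            i for i, r in enumerate(records) if str(r.seq) == model.smn1_ref
        ]
        # a haplotype's reads are shuffled through the file, not a prefix block
        assert smn1_positions != list(range(len(smn1_positions)))

    def test_total_depth_scales_linearly(self, model):
        # total reads ~ Poisson(total_copies * depth); 3-sigma bound at depth 1000
        spec = _spec("SMN1*2 + SMN2*1", depth_per_copy=1000.0, seed=11)
        n = len(simulate_ccs(spec, model))
        mean = 3 * 1000.0
        assert abs(n - mean) < 3 * math.sqrt(mean)


class TestMlpa:
    def test_noise_free_reproduces_printed_mlpa_for_every_genotype(self, model, table1):
        for _, row in table1.iterrows():
            res = simulate_mlpa(sample_spec_from_row(row), model)
            assert (res.smn1_e7, res.smn1_e8, res.smn2_e7, res.smn2_e8) == (
                row.mlpa_smn1_e7,
                row.mlpa_smn1_e8,
                row.mlpa_smn2_e7,
                row.mlpa_smn2_e8,
            ), row["sample"]
            assert res.flags == {}

    def test_probe_window_variant_masks_a_copy(self, model):
        # the 2-nt deletion beside the exon-8 PSV breaks probe hybridisation:
        # true SMN1 exon-8 copies = 2, probe sees only 1
        spec = _spec("SMN1*1 + SMN1[c.*237_*238del]*1 + SMN2*1")
        res = simulate_mlpa(spec, model)
        assert (res.smn1_e7, res.smn1_e8, res.smn2_e7, res.smn2_e8) == (2, 1, 1, 1)

    def test_converted_exon8_counts_toward_the_other_gene(self, model):
        spec = _spec("SMN1*2 + SMN2*1 + SMN2[c.*239A>G]*1")
        res = simulate_mlpa(spec, model)
        assert (res.smn1_e7, res.smn1_e8, res.smn2_e7, res.smn2_e8) == (2, 3, 2, 1)

    def test_dosage_rounding_and_gray_flags(self):
        assert dosage_call(2.0, 0.15) == (2, None)
        assert dosage_call(2.4, 0.15) == (2, "NLT")
        assert dosage_call(2.55, 0.15) == (3, "NUT")
        assert dosage_call(2.2, 0.15) == (2, None)
        assert dosage_call(0.0, 0.15) == (0, None)

    def test_noisy_dosage_flags_appear_near_thresholds(self, model):
        noise = AssayNoise(mlpa_sigma=0.25, gray_band=0.5)
        res = simulate_mlpa(_spec("SMN1*2 + SMN2*2"), model, noise, seed=1)
        # with the band covering every dosage, all reported fields are flagged
        assert set(res.flags) == {"smn1_e7", "smn1_e8", "smn2_e7", "smn2_e8"}


class TestQpcr:
    def test_noise_free_matches_printed_qpcr_exon7(self, model, table1):
        for _, row in table1.iterrows():
            res = simulate_qpcr(sample_spec_from_row(row), model)
            assert res.smn1_e7 == row.qpcr_smn1_e7, row["sample"]
            assert res.smn2_e7 is None and res.smn2_e8 is None

    def test_forced_downward_miscalls(self, model):
        noise = AssayNoise(qpcr_miscall=1.0, qpcr_miscall_direction=-1)
        # false negative for duplication: 3 copies reported as 2
        res = simulate_qpcr(_spec("SMN1*3"), model, noise, seed=0)
        assert res.smn1_e7 == 2
        # false positive for deletion: 2 copies reported as 1
        res = simulate_qpcr(_spec("SMN1*2"), model, noise, seed=0)
        assert res.smn1_e7 == 1

    def test_gray_flags_only_on_reported_fields(self, model):
        noise = AssayNoise(qpcr_gray=0.5)
        seen = set()
        for seed in range(10):
            res = simulate_qpcr(_spec("SMN1*2"), model, noise, seed=seed)
            assert set(res.flags) <= {"smn1_e7", "smn1_e8"}
            seen |= set(res.flags)
        assert seen  # at rate 0.5 some call is flagged across ten seeds


@pytest.mark.parametrize(
    "ddcq, ratio, call",
    [(0.0, 1.0, 2), (1.0, 0.5, 1), (-0.585, 1.4997, 3)],
)
def test_cq_to_cn(ddcq, ratio, call):
    got_ratio, got_call = cq_to_cn(ddcq)
    assert got_ratio == pytest.approx(ratio, abs=1e-3)
    assert got_call == call


def test_haplotype_string_roundtrip():
    text = "SMN1*2 + SMN2[c.*3+100A>C;c.*3+215A>G;c.*239A>G]*1"
    haps = parse_haplotype_string(text)
    assert [h.copy_number for h in haps] == [2, 1]
    assert haps[1].variant_labels == ["c.*3+100A>C", "c.*3+215A>G", "c.*239A>G"]
    assert format_haplotype_string(haps) == text
    with pytest.raises(ValueError):
        parse_haplotype_string("SMN3*1")
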