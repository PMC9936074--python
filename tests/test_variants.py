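"""The SNV/indel filtering and prioritization cascade."""

import math
from dataclasses import replace

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rplca import (
    PlantedVariant, SimConfig, ValidationError, VariantRecord,
    assign_tier, call_zygosity, gen_variant_table, maf_filter, prioritize,
    run_frequency_filter, run_frequency_threshold, spliceai_gate,
)
from rplca.variants import candidates, read_variants_tsv, write_variants_tsv


def make_variant(**kwargs) -> VariantRecord:
    base = dict(sample_id="S1", chrom="chr1", pos=1000, ref="A", alt="G",
                gene="USH2A", inheritance="AR", variant_type="missense",
                alt_reads=50, total_reads=100)
    base.update(kwargs)
    return VariantRecord(**base)


class TestZygosity:
    @pytest.mark.parametrize("alt,total,expected", [
        (90, 100, "homozygous"),     # >= 80%
        (80, 100, "homozygous"),     # boundary resolved to homozygous
        (40, 100, "heterozygous"),   # 35-80%
        (35, 100, "heterozygous"),
        (34, 100, "excluded"),       # below the het band
        (8, 9, "excluded"),          # under 10 reads at the position
        (0, 0, "excluded"),
    ])
    def test_bands(self, alt, total, expected):
        assert call_zygosity(alt, total) == expected

    def test_alt_exceeding_total_rejected(self):
        with pytest.raises(ValidationError):
            call_zygosity(11, 10)


class TestMafFilter:
    def test_recessive_keeps_at_half_percent(self):
        v = make_variant(maf_gnomad=0.004, maf_genomes=0.003,
                         maf_inhouse=0.005)
        assert maf_filter(v)

    def test_all_three_sources_must_pass(self):
        v = make_variant(maf_gnomad=0.004, maf_genomes=0.006,
                         maf_inhouse=0.001)
        assert not maf_filter(v)

    def test_dominant_cutoff_tighter(self):
        v = make_variant(inheritance="AD", gene="RHO", maf_gnomad=0.002)
        assert not maf_filter(v)
        assert maf_filter(replace(v, maf_gnomad=0.001))

    def test_x_linked_uses_recessive_cutoff(self):
        v = make_variant(inheritance="XL", gene="RPGR", maf_gnomad=0.004)
        assert maf_filter(v)

    def test_absent_from_all_sources_kept(self):
        assert maf_filter(make_variant())

    def test_known_div_bypasses(self):
        v = make_variant(maf_gnomad=0.01, known_div=True,
                         variant_type="deep_intronic")
        assert maf_filter(v)


class TestRunFrequency:
    def test_380_proband_run_threshold_is_38(self):
        assert run_frequency_threshold(380) == 38

    @given(st.integers(1, 400))
    def test_matches_ceil_table(self, n):
        # brute-force threshold: smallest k with k/n >= 10%
        brute = next(k for k in range(1, n + 1) if k / n >= 0.10)
        assert run_frequency_threshold(n) == brute == math.ceil(0.10 * n)

    def _carriers(self, n_carriers, pos=500):
        return [make_variant(sample_id=f"S{i}", pos=pos)
                for i in range(n_carriers)]

    def test_at_threshold_removed_for_all_carriers(self):
        kept, removed = run_frequency_filter(self._carriers(38), 380)
        assert kept == [] and len(removed) == 38

    def test_below_threshold_kept(self):
        kept, removed = run_frequency_filter(self._carriers(37), 380)
        assert removed == [] and len(kept) == 37

    def test_run_of_100_threshold_10(self):
        kept, removed = run_frequency_filter(self._carriers(10), 100)
        assert kept == []

    def test_div_exempt(self):
        variants = [replace(v, known_div=True)
                    for v in self._carriers(50)]
        kept, removed = run_frequency_filter(variants, 100)
        assert removed == []


class TestTiers:
    @pytest.mark.parametrize("vtype", ["stop_gain", "stop_loss",
                                       "frameshift", "start_loss",
                                       "canonical_splice"])
    def test_truncating_types_tier1(self, vtype):
        assert assign_tier(make_variant(variant_type=vtype)) == 1

    def test_inframe_indel_tier2(self):
        assert assign_tier(make_variant(variant_type="inframe_indel")) == 2

    def test_missense_all_three_scores_tier3(self):
        v = make_variant(phylop=3.0, cadd_phred=20.0, grantham=100.0)
        assert assign_tier(v) == 3

    def test_missense_thresholds_inclusive(self):
        v = make_variant(phylop=2.7, cadd_phred=14.0, grantham=79.0)
        assert assign_tier(v) == 4     # exactly one passes, inclusively
        v3 = make_variant(phylop=2.7, cadd_phred=15.0, grantham=80.0)
        assert assign_tier(v3) == 3

    def test_missense_no_passes_tier5(self):
        v = make_variant(phylop=0.0, cadd_phred=5.0, grantham=10.0)
        assert assign_tier(v) == 5

    def test_missing_scores_do_not_pass(self):
        assert assign_tier(make_variant()) == 5

    @given(st.sampled_from(("stop_gain", "stop_loss", "frameshift",
                            "start_loss", "canonical_splice",
                            "inframe_indel", "missense", "synonymous",
                            "ncss", "deep_intronic", "utr")),
           st.one_of(st.none(), st.floats(-14.1, 6.4)),
           st.one_of(st.none(), st.floats(1, 99)),
           st.one_of(st.none(), st.floats(0, 215)))
    def test_tier_function_total(self, vtype, phylop, cadd, grantham):
        tier = assign_tier(make_variant(variant_type=vtype, phylop=phylop,
                                        cadd_phred=cadd, grantham=grantham))
        assert tier in (1, 2, 3, 4, 5)


class TestSpliceGate:
    def test_any_delta_at_threshold_flags(self):
        v = make_variant(variant_type="deep_intronic",
                         sai_ag=0.0, sai_al=0.0, sai_dg=0.2, sai_dl=0.0)
        assert spliceai_gate(v)

    def test_canonical_splice_exempt(self):
        v = make_variant(variant_type="canonical_splice",
                         sai_ag=0.9, sai_al=0.0, sai_dg=0.0, sai_dl=0.0)
        assert not spliceai_gate(v)

    def test_all_below_threshold(self):
        v = make_variant(sai_ag=0.19, sai_al=0.19, sai_dg=0.19,
                         sai_dl=0.19)
        assert not spliceai_gate(v)

    def test_delta_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            make_variant(sai_ag=1.5)


class TestPrioritize:
    def test_whitelisted_div_survives_high_maf(self):
        v = make_variant(variant_type="deep_intronic", maf_gnomad=0.01,
                         sai_ag=0.6)
        out = prioritize([v], div_whitelist={v.allele_key})
        assert out[0].candidate
        assert out[0].variant.known_div

    def test_synonymous_without_signal_not_candidate(self):
        v = make_variant(variant_type="synonymous")
        out = prioritize([v])
        assert out[0].tier == 5
        assert not out[0].candidate

    def test_splice_flag_rescues_tier5(self):
        v = make_variant(variant_type="synonymous", sai_dg=0.39,
                         sai_dl=0.31)
        out = prioritize([v], n_probands=100)
        assert out[0].tier == 5 and out[0].splice_flag
        assert out[0].candidate

    def test_maf_and_depth_filters_commute(self):
        records = [
            make_variant(pos=1, maf_gnomad=0.02),               # common
            make_variant(pos=2, total_reads=5, alt_reads=4),    # shallow
            make_variant(pos=3, variant_type="stop_gain",
                         acmg_class=5),                          # survivor
        ]
        maf_first = [v for v in records if maf_filter(v)]
        maf_first = [v for v in maf_first
                     if call_zygosity(v.alt_reads, v.total_reads)
                     != "excluded"]
        depth_first = [v for v in records
                       if call_zygosity(v.alt_reads, v.total_reads)
                       != "excluded"]
        depth_first = [v for v in depth_first if maf_filter(v)]
        assert maf_first == depth_first
        out = candidates(prioritize(records, n_probands=100))
        assert [p.variant.pos for p in out] == [3]

    def test_planted_causals_recovered_from_synthetic_table(self):
        config = SimConfig(seed=21, n_samples=100, n_controls=2, n_ntc=1,
                           recurrence_injections=1,
                           planted_variants=[
                               PlantedVariant(0, "USH2A", "homozygous", (5,)),
                               PlantedVariant(1, "EYS", "compound_het",
                                              (4, 3)),
                               PlantedVariant(2, "RHO", "heterozygous",
                                              (4,)),
                           ])
        variants, truth = gen_variant_table(config)
        out = candidates(prioritize(variants,
                                    n_probands=truth["n_probands"]))
        # exactly the four planted alleles survive; zero background leak
        assert len(out) == 4
        assert {p.variant.sample_id for p in out} == \
            {"S0001", "S0002", "S0003"}
        assert all(p.tier <= 3 for p in out)
        surviving_keys = {p.variant.allele_key for p in out}
        assert not surviving_keys & set(
            tuple(k) for k in truth["recurrent_keys"])

    def test_monotone_in_maf_cutoff(self):
        config = SimConfig(seed=5, n_samples=40, n_controls=2, n_ntc=1)
        variants, _ = gen_variant_table(config)
        loose = {p.variant.key_str()
                 for p in candidates(prioritize(variants, ar_cutoff=0.01,
                                                ad_cutoff=0.01))}
        tight = {p.variant.key_str()
                 for p in candidates(prioritize(variants, ar_cutoff=0.001,
                                                ad_cutoff=0.0001))}
        assert tight <= loose


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        records = [
            make_variant(acmg_class=5, variant_type="stop_gain"),
            make_variant(pos=2000, gene="ABCA4", abca4_severity="severe",
                         grantham=120.0, known_div=False),
            make_variant(pos=3000, known_div=True,
                         variant_type="deep_intronic"),
        ]
        path = tmp_path / "v.tsv"
        write_variants_tsv(records, path)
        assert read_variants_tsv(path) == records

    def test_vcf_dialect(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text("\n".join([
            "##fileformat=VCFv4.2",
            '##INFO=<ID=GENE,Number=1,Type=String,Description="g">',
            '##INFO=<ID=INH,Number=1,Type=String,Description="i">',
            '##INFO=<ID=TYPE,Number=1,Type=String,Description="t">',
            '##INFO=<ID=AO,Number=1,Type=Integer,Description="a">',
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">',
            '##INFO=<ID=MAF_G,Number=1,Type=Float,Description="m">',
            '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="s">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
            "chr1\t1000\t.\tA\tG\t.\t.\t"
            "GENE=USH2A;INH=AR;TYPE=stop_gain;AO=48;DP=100;"
            "MAF_G=0.0001;SAMPLE=S9",
        ]) + "\n")
        from rplca.variants import read_variants_vcf
        records = read_variants_vcf(vcf)
        assert len(records) == 1
        v = records[0]
        assert (v.sample_id, v.gene, v.pos, v.alt_reads) == \
            ("S9", "USH2A", 1000, 48)
        assert v.maf_gnomad == pytest.approx(0.0001)
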