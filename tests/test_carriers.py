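"""Carrier grouping and the biallelic-evidence decision table."""

import itertools

import pytest

from hrdscape import carriers as cc
from hrdscape.io import ASCNSegment, VariantRecord


def v(gene="PALB2", consequence="stop_gained", origin="germline", pos=23646191,
      sample="S1", chrom="16", ref="G", alt="T", **kw):
    return VariantRecord(sample, chrom, pos, ref, alt, gene, consequence,
                         origin, **kw)


@pytest.mark.parametrize("consequence,expected", [
    ("stop_gained", "ptv"), ("frameshift", "ptv"), ("splice_donor", "ptv"),
    ("splice_acceptor", "ptv"), ("missense", "missense"), ("other", "other"),
])
def test_classify_consequence(consequence, expected):
    assert cc.classify_consequence(v(consequence=consequence)) == expected


class TestCarrierGroup:
    def test_germline_takes_precedence_and_second_hit_recorded(self):
        variants = [v(origin="germline"),
                    v(origin="somatic", consequence="frameshift", pos=23647000)]
        group = cc.assign_carrier_group(variants)
        assert (group.gene, group.origin) == ("PALB2", "germline")
        assert cc.has_somatic_second_hit(variants, group)

    def test_somatic_only_carrier(self):
        group = cc.assign_carrier_group([v(origin="somatic")])
        assert group.label == "PALB2_somatic"

    def test_missense_only_is_excluded(self):
        group = cc.assign_carrier_group([v(consequence="missense")])
        assert group.category == "excluded_missense"

    def test_no_study_gene_variants_is_non_carrier(self):
        group = cc.assign_carrier_group([v(gene="TP53", consequence="missense")])
        assert group.category == "non_carrier"

    def test_ptvs_in_two_genes_is_ambiguity_error(self):
        with pytest.raises(cc.AmbiguousCarrierError):
            cc.assign_carrier_group([v(gene="PALB2"), v(gene="BRCA1", chrom="17")])

    def test_two_somatic_ptvs_count_as_second_hit(self):
        variants = [v(origin="somatic"),
                    v(origin="somatic", consequence="frameshift", pos=23650000)]
        group = cc.assign_carrier_group(variants)
        assert group.origin == "somatic"
        assert cc.has_somatic_second_hit(variants, group)


class TestLocusLoh:
    def test_ascn_loh_iff_minor_zero(self):
        segs = [ASCNSegment("S1", "16", 1, 50_000_000, 2, 0)]
        assert cc.call_locus_loh_ascn(segs, "16", 23646191) == cc.LOH
        segs = [ASCNSegment("S1", "16", 1, 50_000_000, 1, 1)]
        assert cc.call_locus_loh_ascn(segs, "chr16", 23646191) == cc.NO_LOH

    def test_ascn_gap_is_unknown(self):
        segs = [ASCNSegment("S1", "16", 1, 1000, 2, 0)]
        assert cc.call_locus_loh_ascn(segs, "16", 23646191) == cc.UNKNOWN

    @pytest.mark.parametrize("vt,vg,expected", [
        (0.75, 0.50, cc.LOH),       # 0.25 > 0.20
        (0.65, 0.50, cc.NO_LOH),    # 0.15 <= 0.20
        (0.701, 0.50, cc.LOH),      # strictly greater-than boundary
        (0.70, 0.50, cc.NO_LOH),
        (0.70, None, cc.UNKNOWN),
        (None, 0.50, cc.UNKNOWN),
    ])
    def test_vaf_rule_absolute_difference(self, vt, vg, expected):
        assert cc.call_locus_loh_vaf(vt, vg) == expected


def _oracle_status(ascn, vaf, hit, swgs, origin):
    """Independent re-statement of the resolution rule used for enumeration."""
    if hit:
        return "biallelic", False
    if origin == "somatic":
        if ascn == "loh":
            return "biallelic", False
        return "monoallelic", ascn == "unknown"
    if (ascn, vaf) == ("loh", "loh"):
        return "biallelic", False
    if (ascn, vaf) == ("no_loh", "no_loh"):
        return "monoallelic", False
    if {ascn, vaf} == {"loh", "no_loh"}:
        if swgs == "loss":
            return "biallelic", False
        if swgs == "neutral_or_gain":
            return "monoallelic", False
        return "monoallelic", True
    return "monoallelic", True


class TestResolution:
    def test_second_hit_is_decisive_even_without_loh(self):
        ev = cc.AllelicEvidence("no_loh", "no_loh", somatic_second_hit=True)
        assert cc.resolve_allelic_status(ev).status == "biallelic"

    def test_agreement_and_tie_break(self):
        assert cc.resolve_allelic_status(
            cc.AllelicEvidence("loh", "loh")).status == "biallelic"
        disagree_loss = cc.AllelicEvidence("loh", "no_loh", swgs_state="loss")
        assert cc.resolve_allelic_status(disagree_loss).status == "biallelic"
        disagree_gain = cc.AllelicEvidence("loh", "no_loh",
                                           swgs_state="neutral_or_gain")
        res = cc.resolve_allelic_status(disagree_gain)
        assert res.status == "monoallelic" and not res.insufficient_evidence

    def test_full_decision_table_enumeration(self):
        """All 54 evidence combinations resolve, matching the stated rule."""
        combos = itertools.product(cc.TRI_STATES, cc.TRI_STATES, (False, True),
                                   (None, "loss", "neutral_or_gain", "unknown"))
        n = 0
        for ascn, vaf, hit, swgs in combos:
            ev = cc.AllelicEvidence(ascn, vaf, hit, swgs)
            for origin in ("germline", "somatic"):
                res = cc.resolve_allelic_status(ev, origin=origin)
                exp_status, exp_flag = _oracle_status(ascn, vaf, hit, swgs, origin)
                assert (res.status, res.insufficient_evidence) == (exp_status, exp_flag), \
                    (ascn, vaf, hit, swgs, origin)
                n += 1
        assert n == 3 * 3 * 2 * 4 * 2

    def test_monotonicity_adding_loh_evidence_never_flips_to_monoallelic(self):
        """Strengthening any evidence component keeps biallelic calls."""
        strengthen = {"no_loh": ["loh"], "unknown": ["loh"], "loh": []}
        for ascn, vaf, swgs in itertools.product(
                cc.TRI_STATES, cc.TRI_STATES, (None, "loss", "neutral_or_gain")):
            base = cc.resolve_allelic_status(cc.AllelicEvidence(ascn, vaf, False, swgs))
            if base.status != "biallelic":
                continue
            for a2 in [ascn] + strengthen[ascn]:
                for v2 in [vaf] + strengthen[vaf]:
                    for s2 in {swgs, "loss"}:
                        res = cc.resolve_allelic_status(
                            cc.AllelicEvidence(a2, v2, False, s2))
                        assert res.status == "biallelic", (ascn, vaf, swgs, a2, v2, s2)


class TestCohortClassification:
    def test_classify_sample_assembles_evidence(self):
        variants = [v(vaf_tumour=0.80, vaf_germline=0.50)]
        segs = [ASCNSegment("S1", "16", 1, 50_000_000, 2, 0)]
        row = cc.classify_sample(variants, segs)
        assert row["carrier_group"] == "PALB2_germline"
        assert row["allelic_status"] == "biallelic"
        assert row["ascn_loh"] == "loh" and row["vaf_loh"] == "loh"

    def test_non_carrier_row_has_no_allelic_status(self):
        row = cc.classify_sample([v(gene="OTHER", consequence="other",
                                    origin="somatic")])
        assert row["carrier_group"] == "non_carrier"
        assert row["allelic_status"] == "."

    def test_cohort_table_one_row_per_sample(self):
        variants = [v(sample="A", vaf_tumour=0.8, vaf_germline=0.5),
                    v(sample="B", gene="OTHER", consequence="other",
                      origin="somatic")]
        table = cc.classify_cohort(variants)
        assert list(table["sample_id"]) == ["A", "B"]
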