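"""Synthetic reconstruction of a published PTV tumour cohort summary.

The controlled-access study this pipeline's defaults emulate reported, at
the group level: 9 PALB2 PTV tumours (6 germline / 3 somatic carriers, of
which 2 biallelic via wild-type-allele loss and 1 via a somatic second
PTV), 16 BRCA1 PTV tumours (7 biallelic) and 14 BRCA2 PTV tumours
(7 biallelic), with somatic TP53 mutations in 1/9 and PIK3CA mutations in
2/9 of the PALB2 tumours.  This module reconstructs a per-tumour evidence
table *consistent with those printed counts* — it is synthetic: the real
per-tumour supplementary data are controlled-access and are not shipped.

Running the carrier/allelic pipeline over this table must reproduce the
printed biallelic fractions (33% / 44% / 50%) and driver prevalences
(11% TP53, 22% PIK3CA among PALB2 tumours); the worked example therefore
exercises every branch of the evidence-combination rule on realistic
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import ASCNSegment, VariantRecord

# gene locus coordinates shared with the cohort generator
from .simulate import GENE_LOCI

# per-gene carrier composition: (n_germline, n_somatic, n_loh_biallelic,
# n_second_hit) — biallelic = LOH + second hit
_COMPOSITION = {
    "PALB2": (6, 3, 2, 1),
    "BRCA1": (10, 6, 7, 0),
    "BRCA2": (11, 3, 7, 0),
}

# somatic driver mutations among the PALB2 tumours: sample index -> gene
_PALB2_DRIVERS = {1: "TP53", 2: "PIK3CA", 5: "PIK3CA"}


@dataclass
class WorkedExample:
    variants: list[VariantRecord]
    segments: list[ASCNSegment]
    sample_gene: dict[str, str]


def build_ptv_tumour_table() -> WorkedExample:
    """Per-tumour variant and segment evidence matching the printed counts.

    Biallelic-by-LOH tumours get concordant ASCN (minor copy 0 at the
    locus) and VAF (tumour VAF 0.80 vs germline 0.50) evidence; monoallelic
    tumours get concordant negative evidence; the second-hit tumour carries
    two distinct PTVs with no locus LOH.  Somatic-only carriers have no
    germline VAF, so their ASCN segment alone decides.
    """
    variants: list[VariantRecord] = []
    segments: list[ASCNSegment] = []
    sample_gene: dict[str, str] = {}

    for gene, (n_germ, n_som, n_loh, n_hit) in _COMPOSITION.items():
        chrom, pos = GENE_LOCI[gene]
        total = n_germ + n_som
        for i in range(total):
            sid = f"{gene}_T{i + 1:02d}"
            sample_gene[sid] = gene
            origin = "germline" if i < n_germ else "somatic"
            # evidence layout: first n_hit germline tumours carry a somatic
            # second PTV; the next n_loh tumours have locus LOH
            second_hit = i < n_hit
            locus_loh = (not second_hit) and (i < n_hit + n_loh)

            if origin == "germline":
                vaf_t = 0.80 if locus_loh else 0.52
                variants.append(VariantRecord(
                    sid, chrom, pos, "G", "T", gene=gene,
                    consequence="stop_gained", origin="germline",
                    vaf_tumour=vaf_t, vaf_germline=0.50))
            else:
                variants.append(VariantRecord(
                    sid, chrom, pos, "G", "T", gene=gene,
                    consequence="frameshift", origin="somatic",
                    vaf_tumour=0.42 if locus_loh else 0.28))
            if second_hit:
                variants.append(VariantRecord(
                    sid, chrom, pos + 1200, "C", "A", gene=gene,
                    consequence="splice_donor", origin="somatic",
                    vaf_tumour=0.31))

            cn_minor = 0 if locus_loh else 1
            segments.append(ASCNSegment(
                sid, chrom, max(1, pos - 5_000_000), pos + 5_000_000,
                cn_major=2, cn_minor=cn_minor))

            if gene == "PALB2" and i in _PALB2_DRIVERS:
                driver = _PALB2_DRIVERS[i]
                dchrom, dpos = ("17", 7_577_121) if driver == "TP53" else ("3", 178_936_091)
                variants.append(VariantRecord(
                    sid, dchrom, dpos, "C", "T", gene=driver,
                    consequence="missense", origin="somatic", vaf_tumour=0.35))

    return WorkedExample(variants, segments, sample_gene)


def biallelic_fractions() -> dict[str, float]:
    """Fraction of carrier tumours with biallelic inactivation, per gene,
    computed by running the classification pipeline on the reconstruction."""
    from .carriers import classify_cohort

    ex = build_ptv_tumour_table()
    table = classify_cohort(ex.variants, ex.segments)
    table["gene"] = table["sample_id"].map(ex.sample_gene)
    out = {}
    for gene, sub in table.groupby("gene"):
        out[gene] = float((sub["allelic_status"] == "biallelic").mean())
    return out


def palb2_driver_prevalence() -> dict[str, float]:
    """Prevalence of somatic TP53 / PIK3CA mutations among PALB2 tumours."""
    ex = build_ptv_tumour_table()
    palb2_samples = {s for s, g in ex.sample_gene.items() if g == "PALB2"}
    out = {}
    for driver in ("TP53", "PIK3CA"):
        hit = {v.sample_id for v in ex.variants
               if v.gene == driver and v.origin == "somatic"}
        out[driver] = len(hit & palb2_samples) / len(palb2_samples)
    return out
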