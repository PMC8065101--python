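"""Classify carriers and resolve biallelic status on the worked example.

The reconstructed per-tumour evidence table (synthetic, built from a
published cohort's group-level counts) is pushed through the full
carrier/allelic pipeline: PTV detection, carrier grouping, the two locus
LOH calls (ASCN minor copy number and tumour-vs-germline VAF), and the
evidence-combination rule.
"""

from hrdscape.carriers import classify_cohort
from hrdscape.worked_example import build_ptv_tumour_table

example = build_ptv_tumour_table()
table = classify_cohort(example.variants, example.segments)
table["gene"] = table["sample_id"].map(example.sample_gene)

print(table[["sample_id", "carrier_group", "allelic_status",
             "ascn_loh", "vaf_loh", "somatic_second_hit"]].head(9).to_string(index=False))

print("\nbiallelic fraction per gene (expected 33% / 44% / 50%):")
for gene, sub in table.groupby("gene"):
    frac = (sub["allelic_status"] == "biallelic").mean()
    print(f"  {gene}: {frac:.0%} ({int((sub['allelic_status']=='biallelic').sum())}"
          f"/{len(sub)})")
print("a tumour is biallelic when the wild-type allele is lost (both LOH "
      "routes agree) or a second somatic PTV hits the gene")
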