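"""Carrier grouping and biallelic-status resolution for PALB2/BRCA1/BRCA2.

A sample is a *carrier* when it harbours a protein-truncating variant (PTV:
stop-gain, frameshift, or canonical splice site) in one of the three
homologous-recombination genes; germline PTVs take precedence over somatic
ones for group assignment.  Biallelic inactivation means the second allele is
also lost, established either by a second somatic PTV or by locus-specific
loss of heterozygosity (LOH).

Locus LOH is called by two independent routes and reconciled:

1. ASCN route — the allele-specific copy-number segment overlapping the
   variant locus has minor copy number 0.
2. VAF route — the tumour variant allele fraction exceeds the germline VAF
   by more than ``vaf_delta`` (default 0.20, i.e. 20 percentage points).

When the two routes disagree, an optional per-locus shallow-WGS copy-number
state (``loss`` / ``neutral_or_gain``) breaks the tie.  Evidence that cannot
be resolved (unknowns, missing tie-break) defaults to monoallelic with an
``insufficient_evidence`` flag, because downstream summaries dichotomise.

For somatic-only carriers there is no germline VAF to compare against, so
the ASCN call alone decides LOH (unless a second somatic PTV already proves
biallelic inactivation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import PTV_CONSEQUENCES, STUDY_GENES, ASCNSegment, VariantRecord

LOH, NO_LOH, UNKNOWN = "loh", "no_loh", "unknown"
TRI_STATES = (LOH, NO_LOH, UNKNOWN)
SWGS_STATES = ("loss", "neutral_or_gain", "unknown")

DEFAULT_VAF_DELTA = 0.20


class AmbiguousCarrierError(ValueError):
    """PTVs found in more than one studied gene for a single sample."""


@dataclass(frozen=True)
class CarrierGroup:
    """Carrier category of one sample.

    ``category`` is ``carrier``, ``non_carrier`` or ``excluded_missense``;
    ``gene``/``origin`` are set only for carriers.
    """

    category: str
    gene: str | None = None
    origin: str | None = None

    @property
    def label(self) -> str:
        if self.category == "carrier":
            return f"{self.gene}_{self.origin}"
        return self.category


@dataclass(frozen=True)
class AllelicEvidence:
    ascn_loh: str = UNKNOWN
    vaf_loh: str = UNKNOWN
    somatic_second_hit: bool = False
    swgs_state: str | None = None

    def __post_init__(self):
        if self.ascn_loh not in TRI_STATES:
            raise ValueError(f"bad ascn_loh {self.ascn_loh!r}")
        if self.vaf_loh not in TRI_STATES:
            raise ValueError(f"bad vaf_loh {self.vaf_loh!r}")
        if self.swgs_state is not None and self.swgs_state not in SWGS_STATES:
            raise ValueError(f"bad swgs_state {self.swgs_state!r}")


@dataclass(frozen=True)
class AllelicStatus:
    status: str  # biallelic | monoallelic
    insufficient_evidence: bool
    evidence: AllelicEvidence


def classify_consequence(variant: VariantRecord) -> str:
    """'ptv', 'missense' or 'other' from the annotated consequence term."""
    c = variant.consequence
    if c in PTV_CONSEQUENCES:
        return "ptv"
    if c == "missense":
        return "missense"
    if c == "other":
        return "other"
    raise ValueError(f"unknown consequence {c!r}")


def assign_carrier_group(variants: Sequence[VariantRecord]) -> CarrierGroup:
    """Assign one sample's carrier group from its variants in the study genes.

    Germline PTV > somatic PTV > missense-only (excluded) > non-carrier.
    PTVs in two different studied genes raise :class:`AmbiguousCarrierError`
    rather than being silently resolved.
    """
    sample_ids = {v.sample_id for v in variants}
    if len(sample_ids) > 1:
        raise ValueError(f"variants from multiple samples: {sorted(sample_ids)}")

    in_study = [v for v in variants if v.gene in STUDY_GENES]
    ptvs = [v for v in in_study if classify_consequence(v) == "ptv"]
    ptv_genes = sorted({v.gene for v in ptvs})
    if len(ptv_genes) > 1:
        raise AmbiguousCarrierError(
            f"PTVs in multiple studied genes for sample "
            f"{next(iter(sample_ids), '?')}: {ptv_genes}"
        )
    if ptvs:
        gene = ptv_genes[0]
        origin = "germline" if any(v.origin == "germline" for v in ptvs) else "somatic"
        return CarrierGroup("carrier", gene=gene, origin=origin)
    if any(classify_consequence(v) == "missense" for v in in_study):
        return CarrierGroup("excluded_missense")
    return CarrierGroup("non_carrier")


def has_somatic_second_hit(variants: Sequence[VariantRecord], group: CarrierGroup) -> bool:
    """True when two distinct PTVs hit the carrier gene (second somatic hit)."""
    if group.category != "carrier":
        return False
    hits = {
        (v.origin, v.chrom, v.pos, v.ref, v.alt)
        for v in variants
        if v.gene == group.gene and classify_consequence(v) == "ptv"
    }
    if group.origin == "germline":
        return any(origin == "somatic" for origin, *_ in hits)
    return len(hits) >= 2


def call_locus_loh_ascn(segments: Sequence[ASCNSegment], chrom: str, pos: int) -> str:
    """LOH call from the ASCN segment overlapping the locus; unknown on a gap."""
    from .io import normalize_chrom

    chrom = normalize_chrom(chrom)
    for seg in segments:
        if seg.chrom == chrom and seg.start <= pos <= seg.end:
            return LOH if seg.cn_minor == 0 else NO_LOH
    return UNKNOWN


def call_locus_loh_vaf(
    vaf_tumour: float | None,
    vaf_germline: float | None,
    delta: float = DEFAULT_VAF_DELTA,
) -> str:
    """LOH when the tumour VAF exceeds the germline VAF by more than ``delta``.

    The threshold is an absolute allele-fraction difference (percentage
    points), strictly greater-than.  Either VAF absent -> unknown.
    """
    if vaf_tumour is None or vaf_germline is None:
        return UNKNOWN
    return LOH if (vaf_tumour - vaf_germline) > delta else NO_LOH


def resolve_allelic_status(evidence: AllelicEvidence, origin: str = "germline") -> AllelicStatus:
    """Combine the evidence into a biallelic/monoallelic call.

    Resolution order: a somatic second hit is decisive; otherwise the two LOH
    routes must agree; on disagreement the sWGS state breaks the tie
    (``loss`` -> biallelic); anything unresolved is monoallelic with the
    ``insufficient_evidence`` flag set.  For somatic-origin carriers the VAF
    route is inapplicable and the ASCN call alone decides.
    """
    if origin not in ("germline", "somatic"):
        raise ValueError(f"bad origin {origin!r}")
    if evidence.somatic_second_hit:
        return AllelicStatus("biallelic", False, evidence)

    if origin == "somatic":
        if evidence.ascn_loh == LOH:
            return AllelicStatus("biallelic", False, evidence)
        if evidence.ascn_loh == NO_LOH:
            return AllelicStatus("monoallelic", False, evidence)
        return AllelicStatus("monoallelic", True, evidence)

    a, v = evidence.ascn_loh, evidence.vaf_loh
    if a == LOH and v == LOH:
        return AllelicStatus("biallelic", False, evidence)
    if a == NO_LOH and v == NO_LOH:
        return AllelicStatus("monoallelic", False, evidence)
    if {a, v} == {LOH, NO_LOH}:  # genuine disagreement -> sWGS tie-break
        if evidence.swgs_state == "loss":
            return AllelicStatus("biallelic", False, evidence)
        if evidence.swgs_state == "neutral_or_gain":
            return AllelicStatus("monoallelic", False, evidence)
        return AllelicStatus("monoallelic", True, evidence)
    # at least one route unknown and no agreement possible
    return AllelicStatus("monoallelic", True, evidence)


def classify_sample(
    variants: Sequence[VariantRecord],
    segments: Sequence[ASCNSegment] = (),
    swgs_state: str | None = None,
    vaf_delta: float = DEFAULT_VAF_DELTA,
) -> dict:
    """Run the full carrier/allelic pipeline for one sample; returns a row dict."""
    group = assign_carrier_group(variants)
    row = {
        "sample_id": variants[0].sample_id if variants else "",
        "carrier_group": group.label,
        "allelic_status": ".",
        "ascn_loh": ".",
        "vaf_loh": ".",
        "somatic_second_hit": ".",
        "swgs_state": swgs_state or ".",
        "flags": "",
    }
    if group.category != "carrier":
        return row

    ptvs = [
        v for v in variants
        if v.gene == group.gene and classify_consequence(v) == "ptv"
    ]
    # the evidence locus is the (preferentially germline) PTV's own position
    primary = next((v for v in ptvs if v.origin == group.origin), ptvs[0])
    ascn = call_locus_loh_ascn(segments, primary.chrom, primary.pos)
    if group.origin == "germline":
        vaf = call_locus_loh_vaf(primary.vaf_tumour, primary.vaf_germline, vaf_delta)
    else:
        vaf = UNKNOWN
    evidence = AllelicEvidence(
        ascn_loh=ascn,
        vaf_loh=vaf,
        somatic_second_hit=has_somatic_second_hit(variants, group),
        swgs_state=swgs_state,
    )
    status = resolve_allelic_status(evidence, origin=group.origin)
    row.update({
        "allelic_status": status.status,
        "ascn_loh": evidence.ascn_loh,
        "vaf_loh": evidence.vaf_loh,
        "somatic_second_hit": str(evidence.somatic_second_hit).lower(),
        "flags": "insufficient_evidence" if status.insufficient_evidence else "",
    })
    return row


def classify_cohort(
    variants: Iterable[VariantRecord],
    segments: Iterable[ASCNSegment] = (),
    swgs_states: Mapping[str, str] | None = None,
    vaf_delta: float = DEFAULT_VAF_DELTA,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Classify every sample in ``sample_ids`` (default: those appearing in
    ``variants``).  Samples without any variant evidence are non-carriers."""
    from .io import segments_by_sample

    by_sample: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_sample.setdefault(v.sample_id, []).append(v)
    all_ids = sorted(set(by_sample) | set(sample_ids or []))
    seg_map = segments_by_sample(segments)
    swgs_states = swgs_states or {}
    rows = []
    for sid in all_ids:
        if sid in by_sample:
            rows.append(classify_sample(
                by_sample[sid],
                seg_map.get(sid, []),
                swgs_state=swgs_states.get(sid),
                vaf_delta=vaf_delta,
            ))
        else:
            rows.append({
                "sample_id": sid, "carrier_group": "non_carrier",
                "allelic_status": ".", "ascn_loh": ".", "vaf_loh": ".",
                "somatic_second_hit": ".",
                "swgs_state": swgs_states.get(sid, "."), "flags": "",
            })
    return pd.DataFrame(rows)
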