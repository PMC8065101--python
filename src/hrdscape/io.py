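"""Readers, writers and the cohort data model shared by every pipeline stage.

All coordinates are 1-based inclusive internally (the VCF / Sequenza
convention).  Chromosome names are normalised to a no-``chr``-prefix form at
every boundary, so ``chr17`` and ``17`` refer to the same chromosome.

File dialects
-------------
variants TSV
    Columns ``sample_id  chrom  pos  ref  alt  gene  consequence  origin
    vaf_tumour  vaf_germline  tri_context``; absent optional values are ``.``.
variants VCF
    One patient per file.  INFO keys ``GENE``, ``CSQ`` (consequence term) and
    ``ORIGIN`` (``germline``/``somatic``, default somatic); FORMAT ``AD``.
    The first sample column is the tumour, an optional second one the
    germline; VAF = alt_depth / (ref_depth + alt_depth).
segments TSV (Sequenza dialect)
    Columns ``chromosome  start.pos  end.pos  A  B`` with an optional leading
    ``sample_id`` column for multi-sample files.  ``A``/``B`` are the major /
    minor allele copy numbers; rows with B > A are swapped with a warning.
expression TSV
    First column ``gene``, remaining columns one per sample; values are
    log2(linear + 1).
chromosome map TSV
    Columns ``chrom  length  centromere_start  centromere_end`` (1-based
    inclusive centromere interval).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("hrdscape")

CONSEQUENCES = frozenset(
    {"stop_gained", "frameshift", "splice_donor", "splice_acceptor", "missense", "other"}
)
PTV_CONSEQUENCES = frozenset({"stop_gained", "frameshift", "splice_donor", "splice_acceptor"})
STUDY_GENES = ("PALB2", "BRCA1", "BRCA2")

_BASES = frozenset("ACGT")


def normalize_chrom(chrom: str) -> str:
    """Canonical chromosome name without a ``chr`` prefix."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one sample.

    ``origin`` distinguishes germline from somatic calls; ``vaf_tumour`` /
    ``vaf_germline`` are alternate-allele fractions in the respective DNA and
    may be absent (``None``).  ``tri_context`` is the reference trinucleotide
    centred on the variant position (SNVs only).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    origin: str
    vaf_tumour: float | None = None
    vaf_germline: float | None = None
    tri_context: str | None = None

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref in _BASES and self.alt in _BASES


def validate_variant(v: VariantRecord) -> str | None:
    """Return a description of the first invariant violation, or None."""
    if v.pos < 1:
        return f"pos {v.pos} < 1"
    if v.ref == v.alt:
        return "ref equals alt"
    if v.consequence not in CONSEQUENCES:
        return f"unknown consequence {v.consequence!r}"
    if v.origin not in ("germline", "somatic"):
        return f"unknown origin {v.origin!r}"
    for name, vaf in (("vaf_tumour", v.vaf_tumour), ("vaf_germline", v.vaf_germline)):
        if vaf is not None and not (0.0 <= vaf <= 1.0):
            return f"{name} {vaf} outside [0,1]"
    if v.tri_context is not None:
        if len(v.tri_context) != 3:
            return f"tri_context {v.tri_context!r} not length 3"
        if v.is_snv and v.tri_context[1] != v.ref:
            return f"tri_context middle base {v.tri_context[1]} != ref {v.ref}"
    return None


@dataclass(frozen=True)
class ASCNSegment:
    """An allele-specific copy-number interval: (major, minor) copy numbers."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cn_major: int
    cn_minor: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.cn_minor > self.cn_major:
            raise ValueError("cn_major must be >= cn_minor")
        if self.cn_minor < 0:
            raise ValueError("negative copy number")


class ChromosomeMap:
    """Per-chromosome lengths and centromere intervals (1-based inclusive)."""

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "length", "centromere_start", "centromere_end"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"chromosome map missing columns {sorted(missing)}")
        table = table.copy()
        table["chrom"] = table["chrom"].map(normalize_chrom)
        if table["chrom"].duplicated().any():
            raise ValueError("duplicate chromosome in map")
        for _, row in table.iterrows():
            if not (0 < row.centromere_start <= row.centromere_end <= row.length):
                raise ValueError(
                    f"chrom {row.chrom}: centromere [{row.centromere_start},"
                    f"{row.centromere_end}] incompatible with length {row.length}"
                )
        self._table = table.set_index("chrom")

    @property
    def chroms(self) -> list[str]:
        return list(self._table.index)

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self._table.index

    def length(self, chrom: str) -> int:
        return int(self._table.loc[normalize_chrom(chrom), "length"])

    def centromere(self, chrom: str) -> tuple[int, int]:
        row = self._table.loc[normalize_chrom(chrom)]
        return int(row.centromere_start), int(row.centromere_end)

    def to_frame(self) -> pd.DataFrame:
        return self._table.reset_index()


@dataclass
class GeneSet:
    name: str
    genes: list[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
    "origin", "vaf_tumour", "vaf_germline", "tri_context",
]


def _opt_float(x) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x in (".", ""):
        return None
    return float(x)


def read_variants(path: str | Path, dialect: str = "tsv") -> list[VariantRecord]:
    """Read variant calls from a TSV or VCF file.

    Records that violate the data-model invariants are rejected; the count of
    rejections is logged.  Zero parseable records is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        raw = _variants_from_tsv(path)
    elif dialect == "vcf":
        raw = _variants_from_vcf(path)
    else:
        raise ValueError(f"unknown variants dialect {dialect!r}")

    records, rejected = [], 0
    for v in raw:
        problem = validate_variant(v)
        if problem is None:
            records.append(v)
        else:
            rejected += 1
            log.debug("rejected variant %s:%s %s", v.chrom, v.pos, problem)
    if rejected:
        log.warning("%d variant record(s) rejected while reading %s", rejected, path)
    if not records:
        raise ValueError(f"no parseable variant records in {path}")
    return records


def _variants_from_tsv(path: Path) -> Iterable[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_VARIANT_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise ValueError(f"variants TSV {path} missing columns {sorted(missing)}")
    for row in df.itertuples(index=False):
        d = row._asdict()
        yield VariantRecord(
            sample_id=d["sample_id"],
            chrom=normalize_chrom(d["chrom"]),
            pos=int(d["pos"]),
            ref=d["ref"],
            alt=d["alt"],
            gene=d["gene"],
            consequence=d["consequence"],
            origin=d["origin"],
            vaf_tumour=_opt_float(d.get("vaf_tumour")),
            vaf_germline=_opt_float(d.get("vaf_germline")),
            tri_context=None if d.get("tri_context", ".") in (".", "") else d["tri_context"],
        )


def _variants_from_vcf(path: Path) -> Iterable[VariantRecord]:
    from cyvcf2 import VCF  # deferred: only needed for the VCF dialect

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # malformed header
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = vcf.samples
    if not samples:
        raise ValueError(f"VCF {path} has no sample columns")
    sample_id = samples[0]

    def _vaf(rec, i):
        try:
            ad = rec.format("AD")
        except KeyError:
            return None
        if ad is None or i >= ad.shape[0]:
            return None
        depths = ad[i]
        total = float(depths[0]) + float(depths[1])
        if total <= 0 or depths[0] < 0 or depths[1] < 0:
            return None
        return float(depths[1]) / total

    for rec in vcf:
        gene = rec.INFO.get("GENE")
        csq = rec.INFO.get("CSQ")
        origin = rec.INFO.get("ORIGIN") or "somatic"
        if gene is None or csq is None:
            continue
        vaf_t = _vaf(rec, 0)
        vaf_g = _vaf(rec, 1) if len(samples) > 1 else None
        for alt in rec.ALT:
            yield VariantRecord(
                sample_id=sample_id,
                chrom=normalize_chrom(rec.CHROM),
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                gene=gene,
                consequence=csq,
                origin=origin,
                vaf_tumour=vaf_t,
                vaf_germline=vaf_g,
            )


def write_variants(records: Sequence[VariantRecord], path: str | Path) -> None:
    rows = []
    for v in records:
        rows.append({
            "sample_id": v.sample_id, "chrom": v.chrom, "pos": v.pos,
            "ref": v.ref, "alt": v.alt, "gene": v.gene,
            "consequence": v.consequence, "origin": v.origin,
            "vaf_tumour": "." if v.vaf_tumour is None else f"{v.vaf_tumour:.4f}",
            "vaf_germline": "." if v.vaf_germline is None else f"{v.vaf_germline:.4f}",
            "tri_context": v.tri_context or ".",
        })
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ASCN segments
# ---------------------------------------------------------------------------


def read_segments(path: str | Path, sample_id: str | None = None) -> list[ASCNSegment]:
    """Read allele-specific copy-number segments (Sequenza TSV dialect).

    Per sample and chromosome the returned segments are sorted by start and
    validated for non-overlap; an overlapping pair raises naming both
    segments.  Rows with B > A are repaired by swapping, with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    colmap = {"chromosome": "chrom", "start.pos": "start", "end.pos": "end",
              "A": "cn_major", "B": "cn_minor"}
    df = df.rename(columns=colmap)
    required = {"chrom", "start", "end", "cn_major", "cn_minor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segments file {path} missing columns {sorted(missing)}")
    if "sample_id" not in df.columns:
        if sample_id is None:
            raise ValueError(
                f"segments file {path} has no sample_id column; pass sample_id="
            )
        df["sample_id"] = sample_id

    swapped = int((df["cn_minor"] > df["cn_major"]).sum())
    if swapped:
        log.warning("%d segment row(s) with B > A swapped in %s", swapped, path)
        lo = df[["cn_major", "cn_minor"]].min(axis=1)
        hi = df[["cn_major", "cn_minor"]].max(axis=1)
        df["cn_major"], df["cn_minor"] = hi, lo

    df["chrom"] = df["chrom"].map(normalize_chrom)
    df = df.sort_values(["sample_id", "chrom", "start"], kind="mergesort")
    segments = [
        ASCNSegment(r.sample_id, r.chrom, int(r.start), int(r.end),
                    int(r.cn_major), int(r.cn_minor))
        for r in df.itertuples(index=False)
    ]
    _check_overlap(segments)
    return segments


def _check_overlap(segments: Sequence[ASCNSegment]) -> None:
    prev: ASCNSegment | None = None
    for seg in segments:
        if prev is not None and (seg.sample_id, seg.chrom) == (prev.sample_id, prev.chrom):
            if seg.start <= prev.end:
                raise ValueError(
                    "overlapping segments for sample "
                    f"{seg.sample_id} chrom {seg.chrom}: "
                    f"[{prev.start},{prev.end}] and [{seg.start},{seg.end}]"
                )
        prev = seg


def write_segments(segments: Sequence[ASCNSegment], path: str | Path) -> None:
    rows = [{
        "sample_id": s.sample_id, "chromosome": s.chrom, "start.pos": s.start,
        "end.pos": s.end, "A": s.cn_major, "B": s.cn_minor,
    } for s in segments]
    cols = ["sample_id", "chromosome", "start.pos", "end.pos", "A", "B"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def segments_by_sample(segments: Iterable[ASCNSegment]) -> dict[str, list[ASCNSegment]]:
    out: dict[str, list[ASCNSegment]] = {}
    for s in segments:
        out.setdefault(s.sample_id, []).append(s)
    return out


# ---------------------------------------------------------------------------
# expression matrix, chromosome map, gene sets, generic tables
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample log2-scale expression matrix (genes as index)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene row(s) in {path}: {dups}")
    if pd.Index(df.columns).duplicated().any():
        raise ValueError(f"duplicate sample column(s) in {path}")
    if df.isna().any().any():
        where = [(g, s) for g, s in zip(*np.where(df.isna().to_numpy()))]
        coords = [(df.index[g], df.columns[s]) for g, s in where[:5]]
        raise ValueError(f"missing expression values at (gene, sample): {coords}")
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene", float_format="%.4f")


def read_chrom_map(path: str | Path) -> ChromosomeMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return ChromosomeMap(pd.read_csv(path, sep="\t"))


def write_chrom_map(cmap: ChromosomeMap, path: str | Path) -> None:
    cmap.to_frame().to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets.append(GeneSet(parts[0], parts[2:]))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, ""] + list(gs.genes)) + "\n")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError(f"cohort table {path} missing sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample ids in cohort table {path}")
    return df


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a generic result table with fixed column order and float format."""
    rows.to_csv(path, sep="\t", index=False, float_format="%.6g")
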