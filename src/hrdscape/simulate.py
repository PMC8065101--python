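"""Synthetic breast-tumour cohort generator with ground-truth labels.

The generator emits, in the exact file dialects the readers consume, a
cohort with the statistical structure the analysis assumes: PTV carrier
groups for PALB2/BRCA1/BRCA2 with configurable biallelic subsets, elevated
somatic SNV burden / signature-3 weight / genomic scar scores in biallelic
tumours, germline-locus VAF elevation under LOH, and immune-gene elevation
in BRCA1 tumours.  Default group sizes and per-stratum targets follow the
published cohort the pipeline emulates (9/16/14 carrier tumours with
biallelic subsets 3/7/7 against several hundred non-carriers; SNV medians
125/146/214 vs 46; signature-3 means 0.489/0.444/0.395 vs 0.082; scar-score
medians LOH 14/19/13, TAI 27/26/19, LST 22/26/21 vs 6/9/7).

Scar events are implanted so that each contributes to exactly one score:

* LOH events are interior minor-copy-0 segments (16-28 Mb),
* TAI events are telomeric allelic-imbalance segments (>= 11 Mb),
* LST events are adjacent 10-14 Mb segment pairs with differing balanced
  states,

and every event is isolated from its neighbours by 3.5 Mb coverage gaps
(larger than the 3 Mb LST smoothing window), so the implanted event counts
recorded in the ground truth are exactly the scores the scorer should
report.  The genome is a reduced synthetic one: 22 autosomes with realistic
lengths and centromere positions, no sex chromosomes.

All randomness flows from a single seed through named, deterministically
spawned streams; two runs with the same config produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import nbinom, poisson

from . import io as cio
from .immune import CYT_GENES, load_default_immune_set
from .signatures import CHANNELS, SignatureMatrix, load_default_signatures, revcomp

GENES = ("PALB2", "BRCA1", "BRCA2")

# reduced synthetic genome: GRCh37-like autosome lengths and centromeres (bp)
_GENOME: dict[str, tuple[int, int, int]] = {
    "1": (249_250_000, 121_500_000, 142_500_000),
    "2": (243_200_000, 90_500_000, 96_800_000),
    "3": (198_000_000, 87_900_000, 93_900_000),
    "4": (191_150_000, 48_200_000, 52_700_000),
    "5": (180_900_000, 46_100_000, 50_700_000),
    "6": (171_100_000, 58_800_000, 63_300_000),
    "7": (159_100_000, 58_100_000, 61_100_000),
    "8": (146_400_000, 43_100_000, 48_100_000),
    "9": (141_200_000, 47_300_000, 50_700_000),
    "10": (135_500_000, 38_000_000, 42_300_000),
    "11": (135_000_000, 51_600_000, 55_700_000),
    "12": (133_900_000, 33_300_000, 38_200_000),
    "13": (115_200_000, 16_000_000, 19_500_000),
    "14": (107_300_000, 16_000_000, 19_100_000),
    "15": (102_500_000, 15_800_000, 20_700_000),
    "16": (90_300_000, 34_600_000, 38_600_000),
    "17": (81_200_000, 22_200_000, 25_800_000),
    "18": (78_100_000, 15_400_000, 19_000_000),
    "19": (59_100_000, 24_400_000, 28_600_000),
    "20": (63_000_000, 25_600_000, 29_400_000),
    "21": (48_100_000, 10_900_000, 14_300_000),
    "22": (51_300_000, 12_200_000, 17_900_000),
}

GENE_LOCI: dict[str, tuple[str, int]] = {
    "PALB2": ("16", 23_646_191),
    "BRCA1": ("17", 41_276_045),
    "BRCA2": ("13", 32_936_732),
}

EVENT_GAP = 3_500_000  # isolates implanted events from each other / baseline


def default_chrom_map() -> cio.ChromosomeMap:
    rows = [{"chrom": c, "length": l, "centromere_start": cs, "centromere_end": ce}
            for c, (l, cs, ce) in _GENOME.items()]
    return cio.ChromosomeMap(pd.DataFrame(rows))


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the published cohort's group sizes and per-stratum targets;
    distribution rate parameters are solved so the distribution *median*
    matches the stated target.
    """

    seed: int = 0
    group_sizes: dict = field(default_factory=lambda: {"PALB2": 9, "BRCA1": 16, "BRCA2": 14})
    germline_counts: dict = field(default_factory=lambda: {"PALB2": 6, "BRCA1": 10, "BRCA2": 11})
    biallelic_counts: dict = field(default_factory=lambda: {"PALB2": 3, "BRCA1": 7, "BRCA2": 7})
    second_hit_counts: dict = field(default_factory=lambda: {"PALB2": 1, "BRCA1": 0, "BRCA2": 0})
    n_noncarrier: int = 500

    snv_median_biallelic: dict = field(default_factory=lambda: {"PALB2": 125, "BRCA1": 146, "BRCA2": 214})
    snv_median_monoallelic: dict = field(default_factory=lambda: {"PALB2": 74, "BRCA1": 42, "BRCA2": 68})
    snv_median_noncarrier: int = 46
    nb_dispersion: float = 1.0  # negative binomial size parameter

    sig3_mean_biallelic: dict = field(default_factory=lambda: {"PALB2": 0.489, "BRCA1": 0.444, "BRCA2": 0.395})
    sig3_mean_monoallelic: dict = field(default_factory=lambda: {"PALB2": 0.188, "BRCA1": 0.151, "BRCA2": 0.306})
    sig3_mean_noncarrier: float = 0.082
    sig3_concentration: float = 30.0  # Beta concentration of per-sample sig3 weight

    loh_median_biallelic: dict = field(default_factory=lambda: {"PALB2": 14, "BRCA1": 19, "BRCA2": 13})
    tai_median_biallelic: dict = field(default_factory=lambda: {"PALB2": 27, "BRCA1": 26, "BRCA2": 19})
    lst_median_biallelic: dict = field(default_factory=lambda: {"PALB2": 22, "BRCA1": 26, "BRCA2": 21})
    loh_median_background: int = 6   # non-carriers and monoallelic carriers
    tai_median_background: int = 9
    lst_median_background: int = 7

    purity: float = 0.7
    vaf_noise_sd: float = 0.02
    expr_baseline_mean: float = 6.0
    expr_baseline_sd: float = 1.5
    expr_sample_sd: float = 0.8
    immune_effect_brca1: float = 1.2   # log2 shift of immune genes in BRCA1 tumours
    own_gene_effect_biallelic: float = -1.0  # log2 shift of the carrier's own gene
    n_filler_genes: int = 120

    def validate(self) -> None:
        for gene in GENES:
            if not (0 <= self.biallelic_counts[gene] <= self.group_sizes[gene]):
                raise ValueError(f"{gene}: biallelic subset exceeds group size")
            if not (0 <= self.germline_counts[gene] <= self.group_sizes[gene]):
                raise ValueError(f"{gene}: germline count exceeds group size")
            if self.second_hit_counts[gene] > self.biallelic_counts[gene]:
                raise ValueError(f"{gene}: second-hit count exceeds biallelic subset")
        if not (0 < self.purity <= 1):
            raise ValueError("purity must be in (0, 1]")
        if self.nb_dispersion <= 0 or self.sig3_concentration <= 0:
            raise ValueError("rate parameters must be > 0")
        if self.n_noncarrier < 0 or self.vaf_noise_sd < 0:
            raise ValueError("sizes and noise must be >= 0")


def _nb_mu_for_median(target: float, dispersion: float) -> float:
    """Mean of a negative binomial (size=dispersion) whose median is target."""
    lo, hi = 1e-3, max(10.0, target * 20)
    for _ in range(200):
        mid = (lo + hi) / 2
        med = nbinom.median(dispersion, dispersion / (dispersion + mid))
        if med < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _poisson_lambda_for_median(target: float) -> float:
    lo, hi = 1e-3, max(10.0, target * 4)
    for _ in range(200):
        mid = (lo + hi) / 2
        if poisson.median(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def spectrum_sampler(
    weights: dict[str, float],
    signatures: SignatureMatrix,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial channel draws from a signature mixture.

    Weights must be non-negative and sum to <= 1; any remaining mass goes to
    a flat background over the 96 channels.  Returns channel indices.
    """
    if any(w < 0 for w in weights.values()):
        raise ValueError("negative signature weight")
    total = sum(weights.values())
    if total > 1 + 1e-9:
        raise ValueError("signature weights sum to > 1")
    mix = np.full(96, (1.0 - total) / 96.0)
    for name, w in weights.items():
        mix += w * signatures.profiles[:, signatures.names.index(name)]
    mix = mix / mix.sum()
    return rng.choice(96, size=n, p=mix)


# ---------------------------------------------------------------------------
# segment construction
# ---------------------------------------------------------------------------


class _Placer:
    """Tracks free intervals per chromosome and places isolated events."""

    def __init__(self, chrom_map: cio.ChromosomeMap):
        self.cmap = chrom_map
        # interior free intervals exclude position 1 / length so interior
        # events never touch a telomere, and exclude the centromere
        self.free: dict[str, list[tuple[int, int]]] = {}
        self.telomere_slots: list[tuple[str, str]] = []
        for chrom in chrom_map.chroms:
            length = chrom_map.length(chrom)
            cs, ce = chrom_map.centromere(chrom)
            self.free[chrom] = [(2, cs - 1), (ce + 1, length - 1)]
            self.telomere_slots.append((chrom, "p"))
            self.telomere_slots.append((chrom, "q"))
        self.placed: dict[str, list[tuple[int, int, int, int]]] = {
            c: [] for c in chrom_map.chroms
        }

    def _carve(self, chrom: str, start: int, end: int) -> None:
        pad_start, pad_end = start - EVENT_GAP, end + EVENT_GAP
        new: list[tuple[int, int]] = []
        for a, b in self.free[chrom]:
            if pad_end < a or pad_start > b:
                new.append((a, b))
                continue
            if a < pad_start:
                new.append((a, pad_start - 1))
            if b > pad_end:
                new.append((pad_end + 1, b))
        self.free[chrom] = new

    def place_telomeric(self, chrom: str, arm: str, span: int,
                        state: tuple[int, int]) -> bool:
        length = self.cmap.length(chrom)
        cs, ce = self.cmap.centromere(chrom)
        if arm == "p":
            start, end = 1, span
            if end > cs - 1 - EVENT_GAP:
                return False
            ok = any(a <= 2 and b >= end + EVENT_GAP for a, b in self.free[chrom])
        else:
            start, end = length - span + 1, length
            if start < ce + 1 + EVENT_GAP:
                return False
            ok = any(a <= start - EVENT_GAP and b >= length - 1 for a, b in self.free[chrom])
        if not ok:
            return False
        self.placed[chrom].append((start, end, *state))
        self._carve(chrom, start, end)
        return True

    def place_interior(self, rng: np.random.Generator, span: int,
                       states: list[tuple[int, int]],
                       at: tuple[str, int] | None = None) -> bool:
        """Place one interior event of total span ``span``; ``states`` splits
        the span into equal consecutive pieces (1 piece = LOH, 2 = LST pair).
        ``at`` pins the event to contain a (chrom, pos) locus."""
        need = span + 2 * EVENT_GAP
        if at is not None:
            chrom, pos = at
            for a, b in self.free[chrom]:
                lo = max(a + EVENT_GAP, pos - span + 1)
                hi = min(b - EVENT_GAP - span + 1, pos)
                if lo <= hi:
                    start = (lo + hi) // 2
                    self._record(chrom, start, span, states)
                    return True
            return False
        chroms = list(self.free)
        order = rng.permutation(len(chroms))
        for ci in order:
            chrom = chroms[ci]
            slots = [(a, b) for a, b in self.free[chrom] if b - a + 1 >= need]
            if not slots:
                continue
            a, b = slots[int(rng.integers(len(slots)))]
            start = int(rng.integers(a + EVENT_GAP, b - EVENT_GAP - span + 2))
            self._record(chrom, start, span, states)
            return True
        return False

    def _record(self, chrom: str, start: int, span: int,
                states: list[tuple[int, int]]) -> None:
        piece = span // len(states)
        cursor = start
        for i, state in enumerate(states):
            end = start + span - 1 if i == len(states) - 1 else cursor + piece - 1
            self.placed[chrom].append((cursor, end, *state))
            cursor = end + 1
        self._carve(chrom, start, start + span - 1)

    def baseline_fill(self) -> None:
        for chrom, intervals in self.free.items():
            for a, b in intervals:
                if b >= a:
                    self.placed[chrom].append((a, b, 1, 1))
        # extend outermost baseline to the telomeres where free
        self.free = {c: [] for c in self.free}

    def segments(self, sample_id: str) -> list[cio.ASCNSegment]:
        out = []
        for chrom in self.cmap.chroms:
            for start, end, a, b in sorted(self.placed[chrom]):
                out.append(cio.ASCNSegment(sample_id, chrom, start, end, a, b))
        return out


def _build_segments(
    rng: np.random.Generator,
    sample_id: str,
    chrom_map: cio.ChromosomeMap,
    n_loh: int,
    n_tai: int,
    n_lst: int,
    locus: tuple[str, int] | None,
    protect: tuple[str, int] | None = None,
) -> tuple[list[cio.ASCNSegment], int, int, int]:
    """Implant isolated scar events; returns segments and realised counts.

    ``locus`` pins an LOH event over the germline-variant position;
    ``protect`` instead pins a copy-neutral (1,1) segment there so that
    random events cannot create spurious locus LOH in samples whose ground
    truth has none.
    """
    placer = _Placer(chrom_map)
    placed_loh = placed_tai = placed_lst = 0

    if locus is not None:
        if not placer.place_interior(rng, 16_000_000, [(2, 0)], at=locus):
            raise ValueError(f"cannot place locus LOH event at {locus}")
        placed_loh += 1
        n_loh = max(0, n_loh - 1)
    elif protect is not None:
        if not placer.place_interior(rng, 10_000_000, [(1, 1)], at=protect):
            raise ValueError(f"cannot place protective segment at {protect}")

    slots = [placer.telomere_slots[i] for i in rng.permutation(len(placer.telomere_slots))]
    for _ in range(n_tai):
        state = (2, 1) if rng.random() < 0.7 else (3, 1)
        span = int(rng.integers(11_000_000, 22_000_000))
        while slots:
            chrom, arm = slots.pop()
            if placer.place_telomeric(chrom, arm, span, state):
                placed_tai += 1
                break
        else:
            break  # telomere capacity exhausted

    for _ in range(n_loh):
        span = int(rng.integers(16_000_000, 28_000_000))
        state = (2, 0) if rng.random() < 0.7 else (1, 0)
        if placer.place_interior(rng, span, [state]):
            placed_loh += 1
    for _ in range(n_lst):
        span = int(rng.integers(20_000_000, 28_000_000))
        right = (2, 2) if rng.random() < 0.7 else (3, 3)
        if placer.place_interior(rng, span, [(1, 1), right]):
            placed_lst += 1

    placer.baseline_fill()
    return placer.segments(sample_id), placed_loh, placed_tai, placed_lst


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


_PTV_CONSEQ = ("stop_gained", "frameshift", "splice_donor", "splice_acceptor")


def _decode_channel(idx: int, rng: np.random.Generator) -> tuple[str, str, str]:
    """(ref, alt, tri_context) for a channel index, with random strand."""
    label = CHANNELS[idx]
    f5, ref, alt, f3 = label[0], label[2], label[4], label[6]
    ctx = f5 + ref + f3
    if rng.random() < 0.5:  # place on the opposite strand
        ctx = revcomp(ctx)
        ref, alt = revcomp(ref), revcomp(alt)
    return ref, alt, ctx


@dataclass
class CohortFiles:
    outdir: Path
    variants: Path
    segments: Path
    expression: Path
    chrom_map: Path
    cohort: Path
    ground_truth: Path


def generate_cohort(config: GeneratorConfig, outdir: str | Path) -> CohortFiles:
    """Generate and write the full synthetic cohort; returns the file paths.

    Emits variants.tsv, segments.tsv, expression.tsv, chrom_map.tsv,
    cohort.tsv and ground_truth.tsv in ``outdir``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(child) for name, child in zip(
        ["roster", "snv", "scar", "vaf", "expr", "pathology"], ss.spawn(6))}

    chrom_map = default_chrom_map()
    signatures = load_default_signatures()
    sig3_rest = ["Signature 1", "Signature 2", "Signature 13", "Signature 18"]

    # --- roster with ground-truth statuses -------------------------------
    roster: list[dict] = []
    idx = 1
    for gene in GENES:
        size = config.group_sizes[gene]
        n_germ = config.germline_counts[gene]
        n_bi = config.biallelic_counts[gene]
        n_hit = config.second_hit_counts[gene]
        n_loh_bi = n_bi - n_hit
        for j in range(size):
            origin = "germline" if j < n_germ else "somatic"
            second_hit = j < n_hit  # second-hit samples are germline carriers
            locus_loh = (not second_hit) and (j < n_hit + n_loh_bi)
            biallelic = second_hit or locus_loh
            roster.append({
                "sample_id": f"S{idx:04d}", "gene": gene, "origin": origin,
                "carrier_group": f"{gene}_{origin}",
                "allelic_status": "biallelic" if biallelic else "monoallelic",
                "locus_loh": locus_loh, "second_hit": second_hit,
            })
            idx += 1
    for _ in range(config.n_noncarrier):
        roster.append({
            "sample_id": f"S{idx:04d}", "gene": ".", "origin": ".",
            "carrier_group": "non_carrier", "allelic_status": ".",
            "locus_loh": False, "second_hit": False,
        })
        idx += 1

    # --- per-stratum distribution parameters -----------------------------
    th = config.nb_dispersion
    nb_mu = {("bi", g): _nb_mu_for_median(config.snv_median_biallelic[g], th) for g in GENES}
    nb_mu.update({("mono", g): _nb_mu_for_median(config.snv_median_monoallelic[g], th) for g in GENES})
    nb_mu[("nc", ".")] = _nb_mu_for_median(config.snv_median_noncarrier, th)
    lam = {}
    for g in GENES:
        lam[("bi", g)] = (
            _poisson_lambda_for_median(config.loh_median_biallelic[g]),
            _poisson_lambda_for_median(config.tai_median_biallelic[g]),
            _poisson_lambda_for_median(config.lst_median_biallelic[g]),
        )
    lam_bg = (
        _poisson_lambda_for_median(config.loh_median_background),
        _poisson_lambda_for_median(config.tai_median_background),
        _poisson_lambda_for_median(config.lst_median_background),
    )

    def stratum_of(row) -> tuple[str, str]:
        if row["carrier_group"] == "non_carrier":
            return ("nc", ".")
        return ("bi" if row["allelic_status"] == "biallelic" else "mono", row["gene"])

    # --- variants, segments, ground truth --------------------------------
    rng_snv, rng_scar, rng_vaf = streams["snv"], streams["scar"], streams["vaf"]
    variants: list[cio.VariantRecord] = []
    segments: list[cio.ASCNSegment] = []
    truth_rows: list[dict] = []
    chrom_names = chrom_map.chroms
    chrom_lens = np.array([chrom_map.length(c) for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()

    for row in roster:
        sid = row["sample_id"]
        stratum = stratum_of(row)
        gene = row["gene"]

        # somatic SNV burden from the stratum's signature mixture
        n_snv = int(rng_snv.negative_binomial(th, th / (th + nb_mu[stratum])))
        if stratum[0] == "bi":
            m3 = config.sig3_mean_biallelic[gene]
        elif stratum[0] == "mono":
            m3 = config.sig3_mean_monoallelic[gene]
        else:
            m3 = config.sig3_mean_noncarrier
        c = config.sig3_concentration
        sig3_w = float(rng_snv.beta(c * m3, c * (1 - m3)))
        rest = rng_snv.dirichlet(np.full(len(sig3_rest), 2.0)) * (1 - sig3_w)
        weights = {"Signature 3": sig3_w, **dict(zip(sig3_rest, rest))}
        channels = spectrum_sampler(weights, signatures, n_snv, rng_snv)
        chrom_idx = rng_snv.choice(len(chrom_names), size=n_snv, p=chrom_p)
        for ch_i, cidx in zip(channels, chrom_idx):
            ref, alt, ctx = _decode_channel(int(ch_i), rng_snv)
            chrom = chrom_names[cidx]
            pos = int(rng_snv.integers(2, chrom_map.length(chrom) - 1))
            vaf_t = float(np.clip(rng_vaf.normal(config.purity / 2, 0.05), 0.02, 0.98))
            variants.append(cio.VariantRecord(
                sid, chrom, pos, ref, alt, gene="OTHER", consequence="other",
                origin="somatic", vaf_tumour=round(vaf_t, 4), tri_context=ctx))

        # PTV variant(s) at the gene locus
        if row["carrier_group"] != "non_carrier":
            chrom, pos = GENE_LOCI[gene]
            conseq = _PTV_CONSEQ[int(rng_vaf.integers(len(_PTV_CONSEQ)))]
            if row["origin"] == "germline":
                vaf_g = float(np.clip(rng_vaf.normal(0.5, config.vaf_noise_sd), 0.05, 0.95))
                if row["locus_loh"]:
                    vaf_t = float(np.clip(
                        rng_vaf.normal(0.5 + config.purity / 2, config.vaf_noise_sd), 0.05, 0.99))
                else:
                    vaf_t = float(np.clip(rng_vaf.normal(0.5, config.vaf_noise_sd), 0.05, 0.95))
                variants.append(cio.VariantRecord(
                    sid, chrom, pos, "G", "T", gene=gene, consequence=conseq,
                    origin="germline", vaf_tumour=round(vaf_t, 4),
                    vaf_germline=round(vaf_g, 4)))
            else:
                vaf_t = float(np.clip(rng_vaf.normal(config.purity / 2, 0.05), 0.02, 0.98))
                variants.append(cio.VariantRecord(
                    sid, chrom, pos, "G", "T", gene=gene, consequence=conseq,
                    origin="somatic", vaf_tumour=round(vaf_t, 4)))
            if row["second_hit"]:
                conseq2 = _PTV_CONSEQ[int(rng_vaf.integers(len(_PTV_CONSEQ)))]
                vaf_t = float(np.clip(rng_vaf.normal(config.purity / 2, 0.05), 0.02, 0.98))
                variants.append(cio.VariantRecord(
                    sid, chrom, pos + 1500, "C", "A", gene=gene, consequence=conseq2,
                    origin="somatic", vaf_tumour=round(vaf_t, 4)))

        # segments with implanted, isolated scar events
        l_loh, l_tai, l_lst = lam[stratum] if stratum[0] == "bi" else lam_bg
        n_loh = int(rng_scar.poisson(l_loh))
        n_tai = int(rng_scar.poisson(l_tai))
        n_lst = int(rng_scar.poisson(l_lst))
        locus = GENE_LOCI[gene] if row["locus_loh"] else None
        protect = None
        if locus is None and row["carrier_group"] != "non_carrier":
            protect = GENE_LOCI[gene]
        if locus is not None:
            n_loh = max(1, n_loh)
        segs, got_loh, got_tai, got_lst = _build_segments(
            rng_scar, sid, chrom_map, n_loh, n_tai, n_lst, locus, protect)
        segments.extend(segs)

        truth_rows.append({
            **row, "n_snv": n_snv, "true_sig3": round(sig3_w, 4),
            "loh_events": got_loh, "tai_events": got_tai, "lst_events": got_lst,
        })

    # --- expression matrix ------------------------------------------------
    rng_expr = streams["expr"]
    immune_genes = load_default_immune_set().genes
    gene_list = list(GENES) + [g for g in CYT_GENES if g not in immune_genes] \
        + immune_genes + [f"FILLER{i:03d}" for i in range(1, config.n_filler_genes + 1)]
    base = rng_expr.normal(config.expr_baseline_mean, config.expr_baseline_sd, len(gene_list))
    sample_ids = [r["sample_id"] for r in roster]
    values = rng_expr.normal(
        base[:, None], config.expr_sample_sd, (len(gene_list), len(sample_ids)))
    gene_pos = {g: i for i, g in enumerate(gene_list)}
    immune_idx = [gene_pos[g] for g in set(immune_genes) | set(CYT_GENES)]
    for j, row in enumerate(roster):
        if row["gene"] == "BRCA1":
            values[immune_idx, j] += config.immune_effect_brca1
        if row["allelic_status"] == "biallelic":
            values[gene_pos[row["gene"]], j] += config.own_gene_effect_biallelic
    expr = pd.DataFrame(np.clip(values, 0, None), index=gene_list, columns=sample_ids)

    # --- cohort pathology table ------------------------------------------
    rng_path = streams["pathology"]
    cohort_rows = []
    for row in roster:
        gene = row["gene"]
        if gene == "BRCA1":
            er = "neg" if rng_path.random() < 0.85 else "pos"
            pr = "neg" if rng_path.random() < 0.85 else "pos"
        elif gene == "BRCA2":
            er = "pos" if rng_path.random() < 0.85 else "neg"
            pr = "pos" if rng_path.random() < 0.65 else "neg"
        else:
            er = "pos" if rng_path.random() < 0.6 else "neg"
            pr = "pos" if rng_path.random() < 0.55 else "neg"
        her2 = "pos" if rng_path.random() < 0.2 else "neg"
        grade = str(int(rng_path.integers(2, 4))) if gene in GENES else \
            str(int(rng_path.integers(1, 4)))
        cohort_rows.append({"sample_id": row["sample_id"], "er": er, "pr": pr,
                            "her2": her2, "grade": grade, "carrier_group": ""})

    # --- write everything --------------------------------------------------
    files = CohortFiles(
        outdir=outdir,
        variants=outdir / "variants.tsv",
        segments=outdir / "segments.tsv",
        expression=outdir / "expression.tsv",
        chrom_map=outdir / "chrom_map.tsv",
        cohort=outdir / "cohort.tsv",
        ground_truth=outdir / "ground_truth.tsv",
    )
    cio.write_variants(variants, files.variants)
    cio.write_segments(segments, files.segments)
    cio.write_expression(expr, files.expression)
    cio.write_chrom_map(chrom_map, files.chrom_map)
    pd.DataFrame(cohort_rows).to_csv(files.cohort, sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(files.ground_truth, sep="\t", index=False)
    return files
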