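"""96-channel mutation catalogues and signature refitting.

The catalogue follows the canonical single-base-substitution convention:
six pyrimidine-centred substitution classes (C>A, C>G, C>T, T>A, T>C, T>G),
each split by the 16 flanking-base contexts in lexicographic order, giving
96 channels such as ``A[C>A]A``.  SNVs with a purine reference base are
reverse-complemented onto the pyrimidine strand before binning.

``refit_exposures`` re-implements the greedy forward-refitting algorithm of
the widely used signature-refit tools: the catalogue is normalised to a
96-bin spectrum, and each iteration golden-section-searches, for every
signature, the weight increment minimising the sum of squared errors between
the spectrum and the *normalised* weighted reconstruction; the single best
increment is applied, and iteration stops when the SSE improvement falls
below ``tol`` (default 1e-4: on normalised 96-bin spectra the total SSE
is itself of order 1e-3, so a coarser threshold under-fits minor
signatures and lets flat profiles absorb their mass).  Final weights are
normalised to sum to 1 and weights below
``weight_cutoff`` are zeroed without renormalisation, so the reported
weights may sum to less than 1.

The packaged signature matrix (``data/signatures_96x13_synthetic.tsv``) is a
deterministic synthetic stand-in carrying the thirteen breast-cancer
signature names commonly used in refitting; it is not the reference COSMIC
matrix, and any 96 x K probability matrix can be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import VariantRecord

log = logging.getLogger("hrdscape")

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = "ACGT"
CHANNELS: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in _FLANKS for f3 in _FLANKS
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_of(ref: str, alt: str, tri_context: str) -> str:
    """Canonical channel label for an SNV, folding onto the pyrimidine strand."""
    if ref in "AG":
        tri_context = revcomp(tri_context)
        ref, alt = revcomp(ref), revcomp(alt)
    return f"{tri_context[0]}[{ref}>{alt}]{tri_context[2]}"


@dataclass
class MutationCatalog:
    """Per-sample counts over the 96 canonical substitution channels."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (96,):
            raise ValueError("catalogue must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("negative channel count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def spectrum(self) -> np.ndarray:
        t = self.total
        return self.counts / t if t else np.zeros(96)


@dataclass
class SignatureMatrix:
    """K signature profiles over the 96 channels; columns sum to 1."""

    names: list[str]
    profiles: np.ndarray  # (96, K)

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (96, len(self.names)):
            raise ValueError("profiles must be 96 x len(names)")
        if (self.profiles < 0).any():
            raise ValueError("negative signature probability")
        sums = self.profiles.sum(axis=0)
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValueError(
                f"signature column(s) do not sum to 1: {[self.names[i] for i in bad]}"
            )

    @property
    def k(self) -> int:
        return len(self.names)

    def subset(self, names: Sequence[str]) -> "SignatureMatrix":
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(list(names), self.profiles[:, idx])


@dataclass
class ExposureVector:
    """Refitted per-signature weights; ``insufficient`` when the catalogue
    had fewer SNVs than the refit minimum and no weights were estimated."""

    sample_id: str
    names: list[str]
    weights: np.ndarray | None
    residual_sse: float
    insufficient: bool = False

    def weight_of(self, name: str) -> float:
        if self.weights is None:
            raise ValueError(f"no exposures for {self.sample_id} (insufficient SNVs)")
        return float(self.weights[self.names.index(name)])


def build_catalog(
    snvs: Iterable[VariantRecord],
    sample_id: str | None = None,
    context_source: Callable[[str, int], str] | None = None,
) -> MutationCatalog:
    """Bin somatic SNVs into the 96-channel catalogue.

    The trinucleotide context comes from each record's ``tri_context`` field
    or, when absent, from ``context_source(chrom, pos)`` (e.g. a pyfaidx
    lookup).  Records that are not SNVs, or whose context contains an
    ambiguous base or does not match the reference base, are skipped and
    counted in the log.
    """
    counts = np.zeros(96, dtype=int)
    skipped = 0
    sid = sample_id
    for v in snvs:
        if sid is None:
            sid = v.sample_id
        if not v.is_snv:
            skipped += 1
            continue
        ctx = v.tri_context
        if ctx is None and context_source is not None:
            ctx = context_source(v.chrom, v.pos)
        if ctx is None or len(ctx) != 3 or any(b not in "ACGT" for b in ctx) or ctx[1] != v.ref:
            skipped += 1
            continue
        counts[_CHANNEL_INDEX[channel_of(v.ref, v.alt, ctx)]] += 1
    if skipped:
        log.info("build_catalog: skipped %d unusable record(s)", skipped)
    return MutationCatalog(sid or "", counts)


def _golden_min(f: Callable[[float], float], a: float, b: float, tol: float = 1e-4) -> tuple[float, float]:
    """Golden-section minimisation of f on [a, b]."""
    invphi = (np.sqrt(5) - 1) / 2
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    x = (a + b) / 2
    return x, f(x)


DEFAULT_MIN_SNVS = 15
DEFAULT_WEIGHT_CUTOFF = 0.06


def refit_exposures(
    catalog: MutationCatalog,
    signatures: SignatureMatrix,
    min_snvs: int = DEFAULT_MIN_SNVS,
    weight_cutoff: float = DEFAULT_WEIGHT_CUTOFF,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> ExposureVector:
    """Greedy forward refit of signature weights to one catalogue.

    Catalogues with fewer than ``min_snvs`` mutations yield an
    ``insufficient`` outcome with no weights, mirroring the practice of
    refitting only adequately mutated samples.
    """
    if catalog.total < min_snvs:
        return ExposureVector(catalog.sample_id, list(signatures.names), None,
                              float("nan"), insufficient=True)
    p = catalog.spectrum()
    S = signatures.profiles
    k = signatures.k
    w = np.zeros(k)

    def sse_of(weights: np.ndarray) -> float:
        r = S @ weights
        s = r.sum()
        if s > 0:
            r = r / s
        return float(((p - r) ** 2).sum())

    sse = sse_of(w)
    for _ in range(max_iter):
        best_k, best_x, best_sse = -1, 0.0, sse
        for j in range(k):
            e = np.zeros(k)
            e[j] = 1.0
            lo = -w[j]  # allow shrinking an existing weight back towards 0
            x, fx = _golden_min(lambda x: sse_of(w + x * e), lo, 1.0)
            if fx < best_sse:
                best_k, best_x, best_sse = j, x, fx
        if best_k < 0 or (sse - best_sse) < tol:
            break
        w[best_k] = max(0.0, w[best_k] + best_x)
        assert best_sse <= sse + 1e-12, "SSE increased during refit"
        sse = best_sse

    total = w.sum()
    if total > 0:
        w = w / total
    w[w < weight_cutoff] = 0.0
    return ExposureVector(catalog.sample_id, list(signatures.names), w, sse_of(w))


def group_mean_exposure(
    exposures: Sequence[ExposureVector],
    grouping: Mapping[str, str],
) -> pd.DataFrame:
    """Arithmetic mean weight per signature for each group of samples.

    Samples with insufficient SNVs are excluded; a group with no exposed
    sample raises.
    """
    rows = []
    for e in exposures:
        if e.insufficient or e.weights is None:
            continue
        if e.sample_id not in grouping:
            continue
        rows.append({"group": grouping[e.sample_id],
                     **dict(zip(e.names, e.weights))})
    if not rows:
        raise ValueError("no exposed samples in any group")
    df = pd.DataFrame(rows)
    present = set(df["group"])
    missing = set(grouping.values()) - present
    if missing:
        raise ValueError(f"group(s) with no exposed sample: {sorted(missing)}")
    return df.groupby("group").mean()


# ---------------------------------------------------------------------------
# signature matrix I/O
# ---------------------------------------------------------------------------


def read_signatures(path) -> SignatureMatrix:
    """Read a channel x signature TSV (first column = channel label)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(CHANNELS):
        raise ValueError("signature matrix rows must be the 96 canonical channels in order")
    return SignatureMatrix(list(df.columns), df.to_numpy())


def write_signatures(sigs: SignatureMatrix, path) -> None:
    pd.DataFrame(sigs.profiles, index=list(CHANNELS), columns=sigs.names).to_csv(
        path, sep="\t", index_label="channel", float_format="%.10f"
    )


def load_default_signatures() -> SignatureMatrix:
    """The packaged synthetic 13-signature stand-in matrix."""
    ref = resources.files("hrdscape.data") / "signatures_96x13_synthetic.tsv"
    with resources.as_file(ref) as path:
        return read_signatures(path)


def catalogs_to_frame(catalogs: Sequence[MutationCatalog]) -> pd.DataFrame:
    return pd.DataFrame(
        {c.sample_id: c.counts for c in catalogs}, index=list(CHANNELS)
    )


def exposures_to_frame(exposures: Sequence[ExposureVector]) -> pd.DataFrame:
    """Signatures x samples table; insufficient samples get NaN columns."""
    data = {}
    for e in exposures:
        if e.weights is None:
            data[e.sample_id] = np.full(len(e.names), np.nan)
        else:
            data[e.sample_id] = e.weights
    names = exposures[0].names if exposures else []
    return pd.DataFrame(data, index=names)
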