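"""HR-deficiency genomic scar scores from allele-specific copy number.

Three established scar scores are computed per sample from ASCN segments,
plus their sum (HRD-sum):

LOH score
    Number of maximal runs of minor copy number 0 longer than 15 Mb that do
    not span the entire chromosome.
TAI score (telomeric allelic imbalance)
    Number of allelic-imbalance runs (major != minor) at least 11 Mb long
    that reach a chromosome end, do not cross the centromere, and do not
    span the whole chromosome.
LST score (large-scale state transitions)
    Per chromosome arm, after removing segments shorter than 3 Mb and
    merging same-state neighbours, the number of copy-number breakpoints
    whose flanking segments are each at least 10 Mb long and separated by
    less than 3 Mb.

Conventions chosen here (the score definitions leave them open):

* LOH/TAI runs merge only strictly contiguous segments (gap of 0 bases);
  LST merging of identical states tolerates gaps below the smoothing length.
* A segment belongs to the arm containing its midpoint; segments straddling
  the centromere are split at its boundaries before arm processing.
* "Reaching a chromosome end" and "spanning the whole chromosome" are tested
  against the chromosome-map coordinates (position 1 and the chromosome
  length).
* Ploidy is not used: there is no near-tetraploid LST adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import ASCNSegment, ChromosomeMap

LOH_MIN_LEN = 15e6
TAI_MIN_LEN = 11e6
LST_SMOOTH_LEN = 3e6
LST_MIN_LEN = 10e6


@dataclass(frozen=True)
class ScarScores:
    sample_id: str
    loh_score: int
    tai_score: int
    lst_score: int

    @property
    def hrd_sum(self) -> int:
        return self.loh_score + self.tai_score + self.lst_score


def _by_chrom(segments: Sequence[ASCNSegment]) -> dict[str, list[ASCNSegment]]:
    out: dict[str, list[ASCNSegment]] = {}
    for s in segments:
        out.setdefault(s.chrom, []).append(s)
    for segs in out.values():
        segs.sort(key=lambda s: s.start)
    return out


def _contiguous_runs(segs: list[ASCNSegment], keep) -> list[tuple[int, int]]:
    """Maximal (start, end) runs of consecutive kept segments with zero gap."""
    runs: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = None
    prev_end = None
    for s in segs:
        if keep(s):
            if cur is not None and s.start == prev_end + 1:
                cur = (cur[0], s.end)
            else:
                if cur is not None:
                    runs.append(cur)
                cur = (s.start, s.end)
            prev_end = s.end
        else:
            if cur is not None:
                runs.append(cur)
                cur = None
            prev_end = None
    if cur is not None:
        runs.append(cur)
    return runs


def score_loh(segments: Sequence[ASCNSegment], chrom_map: ChromosomeMap,
              min_len: float = LOH_MIN_LEN) -> int:
    count = 0
    for chrom, segs in _by_chrom(segments).items():
        if chrom not in chrom_map:
            raise ValueError(f"chromosome {chrom} absent from chromosome map")
        length = chrom_map.length(chrom)
        for start, end in _contiguous_runs(segs, lambda s: s.cn_minor == 0):
            span = end - start + 1
            whole = start <= 1 and end >= length
            if span > min_len and not whole:
                count += 1
    return count


def score_tai(segments: Sequence[ASCNSegment], chrom_map: ChromosomeMap,
              min_len: float = TAI_MIN_LEN) -> int:
    count = 0
    for chrom, segs in _by_chrom(segments).items():
        if chrom not in chrom_map:
            raise ValueError(f"chromosome {chrom} absent from chromosome map")
        length = chrom_map.length(chrom)
        cen_start, cen_end = chrom_map.centromere(chrom)
        for start, end in _contiguous_runs(segs, lambda s: s.cn_major != s.cn_minor):
            span = end - start + 1
            reaches_end = start <= 1 or end >= length
            crosses_cen = start < cen_start and end > cen_end
            whole = start <= 1 and end >= length
            if reaches_end and not crosses_cen and not whole and span >= min_len:
                count += 1
    return count


def _split_arms(segs: list[ASCNSegment], cen_start: int, cen_end: int,
                length: int) -> tuple[list[tuple[int, int, int, int]], list[tuple[int, int, int, int]]]:
    """Split segments at the centromere; return (p-arm, q-arm) tuples
    (start, end, cn_major, cn_minor).  Pieces wholly inside the centromere
    are dropped."""
    p_arm: list[tuple[int, int, int, int]] = []
    q_arm: list[tuple[int, int, int, int]] = []
    for s in segs:
        if s.start < cen_start:
            p_arm.append((s.start, min(s.end, cen_start - 1), s.cn_major, s.cn_minor))
        if s.end > cen_end:
            q_arm.append((max(s.start, cen_end + 1), min(s.end, length), s.cn_major, s.cn_minor))
    return p_arm, q_arm


def score_lst(segments: Sequence[ASCNSegment], chrom_map: ChromosomeMap,
              smooth_len: float = LST_SMOOTH_LEN, min_len: float = LST_MIN_LEN) -> int:
    count = 0
    for chrom, segs in _by_chrom(segments).items():
        if chrom not in chrom_map:
            raise ValueError(f"chromosome {chrom} absent from chromosome map")
        length = chrom_map.length(chrom)
        cen_start, cen_end = chrom_map.centromere(chrom)
        for arm in _split_arms(segs, cen_start, cen_end, length):
            # smoothing: drop short segments, then merge same-state neighbours
            kept = [t for t in arm if (t[1] - t[0] + 1) >= smooth_len]
            merged: list[list[int]] = []
            for start, end, a, b in kept:
                if merged and (a, b) == (merged[-1][2], merged[-1][3]) \
                        and (start - merged[-1][1] - 1) < smooth_len:
                    merged[-1][1] = end
                else:
                    merged.append([start, end, a, b])
            for left, right in zip(merged, merged[1:]):
                gap = right[0] - left[1] - 1
                left_span = left[1] - left[0] + 1
                right_span = right[1] - right[0] + 1
                if gap < smooth_len and left_span >= min_len and right_span >= min_len:
                    count += 1
    return count


def score_sample(segments: Sequence[ASCNSegment], chrom_map: ChromosomeMap,
                 sample_id: str | None = None) -> ScarScores:
    """All three scar scores plus HRD-sum for one sample's segments."""
    sid = sample_id
    if sid is None:
        sid = segments[0].sample_id if segments else ""
    return ScarScores(
        sample_id=sid,
        loh_score=score_loh(segments, chrom_map),
        tai_score=score_tai(segments, chrom_map),
        lst_score=score_lst(segments, chrom_map),
    )
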