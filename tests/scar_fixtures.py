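"""Hand-constructed ASCN segment fixtures with hand-counted scar scores.

Each fixture is (name, segments, expected (loh, tai, lst)) on the toy
genome of conftest's ``test_chrom_map``: chromosome T1 is 100 Mb with
centromere [45, 55] Mb; T2 is 200 Mb with centromere [90, 100] Mb.
Expected counts were tallied by hand from the score definitions.
"""

from hrdscape.io import ASCNSegment

M = 1_000_000


def s(chrom, start, end, a, b):
    return ASCNSegment("FX", chrom, int(start), int(end), a, b)


FIXTURES = [
    # ---- LOH score ----
    ("loh_20mb_interior", [s("T1", 20 * M, 40 * M, 2, 0)], (1, 0, 0)),
    ("loh_whole_chromosome_excluded", [s("T1", 1, 100 * M, 2, 0)], (0, 0, 0)),
    ("loh_adjacent_10mb_pair_merges", [
        s("T1", 1 * M, 11 * M - 1, 2, 0), s("T1", 11 * M, 21 * M - 1, 2, 0)],
     (1, 0, 0)),
    ("loh_10mb_too_short", [s("T1", 20 * M, 30 * M - 1, 2, 0)], (0, 0, 0)),
    ("loh_exactly_15mb_not_longer", [s("T1", 20 * M, 35 * M - 1, 2, 0)], (0, 0, 0)),
    ("loh_two_separate_runs", [
        s("T1", 1 * M, 17 * M, 2, 0), s("T1", 60 * M, 76 * M + M // 2, 1, 0)],
     (2, 0, 0)),
    ("loh_gap_breaks_merging", [
        s("T1", 10 * M, 19 * M, 2, 0), s("T1", 25 * M, 34 * M, 2, 0)],
     (0, 0, 0)),  # two 9-10 Mb runs, neither > 15 Mb after the gap
    # ---- TAI score ----
    ("tai_p_telomere_15mb", [s("T1", 1, 15 * M, 2, 1)], (0, 1, 0)),
    ("tai_interior_run_not_counted", [s("T1", 20 * M, 35 * M, 2, 1)], (0, 0, 0)),
    ("tai_q_telomere", [s("T1", 85 * M + 1, 100 * M, 3, 1)], (0, 1, 0)),
    ("tai_crossing_centromere_excluded", [s("T1", 40 * M, 100 * M, 2, 1)], (0, 0, 0)),
    ("tai_10mb_below_min_len", [s("T1", 1, 10 * M - 1, 2, 1)], (0, 0, 0)),
    ("tai_balanced_telomeric_not_imbalanced", [s("T1", 1, 15 * M, 2, 2)], (0, 0, 0)),
    ("tai_both_telomeres", [
        s("T1", 1, 12 * M, 2, 1), s("T1", 88 * M + 1, 100 * M, 2, 1)],
     (0, 2, 0)),
    ("tai_adjacent_states_merge_to_telomere", [
        s("T1", 1, 6 * M, 2, 1), s("T1", 6 * M + 1, 14 * M, 3, 1)],
     (0, 1, 0)),
    # ---- LST score ----
    ("lst_one_qualifying_breakpoint", [
        s("T1", 1, 20 * M, 1, 1), s("T1", 20 * M + 1, 40 * M, 2, 1)],
     (0, 0, 1)),
    ("lst_small_gap_still_counts", [
        s("T1", 1, 20 * M, 1, 1), s("T1", 22 * M, 42 * M, 2, 1)],
     (0, 0, 1)),
    ("lst_gap_at_least_3mb_breaks", [
        s("T1", 1, 20 * M, 1, 1), s("T1", 25 * M, 44 * M, 2, 1)],
     (0, 0, 0)),
    ("lst_short_segment_smoothed_away", [
        s("T1", 1, 20 * M, 1, 1), s("T1", 20 * M + 1, 22 * M, 3, 0),
        s("T1", 22 * M + 1, 42 * M, 1, 1)],
     (0, 0, 0)),  # flanks merge to one state after smoothing
    ("lst_middle_flank_below_10mb", [
        s("T1", 1, 20 * M, 1, 1), s("T1", 20 * M + 1, 28 * M, 2, 1),
        s("T1", 28 * M + 1, 44 * M, 2, 2)],
     (0, 0, 0)),
    ("lst_q_arm_breakpoint", [
        s("T1", 56 * M, 70 * M, 1, 1), s("T1", 70 * M + 1, 85 * M, 2, 2)],
     (0, 0, 1)),
    ("lst_segment_split_at_centromere", [
        s("T1", 30 * M, 70 * M, 2, 2), s("T1", 70 * M + 1, 85 * M, 1, 1)],
     (0, 0, 1)),  # only the q-arm (2,2)|(1,1) boundary qualifies
    # ---- interactions ----
    ("loh_reaching_telomere_also_tai", [s("T1", 1, 16 * M + M // 2, 2, 0)],
     (1, 1, 0)),
    ("multi_chromosome_sum", [
        s("T1", 20 * M, 40 * M, 2, 0),                      # LOH on T1
        s("T2", 1, 15 * M, 2, 1),                           # TAI on T2 p-end
        s("T2", 110 * M, 125 * M, 1, 1),
        s("T2", 125 * M + 1, 140 * M, 2, 2)],               # LST on T2 q-arm
     (1, 1, 1)),
]
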