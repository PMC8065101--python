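"""Catalogue construction and signature-refit behaviour."""

import itertools

import numpy as np
import pytest

from hrdscape.io import VariantRecord
from hrdscape.signatures import (
    CHANNELS, ExposureVector, MutationCatalog, SignatureMatrix, build_catalog,
    channel_of, exposures_to_frame, group_mean_exposure, refit_exposures,
    revcomp,
)


def snv(ref, alt, ctx, sample="S1", pos=1000):
    return VariantRecord(sample, "1", pos, ref, alt, "OTHER", "other",
                         "somatic", tri_context=ctx)


def grid_oracle_sse(spectrum, profiles, step=0.01):
    """Brute-force minimum SSE over the weight simplex at `step` resolution."""
    k = profiles.shape[1]
    best = np.inf
    ticks = np.arange(0, 1 + step / 2, step)
    for combo in itertools.product(ticks, repeat=k - 1):
        last = 1.0 - sum(combo)
        if last < -1e-9:
            continue
        w = np.array(list(combo) + [max(last, 0.0)])
        r = profiles @ w
        r = r / r.sum()
        sse = ((spectrum - r) ** 2).sum()
        if sse < best:
            best = sse
    return best


class TestCatalog:
    def test_purine_reference_folded_to_pyrimidine_strand(self):
        # A>G in context TAG is the reverse complement of T>C in CTA
        assert channel_of("A", "G", "TAG") == "C[T>C]A"
        assert channel_of("C", "T", "ACA") == "A[C>T]A"

    def test_double_revcomp_is_identity(self):
        for label in CHANNELS[:10]:
            f5, ref, alt, f3 = label[0], label[2], label[4], label[6]
            ctx = f5 + ref + f3
            ctx2 = revcomp(revcomp(ctx))
            assert channel_of(ref, alt, ctx) == channel_of(ref, alt, ctx2)

    def test_counts_sum_to_usable_snvs(self):
        cat = build_catalog([snv("C", "T", "ACA"), snv("C", "T", "ACA"),
                             snv("C", "T", "ACA")])
        assert cat.total == 3
        assert cat.counts[CHANNELS.index("A[C>T]A")] == 3
        assert (cat.counts > 0).sum() == 1

    def test_bad_context_or_indel_skipped(self):
        records = [
            snv("C", "T", "ACA"),
            snv("C", "T", "ANA"),            # ambiguous base
            snv("C", "T", "AGA"),            # middle base mismatch
            VariantRecord("S1", "1", 5, "CT", "C", "OTHER", "other", "somatic"),
        ]
        assert build_catalog(records).total == 1

    def test_context_source_lookup_used_when_field_absent(self):
        rec = VariantRecord("S1", "1", 10, "C", "G", "OTHER", "other", "somatic")
        cat = build_catalog([rec], context_source=lambda chrom, pos: "GCT")
        assert cat.counts[CHANNELS.index("G[C>G]T")] == 1


class TestRefit:
    def test_single_signature_catalogue_recovers_weight_one(self, signatures):
        rng = np.random.default_rng(3)
        for name in ("Signature 1", "Signature 3", "Signature 17"):
            counts = rng.multinomial(
                5000, signatures.profiles[:, signatures.names.index(name)])
            exp = refit_exposures(MutationCatalog("t", counts), signatures)
            assert exp.weight_of(name) == pytest.approx(1.0, abs=0.02)
            others = [w for n, w in zip(exp.names, exp.weights) if n != name]
            assert all(w == 0 for w in others)

    def test_below_min_snvs_is_insufficient(self, signatures):
        counts = np.zeros(96, dtype=int)
        counts[0] = 10
        exp = refit_exposures(MutationCatalog("t", counts), signatures)
        assert exp.insufficient and exp.weights is None

    def test_two_signature_mixture_recovery(self, signatures):
        i, j = signatures.names.index("Signature 1"), signatures.names.index("Signature 13")
        mix = 0.6 * signatures.profiles[:, i] + 0.4 * signatures.profiles[:, j]
        counts = np.random.default_rng(5).multinomial(5000, mix)
        exp = refit_exposures(MutationCatalog("t", counts), signatures)
        assert exp.weights[i] == pytest.approx(0.6, abs=0.05)
        assert exp.weights[j] == pytest.approx(0.4, abs=0.05)

    def test_refit_sse_matches_grid_oracle_k3(self, signatures):
        sub = signatures.subset(["Signature 1", "Signature 2", "Signature 13"])
        rng = np.random.default_rng(9)
        for _ in range(3):
            w_true = rng.dirichlet([1, 1, 1])
            counts = rng.multinomial(3000, sub.profiles @ w_true)
            cat = MutationCatalog("t", counts)
            exp = refit_exposures(cat, sub, weight_cutoff=0.0)
            oracle = grid_oracle_sse(cat.spectrum(), sub.profiles)
            assert exp.residual_sse == pytest.approx(oracle, abs=1e-3)

    def test_weights_below_cutoff_zeroed_without_renormalising(self, signatures):
        i = signatures.names.index("Signature 1")
        j = signatures.names.index("Signature 13")
        mix = 0.97 * signatures.profiles[:, i] + 0.03 * signatures.profiles[:, j]
        counts = np.random.default_rng(0).multinomial(20000, mix)
        exp = refit_exposures(MutationCatalog("t", counts), signatures)
        assert exp.weights[j] == 0.0            # 0.03 < cutoff 0.06
        assert exp.weights.sum() <= 1 + 1e-6    # no renormalisation upward

    def test_deterministic_for_fixed_input(self, signatures):
        counts = np.random.default_rng(2).multinomial(
            2000, signatures.profiles[:, 0])
        cat = MutationCatalog("t", counts)
        a = refit_exposures(cat, signatures)
        b = refit_exposures(cat, signatures)
        assert np.array_equal(a.weights, b.weights)
        assert a.residual_sse == b.residual_sse

    def test_invalid_signature_matrix_rejected(self):
        bad = np.full((96, 2), 1.0 / 96)
        bad[0, 1] += 0.5
        with pytest.raises(ValueError, match="sum to 1"):
            SignatureMatrix(["A", "B"], bad)


class TestGroupMeans:
    @staticmethod
    def _exposure(sid, w3):
        return ExposureVector(sid, ["Signature 3", "Signature 1"],
                              np.array([w3, 1 - w3]), 0.0)

    def test_mean_of_two_samples(self):
        exps = [self._exposure("A", 0.4), self._exposure("B", 0.6)]
        means = group_mean_exposure(exps, {"A": "g1", "B": "g1"})
        assert means.loc["g1", "Signature 3"] == pytest.approx(0.5)

    def test_single_sample_group_equals_itself(self):
        exps = [self._exposure("A", 0.3)]
        means = group_mean_exposure(exps, {"A": "solo"})
        assert means.loc["solo", "Signature 3"] == pytest.approx(0.3)

    def test_group_with_no_exposed_sample_raises(self):
        insufficient = ExposureVector("A", ["Signature 3"], None, float("nan"),
                                      insufficient=True)
        with pytest.raises(ValueError, match="no exposed"):
            group_mean_exposure([insufficient], {"A": "g1"})

    def test_exposures_frame_has_nan_for_insufficient(self):
        exps = [self._exposure("A", 0.2),
                ExposureVector("B", ["Signature 3", "Signature 1"], None,
                               float("nan"), insufficient=True)]
        frame = exposures_to_frame(exps)
        assert np.isnan(frame["B"]).all()
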