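"""Feature encoding: one-hot sequence encoding and bi-profile Bayesian profiles."""

from collections import Counter

import numpy as np
import pytest

from cleavesite.encoding import (
    CHANNEL_ALPHABETS,
    BiProfile,
    EncodingError,
    EncodingScheme,
    descriptor_group,
    encode,
    encode_beaa,
    encode_bpb,
    encode_windows,
    fit_biprofile,
    fit_profiles,
)
from cleavesite.substrates import AA_ALPHABET, SiteWindow


def window(residues, span=None, label="cleaved", **channels):
    span = span or (len(residues) // 2, len(residues) - len(residues) // 2)
    return SiteWindow("s", span[0], span, residues, label, **channels)


class TestBEAA:
    def test_one_hot_count_and_length(self):
        fv = encode_beaa(window("DEVDGA", span=(4, 2)))
        assert len(fv.values) == 120
        assert fv.values.sum() == 6

    def test_padding_encodes_to_zeros(self):
        fv = encode_beaa(window("--VDGA", span=(4, 2)))
        assert fv.values.sum() == 4

    def test_orthonormality_between_positions(self):
        fv = encode_beaa(window("DDEA", span=(2, 2)))
        blocks = fv.values.reshape(4, 20)
        dots = blocks @ blocks.T
        # dot product 1 iff same residue, 0 otherwise
        assert dots[0, 1] == 1.0 and dots[0, 2] == 0.0 and dots[2, 3] == 0.0

    def test_descriptors_unique_and_labelled(self):
        fv = encode_beaa(window("DEVDGA", span=(4, 2)))
        assert len(set(fv.descriptors)) == 120
        assert "BEAA:P1:D" in fv.descriptors


class TestBiProfileFit:
    def test_hand_count_oracle_without_pseudocount(self):
        pos = [window("DD", span=(1, 1)), window("DE", span=(1, 1))]
        neg = [window("AA", span=(1, 1), label="non-cleaved")] * 2
        prof = fit_biprofile(pos, neg, "AA", pseudocount=0.0)
        d = AA_ALPHABET.index("D")
        e = AA_ALPHABET.index("E")
        a = AA_ALPHABET.index("A")
        assert prof.pos_freq[0, d] == 1.0
        assert prof.pos_freq[1, d] == 0.5 and prof.pos_freq[1, e] == 0.5
        assert prof.neg_freq[0, a] == 1.0

    def test_laplace_closed_form(self):
        pos = [window("DD", span=(1, 1)), window("DE", span=(1, 1))]
        neg = [window("AA", span=(1, 1), label="non-cleaved")] * 2
        prof = fit_biprofile(pos, neg, "AA", pseudocount=1.0)
        assert prof.pos_freq[0, AA_ALPHABET.index("D")] == pytest.approx((2 + 1) / (2 + 20))

    def test_all_entries_positive_with_pseudocount(self):
        pos = [window("DD", span=(1, 1))]
        neg = [window("AA", span=(1, 1), label="non-cleaved")]
        prof = fit_biprofile(pos, neg, "AA", pseudocount=1.0)
        assert (prof.pos_freq > 0).all() and (prof.neg_freq > 0).all()

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        mk = lambda lab: window(
            "".join(rng.choice(list(AA_ALPHABET), size=6)), span=(4, 2), label=lab
        )
        prof = fit_biprofile([mk("cleaved") for _ in range(7)],
                             [mk("non-cleaved") for _ in range(9)], "AA")
        assert np.allclose(prof.pos_freq.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(prof.neg_freq.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("n_pos,n_neg,seed", [(3, 5, 1), (20, 50, 2), (17, 33, 3)])
    def test_matches_bruteforce_counting(self, n_pos, n_neg, seed):
        """Fitted tables equal an independent symbol-counting oracle exactly."""
        rng = np.random.default_rng(seed)
        span, pc = (2, 2), 1.0
        mk = lambda lab: window(
            "".join(rng.choice(list(AA_ALPHABET), size=4)), span=span, label=lab
        )
        pos = [mk("cleaved") for _ in range(n_pos)]
        neg = [mk("non-cleaved") for _ in range(n_neg)]
        prof = fit_biprofile(pos, neg, "AA", pseudocount=pc)
        for i in range(4):
            pos_counts = Counter(w.residues[i] for w in pos)
            neg_counts = Counter(w.residues[i] for w in neg)
            for j, sym in enumerate(AA_ALPHABET):
                assert prof.pos_freq[i, j] == pytest.approx(
                    (pos_counts[sym] + pc) / (n_pos + pc * 20), abs=0
                )
                assert prof.neg_freq[i, j] == pytest.approx(
                    (neg_counts[sym] + pc) / (n_neg + pc * 20), abs=0
                )

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        mk = lambda lab: window(
            "".join(rng.choice(list(AA_ALPHABET), size=4)), span=(2, 2), label=lab
        )
        pos = [mk("cleaved") for _ in range(10)]
        neg = [mk("non-cleaved") for _ in range(10)]
        a = fit_biprofile(pos, neg, "AA")
        b = fit_biprofile(pos[::-1], neg[::-1], "AA")
        assert np.array_equal(a.pos_freq, b.pos_freq)

    def test_span_mismatch_and_missing_channel_rejected(self):
        pos = [window("DD", span=(1, 1))]
        with pytest.raises(EncodingError, match="span"):
            fit_biprofile(pos, [window("AAA", span=(2, 1), label="non-cleaved")], "AA")
        with pytest.raises(EncodingError, match="SS"):
            fit_biprofile(pos, [window("AA", span=(1, 1), label="non-cleaved")], "SS")


class TestBPBEncoding:
    def _toy_profile(self):
        pos = [window("DD", span=(1, 1)), window("DE", span=(1, 1))]
        neg = [window("AA", span=(1, 1), label="non-cleaved")] * 2
        return fit_biprofile(pos, neg, "AA", pseudocount=0.0)

    def test_hand_computed_vector(self):
        prof = self._toy_profile()
        fv = encode_bpb(window("DE", span=(1, 1)), prof)
        assert fv.values.tolist() == [1.0, 0.5, 0.0, 0.0]

    def test_degenerate_profile_gives_ones_then_zeros(self):
        pos = [window("DD", span=(1, 1))] * 2
        neg = [window("AA", span=(1, 1), label="non-cleaved")] * 2
        prof = fit_biprofile(pos, neg, "AA", pseudocount=0.0)
        fv = encode_bpb(window("DD", span=(1, 1)), prof)
        assert fv.values[:2].tolist() == [1.0, 1.0]
        assert fv.values[2:].tolist() == [0.0, 0.0]

    def test_gap_symbol_uses_configured_pseudofrequencies(self):
        pos = [window("DD", span=(1, 1))] * 2
        neg = [window("AA", span=(1, 1), label="non-cleaved")] * 3
        prof = fit_biprofile(pos, neg, "AA", pseudocount=1.0)
        fv = encode_bpb(window("-D", span=(1, 1)), prof)
        assert fv.values[0] == pytest.approx(1 / (2 + 20))
        assert fv.values[2] == pytest.approx(1 / (3 + 20))

    def test_structural_channel_encoding(self):
        pos = [window("DD", span=(1, 1), ss="CC")]
        neg = [window("AA", span=(1, 1), label="non-cleaved", ss="HH")]
        prof = fit_biprofile(pos, neg, "SS", pseudocount=0.0)
        fv = encode_bpb(window("XX", span=(1, 1), ss="CH"), prof)
        assert fv.values.tolist() == [1.0, 0.0, 0.0, 1.0]


class TestSchemes:
    @pytest.mark.parametrize(
        "name,span,expected",
        [
            ("ALL", (8, 8), 448),   # 28 * 16
            ("ALL", (4, 2), 168),   # 28 * 6
            ("BEAA", (4, 2), 120),  # 20 * 6
            ("BEAA+BPBSS", (4, 2), 132),
        ],
    )
    def test_vector_lengths(self, name, span, expected):
        assert EncodingScheme.from_name(name, span).vector_length == expected

    def test_unknown_block_rejected(self):
        with pytest.raises(EncodingError):
            EncodingScheme.from_name("BEAA+NOPE", (4, 2))

    def test_missing_profile_names_the_block(self):
        w = window("DEVDGA", span=(4, 2), ss="CCCCCC", sa="eeeeee", diso="******")
        scheme = EncodingScheme.from_name("ALL", (4, 2))
        with pytest.raises(EncodingError, match="BPBAA"):
            encode(w, scheme, profiles={})

    def test_full_scheme_concatenation(self, caspase_windows):
        scheme = EncodingScheme.from_name("ALL", (4, 2))
        profiles = fit_profiles(caspase_windows, scheme)
        X, descriptors = encode_windows(caspase_windows[:10], scheme, profiles)
        assert X.shape == (10, 168)
        assert len(descriptors) == 168 and len(set(descriptors)) == 168

    def test_twenty_descriptor_groups_for_extended_window(self):
        scheme = EncodingScheme.from_name("ALL", (8, 8))
        mk = lambda res, lab, st: window(res, span=(8, 8), label=lab,
                                         ss="C" * 16, sa="e" * 16, diso=st)
        ws = [mk("D" * 16, "cleaved", "*" * 16), mk("A" * 16, "non-cleaved", "." * 16)]
        profiles = fit_profiles(ws, scheme)
        _, descriptors = encode_windows(ws, scheme, profiles)
        groups = {descriptor_group(d) for d in descriptors}
        assert len(groups) == 20  # 16 per-position BEAA groups + 4 BPB groups

    def test_tsv_round_trip(self, tmp_path):
        pos = [window("DD", span=(1, 1)), window("DE", span=(1, 1))]
        neg = [window("AA", span=(1, 1), label="non-cleaved")] * 2
        prof = fit_biprofile(pos, neg, "AA")
        prof.to_tsv(tmp_path / "p.tsv")
        back = BiProfile.from_tsv(tmp_path / "p.tsv", (1, 1))
        assert np.allclose(back.pos_freq, prof.pos_freq)
        assert np.allclose(back.neg_freq, prof.neg_freq)
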