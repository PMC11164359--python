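"""RSCU, ENC, CBI, positional GC, ENC null curve, correlations."""

import numpy as np
import pytest

from mitocomp import (
    cbi,
    correlation,
    count_codons,
    enc,
    enc_null_curve,
    get_code,
    positional_gc,
    rscu,
)
from mitocomp.codon_usage import CodonCounts


class TestCountCodons:
    def test_stop_excluded_by_default(self, code):
        counts = count_codons(["ATGAAATAA"], code)
        assert counts.counts == {"ATG": 1, "AAA": 1}
        assert counts.total == 2

    def test_ambiguous_codon_excluded(self, code):
        counts = count_codons(["ATGNAAAAA"], code)
        assert counts.total == 2
        assert "NAA" not in counts.counts

    def test_trailing_partial_codon_dropped(self, code):
        counts = count_codons(["ATGAAAT"], code)
        assert counts.total == 2

    def test_short_cds_skipped_with_warning(self, code):
        with pytest.warns(UserWarning):
            counts = count_codons(["AT", "ATGAAA"], code)
        assert counts.total == 2


class TestRSCU:
    def test_uniform_family(self, code):
        r = rscu(CodonCounts({"TTT": 5, "TTC": 5}, code.code_id))
        assert r["TTT"] == r["TTC"] == 1.0

    def test_extreme_family(self, code):
        r = rscu(CodonCounts({"TTT": 10, "TTC": 0}, code.code_id))
        assert (r["TTT"], r["TTC"]) == (2.0, 0.0)

    def test_fourfold_hand_arithmetic(self, code):
        r = rscu(CodonCounts(
            {"GTA": 4, "GTT": 2, "GTG": 1, "GTC": 1}, code.code_id))
        assert r["GTA"] == pytest.approx(2.0)

    def test_unused_family_reported_missing(self, code):
        r = rscu(CodonCounts({"TTT": 3}, code.code_id))
        assert r["GGA"] is None

    def test_family_sums_equal_family_size(self, code, genome):
        from mitocomp.pipeline import pcg_sequences

        counts = count_codons(list(pcg_sequences(genome).values()), code)
        r = rscu(counts)
        for aa, fam in code.families.items():
            total = sum(counts[c] for c in fam)
            if total:
                assert sum(r[c] for c in fam) == pytest.approx(len(fam))


class TestENC:
    def test_invertebrate_mito_degeneracy_classes(self, code):
        classes = {k: len(v) for k, v in code.degeneracy_classes().items()}
        assert classes == {2: 12, 4: 6, 6: 1, 8: 1}

    def test_maximal_bias_is_20(self, code):
        counts = {fam[0]: 10 for fam in code.families.values()}
        assert enc(CodonCounts(counts, code.code_id)) == 20.0

    def test_uniform_limit_is_62(self, code):
        counts = {c: 10**5 for c in code.sense_codons}
        assert enc(CodonCounts(counts, code.code_id)) == pytest.approx(
            62.0, abs=0.5)

    def test_closed_form_class_means(self, code):
        """F-bar of exactly 1/2, 1/4, 1/6, 1/8 per class gives ENC = 62.

        Built from uniform within-family usage at large n, where
        F-hat -> 1/k for every family."""
        counts = {}
        for fam in code.families.values():
            for c in fam:
                counts[c] = 120000 // len(fam)
        val = enc(CodonCounts(counts, code.code_id))
        assert val == pytest.approx(12 / 0.5 + 6 / 0.25 + 6 + 8, abs=0.05)

    def test_insufficient_codons_error(self, code):
        with pytest.raises(ValueError, match="insufficient"):
            enc(CodonCounts({"TTT": 1, "GGA": 1}, code.code_id))

    def test_monotone_decrease_along_bias_sweep(self, code):
        n_fam = 6000
        values = []
        for lam in np.linspace(0.0, 1.0, 11):
            counts = {}
            for fam in code.families.values():
                k = len(fam)
                pref = round(n_fam * (1 / k + lam * (1 - 1 / k)))
                rest = (n_fam - pref) // (k - 1) if k > 1 else 0
                counts[fam[0]] = pref
                for c in fam[1:]:
                    counts[c] = rest
            values.append(enc(CodonCounts(counts, code.code_id)))
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))
        assert values[0] > 55 and values[-1] == pytest.approx(20.0, abs=0.1)


class TestCBI:
    def test_all_preferred_is_one(self, code):
        counts = CodonCounts({"TTT": 5, "AAA": 7}, code.code_id)
        assert cbi(counts) == pytest.approx(1.0)

    def test_uniform_usage_with_a_priori_preferred_is_zero(self, code):
        counts = {c: 4 for c in code.sense_codons}
        preferred = {aa: fam[0] for aa, fam in code.families.items()}
        assert cbi(CodonCounts(counts, code.code_id),
                   preferred=preferred) == pytest.approx(0.0)

    def test_hand_arithmetic_example(self, code):
        counts = CodonCounts(
            {"TTT": 3, "TTC": 1, "AAA": 4, "AAG": 0}, code.code_id)
        assert cbi(counts) == pytest.approx(0.75)


class TestPositionalGC:
    def test_single_codon(self, code):
        pos = positional_gc(["ATGCCC"], code)
        assert pos["gc3"] == pytest.approx(100.0)
        assert pos["gc1"] == pytest.approx(50.0)

    def test_gcg_only(self, code):
        pos = positional_gc(["GCGGCG"], code)
        assert pos["gc1"] == pos["gc2"] == pos["gc3"] == 100.0
        assert pos["at3"] == 0.0

    def test_gc12_is_mean(self, code, genome):
        from mitocomp.pipeline import pcg_sequences

        pos = positional_gc(list(pcg_sequences(genome).values()), code)
        assert pos["gc12"] == pytest.approx((pos["gc1"] + pos["gc2"]) / 2)

    def test_third_position_most_at_rich(self, code, genome):
        from mitocomp.pipeline import pcg_sequences

        pos = positional_gc(list(pcg_sequences(genome).values()), code)
        assert pos["at3"] > pos["at1"] and pos["at3"] > pos["at2"]


class TestENCNullCurve:
    def test_closed_form_at_half(self):
        assert enc_null_curve(0.5) == pytest.approx(60.5)

    def test_symmetry_of_quadratic_term(self):
        assert enc_null_curve(0.3) - 0.3 == pytest.approx(
            enc_null_curve(0.7) - 0.7)

    @pytest.mark.parametrize("s", [0.0, 1.0, -0.2, 1.3])
    def test_domain_error(self, s):
        with pytest.raises(ValueError):
            enc_null_curve(s)


class TestNeutralityAndCorrelation:
    def test_perfect_linear(self):
        x = np.arange(1.0, 6.0)
        _, r2, _ = correlation(x, 2 * x)
        assert r2 == pytest.approx(1.0)

    def test_orthogonal_by_construction(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])  # zero covariance with x
        _, r2, _ = correlation(x, y)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # cov = 4.5, var_x = 5, var_y = 4.75 -> r^2 = 20.25/23.75
        _, r2, _ = correlation([1, 2, 3, 4], [1, 2, 2, 4])
        assert r2 == pytest.approx(20.25 / 23.75, abs=1e-12)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            correlation([1, 1, 1], [1, 2, 3])

    def test_neutrality_slopes(self, code):
        """GC12-on-GC3 regression slope is ~1 under shared mutation pressure
        and ~0 when only position 3 varies."""
        rng = np.random.default_rng(0)
        codons = [c for c in code.sense_codons]

        def gene(gc, third_only):
            p = np.array([
                ((0.5 if third_only else gc) if b in "GC" else
                 (0.5 if third_only else 1 - gc)) / 2
                for b in "ACGT"
            ])
            # draw positions independently; for third_only the first two
            # positions keep a fixed composition
            out = []
            for _ in range(1500):
                b12 = rng.choice(list("ACGT"), size=2,
                                 p=p / p.sum()) if not third_only else \
                    rng.choice(list("ACGT"), size=2)
                p3 = np.array([gc / 2 if b in "GC" else (1 - gc) / 2
                               for b in "ACGT"])
                b3 = rng.choice(list("ACGT"), p=p3 / p3.sum())
                out.append("".join(b12) + b3)
            return "".join(out)

        gcs = np.linspace(0.2, 0.8, 9)
        for third_only, expected in ((False, 1.0), (True, 0.0)):
            pts = []
            for gc in gcs:
                pos = positional_gc([gene(gc, third_only)], code)
                pts.append((pos["gc3"], pos["gc12"]))
            x, y = np.array(pts).T
            slope = np.polyfit(x, y, 1)[0]
            assert slope == pytest.approx(expected, abs=0.15)
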