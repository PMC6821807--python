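"""Read assignment, top-frag-end removal, normalization, running mean."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fourc.fragends import FragEnd, _reverse_complement
from fourc.profiles import (
    CoverageProfile,
    ProfileStateError,
    Viewpoint,
    assign_reads,
    normalize,
    remove_top_fragend,
    running_mean,
)

PRIMER = "GTCCCAAGGGCACACTGATC"


def make_library(seqs, chrom="chrV", spacing=500, start=1000):
    lib = []
    for i, seq in enumerate(seqs):
        lib.append(
            FragEnd(chrom=chrom, pos=start + i * spacing, side="left_of_fragment",
                    sequence=seq, fragment_index=i)
        )
    return lib


@pytest.fixture()
def vp():
    return Viewpoint(name="vp", chrom="chrV", position=2000, reading_primer=PRIMER)


@pytest.fixture()
def library():
    seqs = ["AACCGGTTAACCGGTTAACC", "TTGGCCAATTGGCCAATTGG",
            "ACACACACACACACACACAC", "GTGTGAGAGTGTGAGAGTGT"]
    lib = make_library(seqs)
    lib.append(FragEnd(chrom="chrT", pos=500, side="left_of_fragment",
                       sequence="CCCCAAAATTTTGGGGCCCC", fragment_index=0))
    return lib


class TestAssignReads:
    def test_exact_match_increments_count(self, vp, library):
        reads = [PRIMER + library[0].sequence]
        profile = assign_reads(reads, vp, library)
        assert profile.counts[0] == 1
        assert profile.total_reads == 1

    def test_reverse_complement_matches(self, vp, library):
        reads = [PRIMER + _reverse_complement(library[2].sequence)]
        profile = assign_reads(reads, vp, library)
        assert profile.counts[2] == 1

    def test_read_without_primer_discarded(self, vp, library):
        profile = assign_reads(["TTTT" + library[0].sequence], vp, library)
        assert profile.total_reads == 0
        assert profile.discarded["no_primer"] == 1

    def test_read_matching_nothing_discarded(self, vp, library):
        profile = assign_reads([PRIMER + "T" * 20], vp, library)
        assert profile.discarded["no_match"] == 1

    def test_read_matching_non_unique_fragend_discarded(self, vp):
        dup = "AAGGAAGGAAGGAAGGAAGG"
        lib = make_library([dup, dup, "AAACCCTTTGGGAAACCCTT"])
        from fourc.fragends import mark_unique

        lib = mark_unique(lib)
        profile = assign_reads([PRIMER + dup], vp, lib)
        assert profile.total_reads == 0
        assert profile.discarded["non_unique"] == 1

    def test_conservation_assigned_plus_discarded(self, vp, library, rng):
        reads = []
        for _ in range(200):
            kind = rng.integers(3)
            if kind == 0:
                reads.append(PRIMER + library[rng.integers(len(library))].sequence)
            elif kind == 1:
                reads.append("ACGT" * 10)
            else:
                reads.append(PRIMER + "".join(rng.choice(list("ACGT"), 20)))
        profile = assign_reads(reads, vp, library)
        assert profile.total_reads + sum(profile.discarded.values()) == len(reads)

    def test_order_invariance(self, vp, library, rng):
        reads = [PRIMER + library[int(i)].sequence
                 for i in rng.integers(len(library), size=100)]
        shuffled = list(reads)
        rng.shuffle(shuffled)
        p1 = assign_reads(reads, vp, library)
        p2 = assign_reads(shuffled, vp, library)
        np.testing.assert_array_equal(p1.counts, p2.counts)

    def test_empty_library_rejected(self, vp):
        with pytest.raises(ValueError):
            assign_reads([], vp, [])

    def test_accepts_tuples_and_seqrecords(self, vp, library):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        read = PRIMER + library[1].sequence
        profile = assign_reads(
            [("r1", read, "I" * len(read)), SeqRecord(Seq(read), id="r2")],
            vp, library,
        )
        assert profile.counts[1] == 2


def make_profile(counts, vp, library, state="raw"):
    return CoverageProfile(viewpoint=vp, library=library,
                           counts=np.asarray(counts, float), state=state)


class TestRemoveTopFragend:
    def test_single_maximum_removed(self, vp, library):
        profile = make_profile([5, 3, 1, 0, 2], vp, library)
        out = remove_top_fragend(profile)
        assert out.removed_fragend.id == library[0].id
        np.testing.assert_array_equal(out.counts, [0, 3, 1, 0, 2])
        assert out.state == "filtered"

    def test_tie_broken_by_lowest_coordinate(self, vp, library):
        profile = make_profile([5, 5, 0, 0, 0], vp, library)
        out = remove_top_fragend(profile)
        assert out.removed_fragend.pos == min(library[0].pos, library[1].pos)

    def test_all_zero_profile_rejected(self, vp, library):
        with pytest.raises(ValueError, match="empty profile"):
            remove_top_fragend(make_profile([0, 0, 0, 0, 0], vp, library))

    def test_requires_raw_state(self, vp, library):
        profile = make_profile([1, 2, 0, 0, 0], vp, library, state="filtered")
        with pytest.raises(ProfileStateError):
            remove_top_fragend(profile)


class TestNormalize:
    def test_cis_counts_scaled_to_one_million(self, vp, library):
        profile = make_profile([2, 3, 5, 0, 0], vp, library, state="filtered")
        out = normalize(profile)
        np.testing.assert_allclose(out.counts[:3], [2e5, 3e5, 5e5])
        assert out.intrachromosomal_total == pytest.approx(1e6, rel=1e-9)

    def test_already_at_target_unchanged(self, vp, library):
        profile = make_profile([4e5, 6e5, 0, 0, 0], vp, library, state="filtered")
        out = normalize(profile)
        assert out.scale_factor == 1.0
        np.testing.assert_array_equal(out.counts, profile.counts)

    def test_trans_fragend_scaled_by_same_factor(self, vp, library):
        # cis sum 1e5 -> s = 10; trans count 4 -> 40
        profile = make_profile([6e4, 4e4, 0, 0, 4], vp, library, state="filtered")
        out = normalize(profile)
        assert out.scale_factor == pytest.approx(10.0)
        assert out.counts[4] == pytest.approx(40.0)

    def test_zero_cis_signal_rejected(self, vp, library):
        profile = make_profile([0, 0, 0, 0, 7], vp, library, state="filtered")
        with pytest.raises(ValueError, match="intrachromosomal"):
            normalize(profile)

    def test_scale_factor_times_cis_sum_is_target(self, vp, library, rng):
        for _ in range(10):
            counts = rng.integers(0, 1000, size=5).astype(float)
            counts[0] += 1  # ensure cis signal
            profile = make_profile(counts, vp, library, state="filtered")
            out = normalize(profile)
            assert out.scale_factor * counts[:4].sum() == pytest.approx(1e6)


def naive_running_mean(values, window):
    """Brute-force shrinking-window oracle."""
    half = (window - 1) // 2
    out = []
    n = len(values)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out.append(np.mean(values[i - h : i + h + 1]))
    return np.array(out)


def long_cis_profile(values, vp):
    lib = make_library([f"SEQ{i}" for i in range(len(values))])
    return CoverageProfile(viewpoint=vp, library=lib,
                           counts=np.asarray(values, float), state="normalized")


class TestRunningMean:
    def test_constant_profile_unchanged(self, vp):
        profile = long_cis_profile([7.5] * 40, vp)
        out = running_mean(profile)
        np.testing.assert_allclose(out.counts, 7.5)
        assert out.state == "smoothed" and out.window == 21

    def test_interior_impulse_spread_over_21_positions(self, vp):
        values = np.zeros(101)
        values[50] = 42.0
        out = running_mean(long_cis_profile(values, vp))
        nonzero = np.flatnonzero(out.counts)
        assert len(nonzero) == 21
        np.testing.assert_allclose(out.counts[nonzero], 42.0 / 21)

    def test_matches_naive_oracle_window5(self, vp, rng):
        values = rng.random(50) * 100
        out = running_mean(long_cis_profile(values, vp), window=5)
        np.testing.assert_allclose(out.counts, naive_running_mean(values, 5),
                                   rtol=1e-12)

    def test_even_window_rejected(self, vp):
        with pytest.raises(ValueError):
            running_mean(long_cis_profile([1.0] * 30, vp), window=4)

    def test_requires_normalized_state(self, vp):
        profile = long_cis_profile([1.0] * 30, vp)
        profile.state = "raw"
        with pytest.raises(ProfileStateError):
            running_mean(profile)

    def test_chromosomes_smoothed_independently(self, vp):
        lib = make_library([f"A{i}" for i in range(30)])
        lib += make_library([f"B{i}" for i in range(30)], chrom="chrT")
        counts = np.zeros(60)
        counts[29] = 21.0  # last frag-end of chrV
        profile = CoverageProfile(viewpoint=vp, library=lib, counts=counts,
                                  state="normalized")
        out = running_mean(profile)
        assert np.all(out.counts[30:] == 0)  # no bleed into chrT
        assert out.counts[29] == pytest.approx(21.0)  # edge window shrinks to 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_linearity(self, seed):
        vp = Viewpoint(name="vp", chrom="chrV", position=0, reading_primer="G")
        rng = np.random.default_rng(seed)
        x, y = rng.random(40), rng.random(40)
        a, b = rng.random(2) * 5
        sm = lambda v: running_mean(long_cis_profile(v, vp)).counts
        np.testing.assert_allclose(sm(a * x + b * y), a * sm(x) + b * sm(y),
                                   rtol=1e-9, atol=1e-12)

    def test_mass_conserved_for_interior_signal(self, vp, rng):
        # all mass >= 10 positions from both edges: every contributing
        # window is full width, so smoothing redistributes without loss
        values = np.zeros(80)
        values[20:60] = rng.random(40) * 50
        out = running_mean(long_cis_profile(values, vp))
        assert out.counts.sum() == pytest.approx(values.sum(), rel=1e-9)
        assert out.counts.mean() == pytest.approx(values.mean(), rel=1e-9)
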