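"""Fragment reading, per-nucleotide occupancy counting, bedGraph output."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucdup.genome_model import GenomicInterval
from nucdup.occupancy import (
    BedParseError,
    FragmentSet,
    compute_occupancy,
    filter_by_length,
    read_fragments_bed,
    write_profile_bedgraph,
)

from .conftest import brute_force_coverage, brute_force_dyad


class TestReadFragmentsBed:
    def test_bed3_passthrough(self):
        fs = read_fragments_bed(io.StringIO("c1\t0\t147\n"))
        assert fs.fragments == [("c1", 0, 147)]

    def test_extra_columns_ignored_and_empty_stream(self):
        fs = read_fragments_bed(io.StringIO("c1\t5\t10\tname\t0\t+\n"))
        assert fs.fragments == [("c1", 5, 10)]
        assert len(read_fragments_bed(io.StringIO(""))) == 0

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("c1\t5\t5\n", "line 1"),
            ("c1\t0\t10\nc1\tfoo\t20\n", "line 2"),
            ("c1\t10\n", "line 1"),
        ],
    )
    def test_errors_name_the_line(self, text, fragment):
        with pytest.raises(BedParseError, match=fragment):
            read_fragments_bed(io.StringIO(text))


class TestComputeOccupancy:
    def test_coverage_counts_match_worked_example(self, toy_fragments):
        iv = GenomicInterval("c", 0, 10, "+", "coding")
        prof = compute_occupancy(toy_fragments, iv)
        assert prof.counts.tolist() == [1, 1, 1, 2, 2, 1, 1, 1, 0, 0]

    def test_minus_strand_reverses_orientation(self, toy_fragments):
        iv = GenomicInterval("c", 0, 10, "-", "coding")
        prof = compute_occupancy(toy_fragments, iv)
        assert prof.counts.tolist() == [0, 0, 1, 1, 1, 2, 2, 1, 1, 1]
        assert prof.genomic_counts.tolist() == [1, 1, 1, 2, 2, 1, 1, 1, 0, 0]

    def test_empty_fragment_set_gives_zeros(self):
        iv = GenomicInterval("c", 0, 10, "+", "coding")
        assert compute_occupancy(FragmentSet([]), iv).counts.sum() == 0

    def test_missing_chromosome_warns_and_zeroes(self, toy_fragments):
        iv = GenomicInterval("other", 0, 10, "+", "coding")
        with pytest.warns(UserWarning, match="no fragments on chromosome"):
            prof = compute_occupancy(toy_fragments, iv)
        assert prof.counts.sum() == 0

    def test_dyad_midpoint_ties_to_lower_central_position(self):
        # length-4 fragment [10,14): central positions 11 and 12 -> 11
        fs = FragmentSet([("c", 10, 14), ("c", 10, 15)])
        iv = GenomicInterval("c", 10, 15, "+", "coding")
        prof = compute_occupancy(fs, iv, mode="dyad")
        assert prof.counts.tolist() == [0, 1, 1, 0, 0]

    def test_half_open_overlap(self):
        # a fragment ending exactly at a position does not cover it
        fs = FragmentSet([("c", 0, 5)])
        iv = GenomicInterval("c", 5, 6, "+", "coding")
        assert compute_occupancy(fs, iv).counts.tolist() == [0]

    def test_unknown_mode_rejected(self, toy_fragments):
        iv = GenomicInterval("c", 0, 10, "+", "coding")
        with pytest.raises(ValueError):
            compute_occupancy(toy_fragments, iv, mode="midpoint")


small_fragment_sets = st.lists(
    st.tuples(
        st.integers(min_value=0, max_value=60),
        st.integers(min_value=1, max_value=30),
    ).map(lambda se: ("c", se[0], se[0] + se[1])),
    max_size=25,
).map(FragmentSet)

small_intervals = st.tuples(
    st.integers(min_value=0, max_value=50),
    st.integers(min_value=1, max_value=40),
    st.sampled_from("+-"),
).map(lambda t: GenomicInterval("c", t[0], t[0] + t[1], t[2], "coding"))


class TestOccupancyProperties:
    @settings(derandomize=True, max_examples=300)
    @given(frags=small_fragment_sets, iv=small_intervals)
    def test_matches_brute_force_oracle(self, frags, iv):
        """Both counting modes agree position-by-position with a naive
        every-position x every-fragment loop, up to strand orientation."""
        cov = compute_occupancy(frags, iv).genomic_counts
        assert cov.tolist() == brute_force_coverage(frags, iv).tolist()
        dyad = compute_occupancy(frags, iv, mode="dyad").genomic_counts
        assert dyad.tolist() == brute_force_dyad(frags, iv).tolist()

    @settings(derandomize=True, max_examples=200)
    @given(frags=small_fragment_sets, iv=small_intervals)
    def test_conservation_and_monotonicity(self, frags, iv):
        """Coverage totals equal the summed fragment-interval intersections;
        adding a fragment never decreases a count."""
        cov = compute_occupancy(frags, iv)
        expected = sum(
            max(0, min(e, iv.end) - max(s, iv.start))
            for c, s, e in frags.fragments
            if c == iv.chrom
        )
        assert cov.counts.sum() == expected

        more = FragmentSet(frags.fragments + [("c", iv.start, iv.end)])
        cov2 = compute_occupancy(more, iv)
        assert (cov2.counts >= cov.counts).all()

    @settings(derandomize=True, max_examples=100)
    @given(frags=small_fragment_sets, iv=small_intervals)
    def test_strand_reversal(self, frags, iv):
        """The + strand profile is the exact reversal of the − strand one."""
        flipped = GenomicInterval(
            iv.chrom, iv.start, iv.end, "-" if iv.strand == "+" else "+", iv.label
        )
        a = compute_occupancy(frags, iv).counts
        b = compute_occupancy(frags, flipped).counts
        assert a.tolist() == b.tolist()[::-1]


class TestBedGraph:
    def _roundtrip(self, profile):
        buf = io.StringIO()
        write_profile_bedgraph(profile, buf)
        counts = np.zeros(len(profile.genomic_interval), dtype=np.int64)
        for line in buf.getvalue().splitlines():
            chrom, s, e, v = line.split("\t")
            counts[int(s) - profile.genomic_interval.start : int(e) - profile.genomic_interval.start] = int(v)
        return buf.getvalue(), counts

    def test_runs_are_merged(self):
        iv = GenomicInterval("c", 100, 103, "+", "coding")
        prof = compute_occupancy(FragmentSet([("c", 100, 102)]), iv)
        text, _ = self._roundtrip(prof)
        assert text == "c\t100\t102\t1\nc\t102\t103\t0\n"

    def test_all_zero_profile_is_single_run(self):
        iv = GenomicInterval("c", 0, 50, "+", "coding")
        text, _ = self._roundtrip(compute_occupancy(FragmentSet([]), iv))
        assert text == "c\t0\t50\t0\n"

    @settings(derandomize=True, max_examples=100)
    @given(frags=small_fragment_sets, iv=small_intervals)
    def test_expansion_recovers_counts(self, frags, iv):
        prof = compute_occupancy(frags, iv)
        _, counts = self._roundtrip(prof)
        assert counts.tolist() == prof.genomic_counts.tolist()


def test_length_filter_keeps_mononucleosome_range():
    fs = FragmentSet([("c", 0, 100), ("c", 0, 147), ("c", 0, 200)])
    kept = filter_by_length(fs, 120, 180)
    assert kept.fragments == [("c", 0, 147)]
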