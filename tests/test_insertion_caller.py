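"""Discordant-pair extraction, interval estimates, orientation, clustering."""

import numpy as np
import pytest

from tepool.config import RunConfig
from tepool.formats_io import GenomicInterval
from tepool.insertion_caller import (
    HOMOLOGY_SLACK,
    DiscordantSupport,
    cluster_supports,
    extract_discordant,
    infer_orientation,
    interval_estimate,
    is_concordant,
)
from tepool.te_matcher import TEHit

from conftest import make_read


class TestIntervalEstimate:
    def test_plus_anchor_extends_downstream(self):
        anchor = make_read(start=910, end=1000, strand="+")
        iv = interval_estimate(anchor, 500)
        assert (iv.start, iv.end) == (1000 - HOMOLOGY_SLACK, 1501)

    def test_minus_anchor_extends_upstream(self):
        anchor = make_read(start=1000, end=1090, strand="-")
        iv = interval_estimate(anchor, 500)
        assert (iv.start, iv.end) == (500, 1001 + HOMOLOGY_SLACK)

    def test_clamping_at_contig_ends(self):
        anchor = make_read(start=9910, end=10_000, strand="+")
        iv = interval_estimate(anchor, 500, contig_length=10_100)
        assert iv.end == 10_100
        anchor = make_read(start=100, end=190, strand="-")
        iv = interval_estimate(anchor, 500)
        assert iv.start == 0
        # an anchor ending at the contig end keeps a (short) valid interval
        anchor = make_read(start=10_010, end=10_100, strand="+")
        iv = interval_estimate(anchor, 500, contig_length=10_100)
        assert 0 <= iv.start < iv.end <= 10_100


class TestOrientation:
    @pytest.mark.parametrize(
        "anchor_strand, te_strand, expected",
        [("+", "+", "-"), ("+", "-", "+"), ("-", "+", "+"), ("-", "-", "-")],
    )
    def test_fr_geometry_truth_table(self, anchor_strand, te_strand, expected):
        assert infer_orientation(anchor_strand, te_strand) == expected

    def test_flipping_te_strand_flips_result(self):
        for a in "+-":
            for t in "+-":
                other = "-" if t == "+" else "+"
                assert infer_orientation(a, t) != infer_orientation(a, other)


def _support(contig, family, orientation, start, end, name="s", side="left"):
    anchor = make_read(name=name, contig=contig, start=max(0, start - 90),
                       end=start, strand="+" if side == "left" else "-")
    return DiscordantSupport(
        anchor=anchor,
        te_hit=TEHit(family, "+", 0, 0),
        interval=GenomicInterval(contig, start, end),
        orientation=orientation,
        side=side,
    )


class TestClustering:
    def test_overlapping_intervals_intersect(self):
        sup = [
            _support("chr1", "roo", "+", 100, 600, "a"),
            _support("chr1", "roo", "+", 400, 900, "b", side="right"),
        ]
        events = cluster_supports(sup)
        assert len(events) == 1
        ev = events[0]
        assert (ev.interval.start, ev.interval.end) == (400, 600)
        assert ev.T == 2
        assert ev.support_sides == "both"

    def test_disjoint_intervals_stay_separate(self):
        sup = [
            _support("chr1", "roo", "+", 100, 600, "a"),
            _support("chr1", "roo", "+", 700, 900, "b"),
        ]
        assert len(cluster_supports(sup)) == 2

    def test_orientation_separates_clusters(self):
        sup = [
            _support("chr1", "roo", "+", 100, 600, "a"),
            _support("chr1", "roo", "-", 100, 600, "b"),
        ]
        events = cluster_supports(sup)
        assert len(events) == 2
        assert {e.strand for e in events} == {"+", "-"}

    def test_family_separates_clusters(self):
        sup = [
            _support("chr1", "roo", "+", 100, 600, "a"),
            _support("chr1", "jockey", "+", 100, 600, "b"),
        ]
        assert len(cluster_supports(sup)) == 2

    def test_chain_with_empty_intersection_splits(self):
        # a-b overlap, b-c overlap, but a-c do not: greedy left-to-right
        sup = [
            _support("chr1", "roo", "+", 100, 500, "a"),
            _support("chr1", "roo", "+", 400, 800, "b"),
            _support("chr1", "roo", "+", 600, 1000, "c"),
        ]
        events = cluster_supports(sup)
        assert len(events) == 2
        assert (events[0].interval.start, events[0].interval.end) == (400, 500)
        assert (events[1].interval.start, events[1].interval.end) == (600, 1000)

    def test_refined_interval_is_subset_of_members(self, rng):
        sup = []
        for i in range(100):
            start = int(rng.integers(0, 5000))
            sup.append(
                _support("chr1", "roo", "+", start, start + 500, f"s{i}")
            )
        for ev in cluster_supports(sup):
            for m in ev.supports:
                assert m.interval.start <= ev.interval.start
                assert ev.interval.end <= m.interval.end
            assert len(ev.interval) >= 1

    def test_permutation_invariance(self, rng):
        sup = [
            _support("chr1", "roo", "+", int(s), int(s) + 500, f"s{i}")
            for i, s in enumerate(rng.integers(0, 3000, size=60))
        ]
        ref = [
            (e.interval.start, e.interval.end, e.T) for e in cluster_supports(sup)
        ]
        for _ in range(5):
            shuffled = list(sup)
            rng.shuffle(shuffled)
            got = [
                (e.interval.start, e.interval.end, e.T)
                for e in cluster_supports(shuffled)
            ]
            assert got == ref

    def test_matches_transitive_closure_oracle_membership(self):
        """Cluster memberships equal single-linkage connected components,
        except that chains with empty common intersection are split; on
        instances where every component has a common intersection the two
        agree exactly (500 random instances)."""
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = int(rng.integers(2, 40))
            width = int(rng.integers(200, 600))
            starts = rng.integers(0, 1500, size=n)
            sup = [
                _support("chr1", "roo", "+", int(s), int(s) + width, f"s{i}")
                for i, s in enumerate(starts)
            ]
            # oracle: connected components under pairwise >=1 bp overlap
            adj = (starts[:, None] < starts[None, :] + width) & (
                starts[None, :] < starts[:, None] + width
            )
            labels = -np.ones(n, dtype=int)
            ncomp = 0
            for i in range(n):
                if labels[i] >= 0:
                    continue
                stack = [i]
                labels[i] = ncomp
                while stack:
                    j = stack.pop()
                    for k in np.nonzero(adj[j])[0]:
                        if labels[k] < 0:
                            labels[k] = ncomp
                            stack.append(k)
                ncomp += 1
            components = [
                {f"s{i}" for i in range(n) if labels[i] == c} for c in range(ncomp)
            ]
            # equal-width intervals: a single-linkage chain always has a
            # non-empty common intersection only if max-min start < width;
            # our clusters must refine the oracle partition
            clusters = [
                {m.anchor.name for m in e.supports} for e in cluster_supports(sup)
            ]
            assert sorted(len(c) for c in clusters) and sum(
                len(c) for c in clusters
            ) == n
            for cluster in clusters:
                assert any(cluster <= comp for comp in components)
            for comp in components:
                span = [int(s) for i, s in enumerate(starts) if f"s{i}" in comp]
                if max(span) - min(span) < width:  # common intersection exists
                    assert comp in clusters


class TestExtractDiscordant:
    def _pair(self, tiny_library, mate_seq, mate_mapped=False, mate_unique=False,
              concordant=False):
        anchor = make_read(
            name="p", contig="chr1", start=1000, end=1090, strand="+",
            mapq=60, is_read1=True, mate_mapped=mate_mapped,
            seq="G" * 90,
        )
        if concordant:
            mate = make_read(
                name="p", contig="chr1", start=1400, end=1490, strand="-",
                mapq=60, is_unique=True, is_read1=False, seq=mate_seq,
            )
        else:
            mate = make_read(
                name="p", contig="chr1" if mate_mapped else None,
                start=1000 if mate_mapped else -1,
                end=1090 if mate_mapped else -1,
                strand="+", mapq=0, is_unique=mate_unique,
                is_mapped=mate_mapped, is_read1=False, seq=mate_seq,
            )
        return [anchor, mate]

    def test_concordant_pair_excluded(self, tiny_library):
        reads = self._pair(tiny_library, tiny_library["alpha"][:90],
                           mate_mapped=True, mate_unique=True, concordant=True)
        cfg = RunConfig(insert_mean=500, insert_sd=50)
        assert extract_discordant(reads, tiny_library, cfg) == []

    def test_unmapped_te_mate_yields_support(self, tiny_library):
        reads = self._pair(tiny_library, tiny_library["alpha"][100:190])
        cfg = RunConfig(insert_mean=500, insert_sd=50)
        supports = extract_discordant(reads, tiny_library, cfg)
        assert len(supports) == 1
        s = supports[0]
        assert s.family == "alpha"
        assert s.side == "left"
        assert s.interval.start == 1090 - HOMOLOGY_SLACK

    def test_mate_without_te_hit_excluded(self, tiny_library, rng):
        from conftest import random_seq

        reads = self._pair(tiny_library, random_seq(rng, 90))
        cfg = RunConfig(insert_mean=500, insert_sd=50)
        assert extract_discordant(reads, tiny_library, cfg) == []

    def test_te_matching_anchor_rejected(self, tiny_library):
        reads = self._pair(tiny_library, tiny_library["alpha"][100:190])
        reads[0].seq = tiny_library["beta"][0:90]  # anchor itself is TE
        cfg = RunConfig(insert_mean=500, insert_sd=50)
        assert extract_discordant(reads, tiny_library, cfg) == []


class TestConcordance:
    def test_fr_within_band_is_concordant(self):
        r1 = make_read(name="p", start=1000, end=1090, strand="+")
        r2 = make_read(name="p", start=1400, end=1490, strand="-", is_read1=False)
        assert is_concordant(r1, r2, 650)
        assert not is_concordant(r1, r2, 400)

    def test_same_strand_or_rf_is_discordant(self):
        r1 = make_read(name="p", start=1000, end=1090, strand="+")
        r2 = make_read(name="p", start=1400, end=1490, strand="+", is_read1=False)
        assert not is_concordant(r1, r2, 650)
        r3 = make_read(name="p", start=500, end=590, strand="-", is_read1=False)
        assert not is_concordant(r1, r3, 650)
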