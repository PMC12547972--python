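"""Split-homolog detection: joint coverage, adjacency, contamination and
the exhaustive-enumeration oracle."""

import itertools

import numpy as np
import pytest

from splithom import (ContaminationModel, GenomeAlignmentInstance, PipelineParams,
                      joint_candidates, neighborhood_filter, finalize_split_calls,
                      union_coverage)
from splithom.split import detect_split_homologs

P = PipelineParams()


def inst(family="famA", rank=1, sstart=1, send=100, slen=200, contig="c1",
         strand="+", pident=35.0, gene=None, human="humX", genome="G1"):
    return GenomeAlignmentInstance(
        human_id=human, genome_id=genome, contig_id=contig, strand=strand,
        feature_rank=rank, gene_id=gene or f"g{rank}_{family}", family_id=family,
        sstart=sstart, send=send, slen=slen, pident=pident, bitscore=100.0)


class TestUnionCoverage:
    @pytest.mark.parametrize(
        "intervals, length, expected",
        [
            ([(1, 150)], 150, 1.0),
            ([(1, 60), (50, 120)], 150, 0.80),
            ([(1, 60), (80, 150)], 150, 131 / 150),
            ([], 100, 0.0),
        ],
    )
    def test_examples(self, intervals, length, expected):
        assert union_coverage(intervals, length) == pytest.approx(expected)

    def test_matches_position_mask_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            length = int(rng.integers(20, 400))
            k = int(rng.integers(1, 6))
            intervals = []
            mask = np.zeros(length, bool)
            for _ in range(k):
                s = int(rng.integers(1, length + 1))
                e = int(rng.integers(s, length + 1))
                intervals.append((s, e))
                mask[s - 1:e] = True
            assert union_coverage(intervals, length) == pytest.approx(mask.sum() / length)


class TestJointCandidates:
    def test_joint_but_not_individual(self):
        # 40% and ~47% individually, union 87%
        group = [inst("famA", 1, 1, 60, 150), inst("famB", 2, 80, 150, 150)]
        kept = joint_candidates(group, P)
        assert ("humX", "G1") in kept

    def test_individually_covering_member_excludes_group(self):
        group = [inst("famA", 1, 1, 113, 150), inst("famB", 2, 80, 150, 150)]
        assert joint_candidates(group, P) == {}

    def test_union_below_threshold_excluded(self):
        group = [inst("famA", 1, 1, 45, 150), inst("famB", 2, 100, 150, 150)]
        assert joint_candidates(group, P) == {}


class TestNeighborhoodFilter:
    def _pair(self, r1, r2, strand2="+", contig2="c1"):
        return [inst("famA", r1, 1, 60, 150),
                inst("famB", r2, 50, 150, 150, contig=contig2, strand=strand2)]

    def test_gap_three_retained(self):
        assert len(neighborhood_filter(self._pair(5, 8), P)) == 1

    def test_gap_four_rejected(self):
        assert neighborhood_filter(self._pair(5, 9), P) == []

    def test_opposite_strands_rejected(self):
        assert neighborhood_filter(self._pair(5, 7, strand2="-"), P) == []

    def test_different_contigs_rejected(self):
        assert neighborhood_filter(self._pair(5, 7, contig2="c2"), P) == []

    def test_chained_adjacency_forms_one_component(self):
        group = [inst("famA", 2, 1, 50, 150), inst("famB", 4, 40, 100, 150),
                 inst("famC", 6, 90, 150, 150)]
        (nb,) = neighborhood_filter(group, P)
        assert len(nb.members) == 3
        assert nb.joint_coverage == pytest.approx(1.0)

    def test_coverage_retested_per_component(self):
        # members jointly cover 87% but the far member is out of range,
        # and the remaining pair covers too little
        group = [inst("famA", 1, 1, 60, 150), inst("famB", 2, 55, 80, 150),
                 inst("famC", 20, 80, 150, 150)]
        assert neighborhood_filter(group, P) == []


class TestFinalize:
    def test_contaminated_member_removal_breaks_neighborhood(self):
        model = ContaminationModel(32.3, 7.6, 55.2, 10)
        group = [inst("famA", 1, 1, 60, 150, pident=60.0),
                 inst("famB", 2, 50, 150, 150, pident=30.0)]
        (nb,) = neighborhood_filter(group, P)
        assert finalize_split_calls([nb], model, P) == []

    def test_clean_neighborhood_unchanged(self):
        model = ContaminationModel(32.3, 7.6, 55.2, 10)
        group = [inst("famA", 1, 1, 60, 150, pident=30.0),
                 inst("famB", 2, 50, 150, 150, pident=40.0)]
        (nb,) = neighborhood_filter(group, P)
        assert finalize_split_calls([nb], model, P) == [nb]

    def test_removal_dropping_union_below_threshold(self):
        model = ContaminationModel(30.0, 5.0, 45.0, 10)
        group = [inst("famA", 1, 1, 60, 150, pident=30.0),
                 inst("famB", 2, 55, 110, 150, pident=30.0),
                 inst("famC", 3, 100, 150, 150, pident=60.0)]
        (nb,) = neighborhood_filter(group, P)
        # famC removed: union of famA+famB = 110/150 ~ 0.73 still passes
        final = finalize_split_calls([nb], model, P)
        assert len(final) == 1
        assert {m.family_id for m in final[0].members} == {"famA", "famB"}
        # shrink famB so the post-removal union fails instead
        group[1] = inst("famB", 2, 55, 90, 150, pident=30.0)
        (nb2,) = neighborhood_filter(group, P)
        assert finalize_split_calls([nb2], model, P) == []


# ---------------------------------------------------------------------------
# Exhaustive-enumeration oracle
# ---------------------------------------------------------------------------

def _enumerate_components(members, params):
    """All maximal same-contig/strand subsets chained by rank gap <=
    max_feature_distance, with >= 2 distinct families and joint coverage
    >= threshold, found by subset enumeration."""
    found = set()
    n = len(members)
    for size in range(2, n + 1):
        for idx in itertools.combinations(range(n), size):
            mem = [members[i] for i in idx]
            if len({(m.contig_id, m.strand) for m in mem}) != 1:
                continue
            ranks = sorted(m.feature_rank for m in mem)
            if any(b - a > params.max_feature_distance for a, b in zip(ranks, ranks[1:])):
                continue
            rest = [members[i] for i in range(n) if i not in idx]
            if any(
                r.contig_id == mem[0].contig_id and r.strand == mem[0].strand
                and min(abs(r.feature_rank - m.feature_rank) for m in mem)
                <= params.max_feature_distance
                for r in rest
            ):
                continue  # not maximal
            if len({m.family_id for m in mem}) < 2:
                continue
            if union_coverage([(m.sstart, m.send) for m in mem], mem[0].slen) \
                    < params.human_cov_min:
                continue
            found.add(frozenset(m.gene_id for m in mem))
    return found


def _oracle_split(group, model, params):
    """Stage-faithful enumeration: S4 on the whole group, S5 components by
    enumeration, S6 member removal then re-enumeration inside each
    neighborhood."""
    if any(m.subject_coverage >= params.human_cov_min for m in group):
        return set()
    if union_coverage([(m.sstart, m.send) for m in group], group[0].slen) \
            < params.human_cov_min:
        return set()
    final = set()
    for comp in _enumerate_components(group, params):
        mem = [m for m in group if m.gene_id in comp]
        survivors = [m for m in mem if m.pident <= model.cutoff]
        final |= _enumerate_components(survivors, params) if len(survivors) >= 2 else set()
    return final


def _random_group(rng):
    n = int(rng.integers(2, 13))
    slen = int(rng.integers(100, 300))
    members = []
    used = set()
    for i in range(n):
        rank = int(rng.integers(1, 20))
        while rank in used:
            rank = int(rng.integers(1, 20))
        used.add(rank)
        s = int(rng.integers(1, slen))
        e = min(slen, s + int(rng.integers(10, slen)))
        members.append(inst(
            family=f"fam{int(rng.integers(0, 5))}", rank=rank, sstart=s, send=e,
            slen=slen, contig=f"c{int(rng.integers(1, 3))}",
            strand="+-"[int(rng.integers(0, 2))],
            pident=float(rng.uniform(20, 70)), gene=f"g{i}"))
    return members


def test_enumeration_oracle_equivalence():
    """Split neighborhoods on random <= 12-instance groups equal
    exhaustive subset enumeration, over 200 random trials."""
    rng = np.random.default_rng(11)
    model = ContaminationModel(35.0, 8.0, 59.0, 10)
    for _ in range(200):
        group = _random_group(rng)
        candidates = joint_candidates(group, P)
        neighborhoods = []
        for key in sorted(candidates):
            neighborhoods.extend(neighborhood_filter(candidates[key], P))
        final = finalize_split_calls(neighborhoods, model, P)
        got = {frozenset(m.gene_id for m in nb.members) for nb in final}
        assert got == _oracle_split(group, model, P)


class TestInvariantsOnFixture:
    def test_final_call_invariants(self, run):
        p = run.params
        for nb in run.split_calls:
            fams = {m.family_id for m in nb.members}
            assert len(fams) >= 2
            assert all(m.genome_id == nb.genome_id for m in nb.members)
            assert all(m.contig_id == nb.contig_id for m in nb.members)
            assert all(m.strand == nb.strand for m in nb.members)
            assert all(m.subject_coverage < p.human_cov_min for m in nb.members)
            assert all(m.pident <= run.contamination.cutoff for m in nb.members)
            assert nb.max_rank_gap <= p.max_feature_distance
            assert nb.joint_coverage >= p.human_cov_min
            assert nb.joint_coverage >= max(m.subject_coverage for m in nb.members)

    def test_filters_only_shrink(self, run):
        led = run.ledger
        assert led["split_calls_final"] <= led["split_neighborhoods_after_distance"]
        assert led["after_microbe_coverage"] <= led["after_best_human_hit"] <= led["alignments_raw"]
        assert led["full_after_contamination"] <= led["full_after_human_coverage"]
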