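"""Shared filters, contamination model and full-length calling."""

import numpy as np
import pytest

from splithom import (AlignmentHSP, GenomeFeature, PipelineParams, best_human_hit,
                      call_full_length, coverage, filter_microbe_side,
                      fit_contamination)
from splithom.homology import filter_human_side

P = PipelineParams()


def hsp(query="famA", subject="humX", pident=35.0, qstart=1, qend=100,
        sstart=1, send=100, evalue=1e-30, bitscore=100.0, qlen=100, slen=100):
    return AlignmentHSP(query, subject, pident, qstart, qend, sstart, send,
                        evalue, bitscore, qlen, slen)


class TestCoverage:
    @pytest.mark.parametrize(
        "kw, side, expected",
        [
            (dict(qstart=1, qend=100, qlen=150), "query", 100 / 150),
            (dict(qstart=1, qend=100, qlen=100), "query", 1.0),
            (dict(sstart=10, send=39, slen=100), "subject", 0.30),
        ],
    )
    def test_position_count(self, kw, side, expected):
        assert coverage(hsp(**kw), side) == pytest.approx(expected)

    def test_matches_mask_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            length = int(rng.integers(10, 500))
            start = int(rng.integers(1, length + 1))
            end = int(rng.integers(start, length + 1))
            h = hsp(sstart=start, send=end, slen=length)
            mask = np.zeros(length, bool)
            mask[start - 1:end] = True
            assert coverage(h, "subject") == pytest.approx(mask.sum() / length)


class TestBestHumanHit:
    def test_highest_bitscore_wins(self):
        hsps = [hsp(subject="humX", bitscore=120), hsp(subject="humY", bitscore=90)]
        assert {h.subject_id for h in best_human_hit(hsps)} == {"humX"}

    def test_bitscore_tie_broken_by_evalue(self):
        hsps = [hsp(subject="humX", bitscore=100, evalue=1e-20),
                hsp(subject="humY", bitscore=100, evalue=1e-30)]
        assert {h.subject_id for h in best_human_hit(hsps)} == {"humY"}

    def test_full_tie_broken_lexicographically(self):
        hsps = [hsp(subject="humY"), hsp(subject="humX")]
        assert {h.subject_id for h in best_human_hit(hsps)} == {"humX"}

    def test_all_hsps_of_winning_pair_kept(self):
        hsps = [hsp(subject="humX", bitscore=120, sstart=1, send=50),
                hsp(subject="humX", bitscore=40, sstart=60, send=100),
                hsp(subject="humY", bitscore=90)]
        assert len(best_human_hit(hsps)) == 2

    def test_families_independent(self):
        hsps = [hsp(query="famA", subject="humX"), hsp(query="famB", subject="humY")]
        assert len(best_human_hit(hsps)) == 2


class TestMicrobeFilter:
    def test_short_family_dropped_even_at_full_coverage(self):
        assert filter_microbe_side([hsp(qstart=1, qend=79, qlen=79)], P) == []

    def test_boundary_coverage_kept(self):
        # 54/80 = 0.675 >= 0.67
        kept = filter_microbe_side([hsp(qstart=1, qend=54, qlen=80)], P)
        assert len(kept) == 1

    def test_below_threshold_dropped(self):
        # 66/100 = 0.66 < 0.67
        assert filter_microbe_side([hsp(qstart=1, qend=66, qlen=100)], P) == []


class TestContamination:
    def test_hand_computed_model(self):
        hsps = [hsp(pident=p) for p in (20.0, 30.0, 40.0)]
        m = fit_contamination(hsps, P)
        assert m.mean_pident == pytest.approx(30.0)
        assert m.sd_pident == pytest.approx(10.0)  # sample SD, n-1
        assert m.cutoff == pytest.approx(60.0)

    def test_degenerate_equal_pidents_warns(self, caplog):
        m = fit_contamination([hsp(pident=30.0)] * 3, P)
        assert m.cutoff == pytest.approx(30.0)
        assert "degenerate" in caplog.text

    def test_single_alignment_fatal(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_contamination([hsp()], P)


def _one_genome_features(genes, genome="G1"):
    return [
        GenomeFeature(genome, "c1", i + 1, "+", 100 * (i + 1), 100 * (i + 1) + 50, g)
        for i, g in enumerate(genes)
    ]


class TestCallFullLength:
    def test_passing_alignment_yields_one_call(self):
        hsps = [hsp(pident=40.0, sstart=1, send=75, slen=100, bitscore=100),
                hsp(query="famB", subject="humX", pident=30.0, sstart=1, send=80,
                    slen=100, bitscore=90)]
        calls, model = call_full_length(
            hsps, {"g1": "famA", "g2": "famB"},
            _one_genome_features(["g1"]) + _one_genome_features(["g2"], "G2"), P)
        assert {(c.human_id, c.genome_id, c.family_id) for c in calls} == {
            ("humX", "G1", "famA"), ("humX", "G2", "famB")}

    def test_pident_above_cutoff_dropped_at_boundary(self):
        from splithom import ContaminationModel
        model = ContaminationModel(32.3, 7.6, 55.2, 100)
        hsps = [hsp(query=f"fam{q}", subject=f"hum{q}", pident=p, sstart=1, send=75, slen=100)
                for q, p in (("A", 56.0), ("B", 55.2), ("C", 40.0))]
        cm = {f"g{q}": f"fam{q}" for q in "ABC"}
        feats = _one_genome_features([f"g{q}" for q in "ABC"])
        calls, _ = call_full_length(hsps, cm, feats, P, contamination=model)
        # strictly above the cutoff is dropped; equality is retained
        assert {c.family_id for c in calls} == {"famB", "famC"}

    def test_best_call_per_genome(self):
        # two member genes of one family in one genome -> a single call
        hsps = [hsp(pident=40.0, sstart=1, send=75, slen=100),
                hsp(query="famB", pident=30.0, sstart=1, send=75, slen=100, bitscore=50)]
        cm = {"g1": "famA", "g2": "famA", "g3": "famB"}
        calls, _ = call_full_length(hsps, cm, _one_genome_features(["g1", "g2", "g3"]), P)
        assert len([c for c in calls if c.family_id == "famA"]) == 1
        # and per (human, genome) only the best-bitscore family is called
        assert {c.family_id for c in calls} == {"famA"}

    def test_family_without_members_warns(self, caplog):
        hsps = [hsp(sstart=1, send=75, slen=100),
                hsp(query="famB", sstart=1, send=75, slen=100)]
        calls, _ = call_full_length(hsps, {"g1": "famA"}, _one_genome_features(["g1"]), P)
        assert "famB" in caplog.text
        assert {c.family_id for c in calls} == {"famA"}


def _random_hsps(rng, n):
    out = []
    for i in range(n):
        qlen = int(rng.integers(60, 300))
        slen = int(rng.integers(100, 500))
        qs = int(rng.integers(1, qlen))
        qe = int(rng.integers(qs, qlen + 1))
        ss = int(rng.integers(1, slen))
        se = int(rng.integers(ss, slen + 1))
        out.append(AlignmentHSP(
            f"fam{int(rng.integers(0, 12))}", f"hum{int(rng.integers(0, 6))}",
            float(rng.uniform(10, 99)), qs, qe, ss, se,
            float(10.0 ** -rng.integers(5, 60)), float(rng.uniform(30, 300)),
            qlen, slen))
    return out


class TestProperties:
    def test_raising_human_coverage_never_adds_calls(self):
        rng = np.random.default_rng(7)
        hsps = _random_hsps(rng, 80)
        cm = {f"g{i}": f"fam{i}" for i in range(12)}
        feats = _one_genome_features([f"g{i}" for i in range(12)])
        step12 = filter_microbe_side(best_human_hit(hsps), P)
        prev = None
        for h in (0.60, 0.70, 0.80, 0.90):
            if len(filter_human_side(step12, P.with_coverages(P.microbe_cov_min, h))) < 2:
                break
            calls, _ = call_full_length(step12, cm, feats, P.with_coverages(P.microbe_cov_min, h))
            pairs = {(c.human_id, c.genome_id) for c in calls}
            if prev is not None:
                assert pairs <= prev
            prev = pairs

    def test_retained_hsps_satisfy_all_predicates(self, run):
        p = run.params
        for h in run.hsps_f3:
            assert coverage(h, "query") >= p.microbe_cov_min
            assert h.qlen >= p.min_microbe_len
            assert coverage(h, "subject") >= p.human_cov_min

    def test_brute_force_oracle_equivalence(self):
        """Calls on small random inputs equal a row-by-row predicate filter
        followed by an independent best-per-group reduction."""
        cm = {f"g{i}": f"fam{i % 12}" for i in range(24)}
        feats = (_one_genome_features([f"g{i}" for i in range(12)], "G1")
                 + _one_genome_features([f"g{i}" for i in range(12, 24)], "G2"))
        gene_of_family_genome = {}
        for g, fam in cm.items():
            genome = "G1" if int(g[1:]) < 12 else "G2"
            gene_of_family_genome.setdefault((fam, genome), []).append(g)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            hsps = _random_hsps(rng, int(rng.integers(20, 100)))
            step12 = filter_microbe_side(best_human_hit(hsps), P)
            f3 = filter_human_side(step12, P)
            if len(f3) < 2:
                continue
            calls, model = call_full_length(step12, cm, feats, P)

            # oracle: independent per-row predicates, then explicit argmax
            expected = {}
            for h in f3:
                if h.pident > model.cutoff:
                    continue
                for genome in ("G1", "G2"):
                    if (h.query_id, genome) not in gene_of_family_genome:
                        continue
                    key = (h.subject_id, genome)
                    cand = expected.get(key)
                    rank = (-h.bitscore, h.evalue, h.query_id)
                    if cand is None or rank < cand[0]:
                        expected[key] = (rank, h.query_id)
            assert {(c.human_id, c.genome_id, c.family_id) for c in calls} == {
                (hum, gen, fam) for (hum, gen), (_, fam) in expected.items()
            }
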