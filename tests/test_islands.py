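import numpy as np
import pandas as pd
import pytest

from pangei.genome import AnnotatedGenome, GeneRecord, Replicon
from pangei.islands import (CandidateRegion, EvidenceVector, IslandConfig,
                            call_islands, candidate_regions,
                            direct_repeat_search, evidence_for,
                            mobile_density, trna_adjacency)
from pangei.pipeline import jaccard, run_pipeline


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestCandidates:
    def test_homogeneous_profile_yields_no_candidates(self):
        genes = [GeneRecord(f"g{i}", "chr", i * 300, i * 300 + 240)
                 for i in range(30)]
        g = AnnotatedGenome([Replicon("chr", 9100)], genes)
        prof = pd.DataFrame({"z_gc3": 0.0, "z_cai": 0.0},
                            index=[x.id for x in genes])
        assert candidate_regions(prof, None, g) == []

    def test_planted_island_found_as_composition_candidate(self, sim_genome):
        genome, truth = sim_genome
        from pangei.genome import extract_cds_sequences
        from pangei import codon
        codons = extract_cds_sequences(genome)
        w = codon.reference_weights(codons, truth.highly_expressed)
        prof = codon.composition_zscores(codons, w)
        cands = candidate_regions(prof, None, genome)
        isl = truth.islands[0]
        best = max(jaccard((c.start, c.end), (isl.start, isl.end)) for c in cands)
        assert best >= 0.8

    def test_cgh_variability_merges_with_composition(self, sim_genome):
        genome, truth = sim_genome
        from pangei.genome import extract_cds_sequences
        from pangei import codon
        codons = extract_cds_sequences(genome)
        w = codon.reference_weights(codons, truth.highly_expressed)
        prof = codon.composition_zscores(codons, w)
        cands = candidate_regions(prof, truth.status, genome)
        assert len(cands) == len(truth.islands)
        assert all(c.source == "merged" for c in cands)


class TestDirectRepeats:
    def _flanked(self, rng, dr_len, island_len=800, flank=1200):
        dr = _random_seq(rng, dr_len)
        left = _random_seq(rng, flank)
        body = _random_seq(rng, island_len)
        right = _random_seq(rng, flank)
        seq = left + dr + body + dr + right
        start = flank + dr_len
        return seq, (start, start + island_len), dr

    def test_planted_20mer_found_exactly(self):
        rng = np.random.default_rng(0)
        seq, ivl, dr = self._flanked(rng, 20)
        hit = direct_repeat_search(seq, ivl)
        assert hit is not None
        assert (hit.length, hit.mismatches) == (20, 0)
        assert seq[hit.left_start:hit.left_start + 20] == dr
        assert hit.right_start == ivl[1]

    def test_planted_10mer_at_floor_found(self):
        rng = np.random.default_rng(5)
        seq, ivl, dr = self._flanked(rng, 10)
        hit = direct_repeat_search(seq, ivl)
        assert hit is not None and hit.length == 10

    def test_9mer_below_floor_not_reported(self):
        rng = np.random.default_rng(1)
        seq, ivl, _ = self._flanked(rng, 9)
        assert direct_repeat_search(seq, ivl) is None

    def test_random_flanks_give_none(self):
        rng = np.random.default_rng(2)
        seq = _random_seq(rng, 4000)
        assert direct_repeat_search(seq, (1800, 2200)) is None

    def test_one_mismatch_tolerated_when_allowed(self):
        rng = np.random.default_rng(3)
        seq, ivl, dr = self._flanked(rng, 30)
        mutated = list(seq)
        pos = ivl[0] - 15  # inside the left repeat copy
        mutated[pos] = "A" if seq[pos] != "A" else "C"
        seq_mm = "".join(mutated)
        assert direct_repeat_search(seq_mm, ivl) is None or \
            direct_repeat_search(seq_mm, ivl).length < 30
        cfg = IslandConfig(dr_max_mismatch=1)
        hit = direct_repeat_search(seq_mm, ivl, cfg)
        assert hit is not None and hit.length == 30 and hit.mismatches == 1

    def test_length_capped_at_112(self):
        rng = np.random.default_rng(4)
        seq, ivl, _ = self._flanked(rng, 112)
        hit = direct_repeat_search(seq, ivl)
        assert hit is not None and hit.length == 112


class TestTrnaAndMobile:
    def _genome_with_trna(self, trna_start, strand):
        seq_len = 20000
        trna = GeneRecord("t1", "chr", trna_start, trna_start + 76, strand, "tRNA")
        cds = GeneRecord("c1", "chr", 12000, 12600, "+", "CDS")
        return AnnotatedGenome([Replicon("chr", seq_len)], [trna, cds])

    def test_plus_strand_trna_200bp_upstream(self):
        g = self._genome_with_trna(9724, "+")  # 3' end at 9800
        assert trna_adjacency((10000, 15000), g)

    def test_distant_trna_false(self):
        g = self._genome_with_trna(100, "+")
        assert not trna_adjacency((10000, 15000), g)

    def test_minus_strand_uses_start_coordinate(self):
        # minus-strand tRNA: 3' end is the feature start
        g = self._genome_with_trna(10005, "-")  # 3' end 10005, inside first kb
        assert trna_adjacency((10000, 15000), g)
        g2 = self._genome_with_trna(8000, "-")  # 3' end 8000: 2 kb upstream
        assert not trna_adjacency((10000, 15000), g2)

    def test_mobile_density_counts(self):
        genes = [GeneRecord("i1", "chr", 1000, 1600, "+", "CDS",
                            mobility_class="IS_transposase"),
                 GeneRecord("i2", "chr", 2000, 2600, "+", "CDS",
                            mobility_class="integrase"),
                 GeneRecord("h1", "chr", 5000, 5600, "+", "CDS")]
        g = AnnotatedGenome([Replicon("chr", 10000)], genes)
        assert mobile_density((500, 3000), g) == (2, True)
        assert mobile_density((4000, 8000), g) == (0, False)

    def test_most_mobile_genes_concentrate_in_islands(self, sim_genome):
        genome, truth = sim_genome
        mobile = [g for g in genome.genes if g.mobility_class != "none"]
        inside = sum(1 for g in mobile if any(
            isl.start <= g.midpoint < isl.end for isl in truth.islands))
        assert inside / len(mobile) >= 0.7


@pytest.fixture(scope="module")
def pipeline_result(default_cfg):
    return run_pipeline(default_cfg)


class TestCallIslands:
    def test_policy_counting(self, pipeline_result):
        for call in pipeline_result.island_calls:
            ev = call.evidence
            expected = sum([ev.composition_anomaly, ev.synteny_break,
                            ev.mobile_genes, ev.trna_3prime_adjacent,
                            ev.direct_repeat is not None])
            assert call.n_criteria_met == expected

    def test_cgh_only_candidate_rejected_by_default_policy(self, sim_genome):
        genome, truth = sim_genome
        # fabricate a flat profile: no composition anomaly anywhere
        prof = pd.DataFrame({"z_gc3": 0.0, "z_cai": 0.0},
                            index=[g.id for g in genome.cds()])
        cand = CandidateRegion("chr", truth.islands[0].start,
                               truth.islands[0].end, "cgh_variability",
                               truth.islands[0].gene_ids)
        calls = call_islands([cand], genome, prof, truth.status, None)
        assert not calls[0].accepted
        assert calls[0].evidence.cgh_variable

    def test_full_synthetic_run_recovers_all_islands(self, pipeline_result):
        res = pipeline_result
        accepted = res.accepted_islands()
        assert len(accepted) == len(res.truth.islands)  # zero false positives
        for isl in res.truth.islands:
            best = max(jaccard((c.start, c.end), (isl.start, isl.end))
                       for c in accepted)
            assert best >= 0.8

    def test_planted_direct_repeats_found_exactly(self, pipeline_result):
        res = pipeline_result
        accepted = sorted(res.accepted_islands(), key=lambda c: c.start)
        for call, isl in zip(accepted, res.truth.islands):
            dr = call.evidence.direct_repeat
            assert dr is not None
            assert dr.length == isl.spec.dr_length
            assert (dr.left_start, dr.right_start) == isl.dr

    def test_evidence_idempotent_on_called_interval(self, pipeline_result):
        res = pipeline_result
        cfg = IslandConfig()
        for call in res.accepted_islands():
            strains = [c for c in res.status.columns if c != "REF"]
            again = evidence_for((call.start, call.end), call.replicon_id,
                                 res.genome, res.profile,
                                 res.status[strains], res.blocks, cfg)
            assert again == call.evidence

    def test_acceptance_monotone_in_evidence(self, pipeline_result):
        cfg = IslandConfig()
        for call in pipeline_result.island_calls:
            if call.accepted:
                ev = call.evidence
                stronger = EvidenceVector(
                    ev.composition_anomaly, True, max(ev.mobile_count, 1), True,
                    True, ev.direct_repeat, ev.cgh_variable)
                assert stronger.n_criteria_met >= ev.n_criteria_met
                assert (stronger.composition_anomaly
                        and stronger.n_criteria_met >= cfg.min_criteria)

    def test_boundary_refinement_bounded_by_flank(self, pipeline_result):
        cfg = IslandConfig()
        calls = {c.start: c for c in pipeline_result.island_calls}
        for isl in pipeline_result.truth.islands:
            near = min(calls.values(), key=lambda c: abs(c.start - isl.start))
            assert abs(near.start - isl.start) <= cfg.flank
            assert abs(near.end - isl.end) <= cfg.flank
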