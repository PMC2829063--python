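import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pangei import codon
from pangei.codon import (RETAINED_FAMILIES, RSCU_CODONS, cai,
                          coa, composition_zscores, gc3, gc_tracks,
                          reference_weights, rscu_matrix)
from pangei.genome import Replicon, extract_cds_sequences
from pangei.simulate import SYN_FAMILIES


class TestRscu:
    def test_exactly_57_columns(self):
        m = rscu_matrix({"g": ["ATG", "TTT", "GGC"]})
        assert m.shape[1] == 57
        assert set(m.columns) == set(RSCU_CODONS)
        assert not set(m.columns) & {"TGT", "TGC", "AGA", "AGG", "TAA", "TAG", "TGA"}

    def test_uniform_family_usage_gives_rscu_one(self):
        m = rscu_matrix({"g": ["TTT", "TTC", "GGT", "GGC", "GGA", "GGG"]})
        assert m.loc["g", ["TTT", "TTC", "GGT", "GGC", "GGA", "GGG"]].eq(1.0).all()

    def test_phe_family_worked_example(self):
        m = rscu_matrix({"g": ["ATG", "TTT", "TTT", "TTC"]})
        assert m.loc["g", "TTT"] == pytest.approx(4 / 3)
        assert m.loc["g", "TTC"] == pytest.approx(2 / 3)

    def test_missing_family_recorded_and_zero(self):
        m = rscu_matrix({"g": ["TTT", "TTC"]})
        assert ("g", "G") in m.attrs["missing_families"]
        assert m.loc["g", list(RETAINED_FAMILIES["G"])].eq(0).all()

    @given(st.lists(st.sampled_from(sorted(RSCU_CODONS)), min_size=1, max_size=400))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_family_sums_property(self, codons):
        """RSCU values of any observed family sum to the family size."""
        m = rscu_matrix({"g": codons})
        present = set(codons)
        for aa, fam in RETAINED_FAMILIES.items():
            if present & set(fam):
                assert m.loc["g", list(fam)].sum() == pytest.approx(len(fam))


class TestCai:
    def test_preferred_codons_only_gives_one(self):
        ref = {"g1": ["TTT", "GGG", "GCA"] * 10}
        w = reference_weights(ref, ["g1"])
        assert cai(["TTT", "GGG", "GCA"], w) == pytest.approx(1.0)

    def test_duplication_invariance(self):
        ref = {"g1": ["TTT", "TTT", "TTC", "GGG"] * 5}
        w = reference_weights(ref, ["g1"])
        gene = ["TTT", "TTC", "GGG", "GGA"]
        assert cai(gene, w) == pytest.approx(cai(gene * 3, w))

    def test_two_family_hand_computed_geometric_mean(self):
        w = {"TTT": 1.0, "TTC": 0.5, "GGG": 1.0, "GGA": 0.25}
        assert cai(["TTT", "TTC"], w) == pytest.approx(np.sqrt(0.5))

    def test_met_trp_and_excluded_codons_uninformative(self):
        w = {"TTT": 0.5}
        # ATG/TGG and the Cys/Arg-duet codons must not affect the result
        assert cai(["ATG", "TGG", "TGT", "AGA", "TTT"], w) == pytest.approx(0.5)

    def test_no_informative_codons_is_error(self):
        with pytest.raises(ValueError):
            cai(["ATG", "TGG"], {"TTT": 1.0})


class TestGc3:
    @pytest.mark.parametrize("codons,expected", [
        (["GCG", "GCG"], 1.0),
        (["AAA", "AAA"], 0.0),
        (["ATG", "GAT", "GAC"], 2 / 3),
    ])
    def test_examples(self, codons, expected):
        assert gc3(codons) == pytest.approx(expected)

    def test_stop_codons_ignored(self):
        assert gc3(["GCG", "TAA"]) == 1.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            gc3(["TAA"])


class TestGcTracks:
    def test_homopolymer_g(self):
        t = gc_tracks(Replicon("r", 3000, seq="G" * 3000), window=1000)
        assert np.allclose(t.table["gc_deviation"], 0)
        assert (t.table["gc_skew"] == 1).all()

    def test_alternating_gc_has_zero_skew(self):
        t = gc_tracks(Replicon("r", 2000, seq="GC" * 1000), window=500)
        assert (t.table["gc_skew"] == 0).all()
        assert np.allclose(t.table["gc_deviation"], 0)

    def test_partial_last_window_and_weighted_mean_zero(self):
        seq = "G" * 1500 + "A" * 700
        t = gc_tracks(Replicon("r", 2200, seq=seq), window=1000)
        assert len(t.table) == 3
        widths = t.table["end"] - t.table["start"]
        assert float((t.table["gc_deviation"] * widths).sum()) == pytest.approx(0, abs=1e-9)

    def test_planted_island_windows_depressed(self, sim_genome):
        genome, truth = sim_genome
        t = gc_tracks(genome.replicons[0], window=1000).table
        isl = truth.islands[0]
        inside = t[(t["start"] >= isl.start) & (t["end"] <= isl.end)]
        assert inside["gc_deviation"].median() < -0.05

    def test_skew_range(self, sim_genome):
        genome, _ = sim_genome
        t = gc_tracks(genome.replicons[0]).table
        assert t["gc_skew"].between(-1, 1).all()


class TestZScores:
    def test_identical_genes_give_zero(self):
        genes = {f"g{i}": ["TTT", "GGG", "GCA"] * 4 for i in range(12)}
        w = reference_weights(genes, ["g0"])
        prof = composition_zscores(genes, w)
        assert np.allclose(prof["z_cai"], 0)
        assert np.allclose(prof["z_gc3"], 0)

    def test_order_invariance(self, sim_genome):
        genome, truth = sim_genome
        codons = extract_cds_sequences(genome)
        w = reference_weights(codons, truth.highly_expressed)
        p1 = composition_zscores(codons, w)
        shuffled = dict(reversed(list(codons.items())))
        p2 = composition_zscores(shuffled, w)
        assert np.allclose(p1.loc[p1.index, "z_gc3"], p2.loc[p1.index, "z_gc3"])

    def test_island_genes_strongly_negative(self, sim_genome):
        genome, truth = sim_genome
        codons = extract_cds_sequences(genome)
        w = reference_weights(codons, truth.highly_expressed)
        prof = composition_zscores(codons, w)
        island_ids = [g for isl in truth.islands for g in isl.gene_ids]
        assert prof.loc[island_ids, "z_gc3"].median() <= -2

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            composition_zscores({"g": ["TTT"]}, {"TTT": 1.0})


def _ca_oracle(x: np.ndarray, k: int):
    """Independent CA via eigendecomposition of the residual cross-products."""
    p = x / x.sum()
    r, c = p.sum(1), p.sum(0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    evals_r, evecs_r = np.linalg.eigh(s @ s.T)
    order = np.argsort(evals_r)[::-1]
    evals = evals_r[order][:k]
    u = evecs_r[:, order][:, :k]
    rows = u * np.sqrt(np.maximum(evals, 0)) / np.sqrt(r)[:, None]
    evals_c, evecs_c = np.linalg.eigh(s.T @ s)
    order_c = np.argsort(evals_c)[::-1]
    v = evecs_c[:, order_c][:, :k]
    cols = v * np.sqrt(np.maximum(evals_c[order_c][:k], 0)) / np.sqrt(c)[:, None]
    return rows, cols, evals, float((s ** 2).sum())


class TestCoa:
    def test_rank_one_matrix_has_zero_inertia(self):
        x = np.outer([1, 2, 3.0], [4, 1, 2, 3.0])
        res = coa(pd.DataFrame(x), n_axes=2)
        assert res.total_inertia == pytest.approx(0, abs=1e-12)

    def test_matches_eigendecomposition_oracle_up_to_sign(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.uniform(0.1, 5.0, size=(rng.integers(4, 9), rng.integers(3, 7)))
            k = 2
            res = coa(pd.DataFrame(x), n_axes=k)
            rows, cols, evals, total = _ca_oracle(x, k)
            assert res.total_inertia == pytest.approx(total, abs=1e-10)
            assert np.allclose(res.inertias, evals, atol=1e-8)
            for axis in range(k):
                for got, want in (
                        (res.row_coords.iloc[:, axis].to_numpy(), rows[:, axis]),
                        (res.col_coords.iloc[:, axis].to_numpy(), cols[:, axis])):
                    i = np.argmax(np.abs(got))
                    sign = np.sign(got[i] * want[i]) or 1.0
                    assert np.allclose(got, sign * want, atol=1e-8)

    def test_inertia_conservation_and_ordering(self, sim_genome):
        genome, _ = sim_genome
        codons = extract_cds_sequences(genome)
        sub = {k: codons[k] for k in list(codons)[:80]}
        m = rscu_matrix(sub)
        res = coa(m, n_axes=min(m.shape) - 1)
        assert (np.diff(res.inertias) <= 1e-12).all()
        assert res.inertias.sum() == pytest.approx(res.total_inertia, abs=1e-8)

    def test_two_codon_usage_classes_separate_on_axis_one(self, sim_genome):
        genome, truth = sim_genome
        codons = extract_cds_sequences(genome)
        island_ids = {g for isl in truth.islands for g in isl.gene_ids}
        m = rscu_matrix(codons)
        res = coa(m, n_axes=2)
        a1 = res.row_coords["axis1"]
        host = a1[~a1.index.isin(island_ids)]
        isl = a1[a1.index.isin(island_ids)]
        lo, hi = sorted([host.mean(), isl.mean()])
        # no overlap between the two classes on axis 1
        if host.mean() < isl.mean():
            assert host.max() < isl.min()
        else:
            assert isl.max() < host.min()

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            coa(pd.DataFrame([[0.0, 0.0], [1.0, 2.0]]))
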