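from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gicmp import metaprograms as mpx
from gicmp.factorization import NMFProgram


def _program(sample, k, f, genes):
    return NMFProgram(
        sample_id=sample,
        k=k,
        factor_index=f,
        genes=tuple(genes),
        weights=tuple(float(len(genes) - i) for i in range(len(genes))),
    )


def _family(prefix, n, size=50, jitter=0):
    """n near-identical programs built on one gene family."""
    base = [f"{prefix}{i:03d}" for i in range(size + jitter * n)]
    out = []
    for j in range(n):
        genes = base[j * jitter : j * jitter + size]
        out.append(_program(f"S{j}", 4 + j % 3, j, genes))
    return out


class TestJaccard:
    def test_identical_and_partial_overlap(self):
        g = [f"g{i}" for i in range(50)]
        h = [f"h{i}" for i in range(50)]
        progs = [
            _program("S0", 4, 0, g),
            _program("S1", 4, 0, g),
            _program("S2", 4, 0, g[:25] + h[:25]),
        ]
        J = mpx.jaccard_matrix(progs)
        assert J.iloc[0, 1] == 1.0
        assert J.iloc[0, 2] == pytest.approx(25 / 75)
        assert np.allclose(np.diag(J), 1.0)
        assert np.allclose(J, J.T)


class TestClustering:
    def test_two_disjoint_families_give_pure_clusters(self):
        fam_a = _family("a", 5, jitter=2)
        fam_b = _family("b", 5, jitter=2)
        mps = mpx.cluster_metaprograms(fam_a + fam_b, n_mps=2)
        assert len(mps) == 2
        for mp in mps:
            prefixes = {m.genes[0][0] for m in mp.member_programs}
            assert len(prefixes) == 1

    def test_as_many_clusters_as_programs(self):
        progs = _family("a", 3, jitter=30)
        mps = mpx.cluster_metaprograms(progs, n_mps=3)
        assert sorted(len(m) for m in mps) == [1, 1, 1]

    def test_partition_invariant_to_program_order(self):
        rng = np.random.default_rng(0)
        progs = _family("a", 4, jitter=5) + _family("b", 4, jitter=5)
        base = mpx.cluster_metaprograms(progs, n_mps=2)
        base_sets = sorted(
            frozenset(p.key for p in mp.member_programs) for mp in base
        )
        for _ in range(3):
            perm = [progs[i] for i in rng.permutation(len(progs))]
            mps = mpx.cluster_metaprograms(perm, n_mps=2)
            assert sorted(
                frozenset(p.key for p in mp.member_programs) for mp in mps
            ) == base_sets

    def test_partition_covers_every_program_once(self):
        progs = _family("a", 6, jitter=4) + _family("b", 3, jitter=4)
        mps = mpx.cluster_metaprograms(progs, n_mps=3)
        keys = [p.key for mp in mps for p in mp.member_programs]
        assert sorted(keys) == sorted(p.key for p in progs)

    def test_too_many_clusters_requested(self):
        with pytest.raises(ValueError, match="n_mps"):
            mpx.cluster_metaprograms(_family("a", 3, jitter=30), n_mps=5)

    def test_curation_merge_joins_clusters(self):
        progs = _family("a", 4, jitter=2) + _family("b", 4, jitter=2)
        plain = mpx.cluster_metaprograms(progs, n_mps=2)
        labels = sorted({1, 2})
        merged = mpx.cluster_metaprograms(
            progs, n_mps=2, curation={"merge": [labels]}
        )
        assert len(merged) == 1
        assert len(merged[0].member_programs) == 8
        assert len(plain) == 2


class TestConsensus:
    def test_identical_members_keep_signature_order(self):
        g = [f"g{i:02d}" for i in range(50)]
        mp = mpx.MetaProgram("MP1", [_program("S0", 4, 0, g), _program("S1", 4, 0, g)])
        assert mpx.consensus_signature(mp) == g

    def test_single_member_returns_its_signature(self):
        g = [f"g{i:02d}" for i in range(50)]
        mp = mpx.MetaProgram("MP1", [_program("S0", 4, 0, g)])
        assert mpx.consensus_signature(mp) == g

    def test_more_frequent_gene_outranks_rarer(self):
        a = [f"a{i:02d}" for i in range(5)]
        members = [
            _program("S0", 4, 0, ["shared3", "shared2"] + a[:3]),
            _program("S1", 4, 0, ["shared3", "shared2"] + a[:3]),
            _program("S2", 4, 0, ["shared3", a[3], a[0], a[1], a[2]]),
            _program("S3", 4, 0, [a[4], a[3], a[0], a[1], a[2]]),
        ]
        mp = mpx.MetaProgram("MP1", members)
        sig = mpx.consensus_signature(mp, size=10)
        assert sig.index("shared3") < sig.index("shared2")


class TestAbundance:
    def test_observed_equal_expected_gives_zero(self):
        table = pd.DataFrame({"EC": [4, 4], "GC": [4, 4]}, index=["MP1", "MP2"])
        out = mpx.abundance(table)
        assert np.allclose(out["A"], 0.0)
        assert not out["significant"].any()
        assert (out["level"] == "low").all()

    def test_printed_formula_example(self):
        # observed 3, expected 1 -> A = log2(4/2) = 1 -> medium
        table = pd.DataFrame({"c1": [3, 1], "c2": [1, 11]}, index=["MP1", "MP2"])
        out = mpx.abundance(table).set_index(["mp_id", "cancer_type"])
        row = out.loc[("MP1", "c1")]
        assert row["expected"] == pytest.approx(1.0)
        assert row["A"] == pytest.approx(1.0)
        assert row["level"] == "medium"

    def test_absence_level_iff_zero_observed(self):
        table = pd.DataFrame({"c1": [0, 5], "c2": [3, 2]}, index=["MP1", "MP2"])
        out = mpx.abundance(table)
        absent = out[out["observed"] == 0]
        assert (absent["level"] == "absence").all()
        assert (out[out["observed"] > 0]["level"] != "absence").all()

    def test_observed_sums_match_cancer_type_totals(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            rng.integers(0, 20, size=(5, 3)),
            index=[f"MP{i}" for i in range(5)],
            columns=["EC", "GC", "CRC"],
        )
        out = mpx.abundance(table)
        sums = out.groupby("cancer_type")["observed"].sum()
        for ct in table.columns:
            assert sums[ct] == table[ct].sum()

    def test_A_recomputes_from_printed_formula(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            rng.integers(0, 15, size=(4, 3)),
            index=[f"M{i}" for i in range(4)],
            columns=["EC", "GC", "CRC"],
        )
        out = mpx.abundance(table)
        recomputed = np.log2((out["observed"] + 1) / (out["expected"] + 1))
        assert np.allclose(out["A"], recomputed, atol=1e-12)

    def test_all_zero_table_rejected(self):
        table = pd.DataFrame({"c1": [0], "c2": [0]}, index=["MP1"])
        with pytest.raises(ValueError):
            mpx.abundance(table)


class TestHypergeometricEnrichment:
    def test_identical_set_is_extremely_enriched(self):
        universe = [f"g{i}" for i in range(500)]
        sig = universe[:30]
        out = mpx.enrich_hypergeometric(sig, {"hit": sig, "other": universe[100:150]}, universe)
        hit = out.set_index("gene_set").loc["hit"]
        assert hit["p"] < 1e-20
        assert bool(hit["significant"])

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(100)]
        out = mpx.enrich_hypergeometric(
            universe[:10], {"disjoint": universe[50:60]}, universe
        )
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_exhaustive_pmf_on_small_universe(self):
        # hypergeometric tail by explicit pmf summation on a 20-gene universe
        universe = [f"g{i}" for i in range(20)]
        sig = universe[:7]
        gene_set = universe[4:12]  # K=8, overlap k=3
        M, N, K, k = 20, 7, 8, 3
        pmf = lambda x: comb(K, x) * comb(M - K, N - x) / comb(M, N)
        expected = sum(pmf(x) for x in range(k, min(K, N) + 1))
        out = mpx.enrich_hypergeometric(sig, {"s": gene_set}, universe)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            mpx.enrich_hypergeometric(["g1"], {"s": ["g1"]}, [])

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bh_adjustment_is_monotone_in_sorted_p(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"g{i}" for i in range(60)]
        sets = {
            f"s{i}": list(rng.choice(universe, size=rng.integers(3, 15), replace=False))
            for i in range(12)
        }
        out = mpx.enrich_hypergeometric(universe[:12], sets, universe)
        srt = out.sort_values("p")
        assert (srt["p_adj"].diff().dropna() >= -1e-12).all()
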