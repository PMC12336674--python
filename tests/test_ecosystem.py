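import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from gicmp import ecosystem as eco
from gicmp import simulate as sim
from gicmp.simulate import generate_lineage_cells

PARENTS = {**sim.DEFAULT_SUBTYPE_PARENTS, "Epithelial": "Epithelial"}


def _cells(rows):
    """rows: list of (sample, subtype, n)"""
    recs = []
    for sample, subtype, n in rows:
        for i in range(n):
            recs.append({"sample": sample, "subtype": subtype})
    return pd.DataFrame(recs, index=[f"c{i}" for i in range(len(recs))])


class TestComposition:
    def test_relative_abundance_is_subtype_over_major(self):
        cells = _cells([("S0", "CD4_T", 30), ("S0", "CD8_T", 30)])
        comp = eco.composition(cells, PARENTS, min_cells_per_sample=10)
        assert comp.relative.loc["S0", "CD4_T"] == pytest.approx(0.5)

    def test_small_compartment_excluded(self):
        cells = _cells([("S0", "CD4_T", 29), ("S0", "CD8_T", 20), ("S0", "Macrophage", 60)])
        comp = eco.composition(cells, PARENTS)  # T total 49 < 50
        assert np.isnan(comp.relative.loc["S0", "CD4_T"])
        assert comp.relative.loc["S0", "Macrophage"] == pytest.approx(1.0)

    def test_relative_abundances_sum_to_one_per_major(self, default_cohort):
        adata, _, _ = default_cohort
        comp = eco.composition(adata.obs, PARENTS)
        for major in ("T", "Myeloid", "B", "Stromal"):
            sts = [s for s, p in PARENTS.items() if p == major]
            sums = comp.relative[sts].sum(axis=1, min_count=len(sts)).dropna()
            assert np.allclose(sums, 1.0)

    def test_single_subtype_major_scales_to_zero(self):
        cells = _cells([("S0", "Macrophage", 60), ("S1", "Macrophage", 80)])
        comp = eco.composition(cells, PARENTS)
        assert (comp.relative["Macrophage"] == 1.0).all()
        assert (comp.scaled["Macrophage"] == 0.0).all()

    def test_orphan_subtype_is_an_error(self):
        cells = _cells([("S0", "Mystery", 60)])
        with pytest.raises(ValueError, match="Mystery"):
            eco.composition(cells, PARENTS)


class TestNicheClustering:
    def test_recovers_planted_composition_groups(self, default_cohort):
        adata, gt, _ = default_cohort
        comp = eco.composition(adata.obs, PARENTS)
        niche = eco.cluster_niches(comp, None, eco.NicheConfig(n_groups=2))
        truth = pd.Series(gt.sample_group).reindex(niche.index)
        assert adjusted_rand_score(truth, niche) >= 0.8

    def test_duplicated_sample_joins_same_group(self, default_cohort):
        adata, _, _ = default_cohort
        obs = adata.obs.copy()
        clone = obs[obs["sample"] == "S00"].copy()
        clone["sample"] = "S99"
        clone.index = [f"dup{i}" for i in range(len(clone))]
        comp = eco.composition(pd.concat([obs, clone]), PARENTS)
        niche = eco.cluster_niches(comp, None, eco.NicheConfig(n_groups=2))
        assert niche["S99"] == niche["S00"]

    def test_thin_subtype_excluded_from_features(self):
        # groups differ ONLY in a 99-cell subtype; with the default
        # min_cells_per_subtype=100 it cannot drive the clustering
        rng = np.random.default_rng(0)
        rows = []
        for si in range(8):
            rows.append((f"S{si}", "Epithelial", 60))
            rows.append((f"S{si}", "CD4_T", 60 + int(rng.integers(0, 3))))
            rows.append((f"S{si}", "CD8_T", 60 + int(rng.integers(0, 3))))
            if si < 4:
                rows.append((f"S{si}", "DC", 24))  # 96 cells total < 100
        cells = _cells(rows)
        comp = eco.composition(cells, PARENTS, min_cells_per_sample=10)
        cfg = eco.NicheConfig(n_groups=2, min_cells_per_sample=10)
        niche = eco.cluster_niches(comp, None, cfg)
        split = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=[f"S{i}" for i in range(8)])
        assert adjusted_rand_score(split.reindex(niche.index), niche) < 0.5

        relaxed = eco.NicheConfig(n_groups=2, min_cells_per_sample=10, min_cells_per_subtype=10)
        niche2 = eco.cluster_niches(comp, None, relaxed)
        assert adjusted_rand_score(split.reindex(niche2.index), niche2) == 1.0

    def test_sample_order_invariance(self, default_cohort):
        adata, _, _ = default_cohort
        obs = adata.obs
        comp1 = eco.composition(obs, PARENTS)
        comp2 = eco.composition(obs.iloc[::-1], PARENTS)
        n1 = eco.cluster_niches(comp1, None, eco.NicheConfig(n_groups=2))
        n2 = eco.cluster_niches(comp2, None, eco.NicheConfig(n_groups=2))
        assert adjusted_rand_score(n1.reindex(n2.index), n2) == 1.0

    def test_fewer_samples_than_groups_rejected(self):
        cells = _cells([("S0", "Epithelial", 60), ("S0", "CD4_T", 60)])
        comp = eco.composition(cells, PARENTS)
        with pytest.raises(ValueError, match="n_groups"):
            eco.cluster_niches(comp, None, eco.NicheConfig(n_groups=3))


@pytest.fixture(scope="module")
def refs():
    return eco.make_synthetic_reference()


class TestLineageInference:
    def test_self_match_assigns_same_cancer_rule(self, refs):
        cells, labels = generate_lineage_cells(
            refs.profiles[["Gastric chief"]], 3, noise_sd=0.01, seed=1
        )
        res = eco.infer_lineages(cells, "GC", refs)
        assert (res["lineage"] == "Gastric chief").all()
        assert (res["rule"] == "same-cancer").all()
        assert (res["pcc"] > 0.95).all()

    def test_gastric_cell_matching_intestinal_profile_uses_rule_two(self, refs):
        cells, _ = generate_lineage_cells(
            refs.profiles[["Intestinal enterocyte"]], 3, noise_sd=0.05, seed=2
        )
        res = eco.infer_lineages(cells, "GC", refs)
        assert (res["lineage"] == "Intestinal enterocyte").all()
        assert (res["rule"] == "other-GIC").all()

    def test_background_cells_fall_to_non_gi_rule(self, refs):
        non_gi = [l for l in refs.profiles.columns if not refs.is_gic(l)]
        cells, _ = generate_lineage_cells(
            refs.profiles, 0, noise_sd=0.2, seed=3,
            n_background_cells=40, background_mixture=non_gi,
        )
        res = eco.infer_lineages(cells, "GC", refs)
        assert (res["lineage"] == "Non-GI").mean() >= 0.95
        assert (res["rule"] == "non-GI").mean() >= 0.9

    def test_accuracy_high_at_low_noise_and_degrades_with_noise(self, refs):
        accs = []
        for sd in (0.2, 0.8, 2.5):
            cells, labels = generate_lineage_cells(refs.profiles, 12, sd, seed=4)
            tissue2cancer = {"oesophageal": "EC", "gastric": "GC", "intestinal": "CRC"}
            ct = labels.map(
                lambda l: tissue2cancer.get(refs.tissue.get(l, ""), "GC")
            )
            res = eco.infer_lineages(cells, ct, refs)
            expected = labels.map(lambda l: l if refs.is_gic(l) else "Non-GI")
            accs.append(float((res["lineage"] == expected).mean()))
        assert accs[0] >= 0.95
        assert accs[0] >= accs[1] >= accs[2]

    def test_depth_scaling_before_normalization_preserves_pcc(self, refs):
        cells, labels = generate_lineage_cells(refs.profiles, 3, 0.2, seed=5)
        res1 = eco.infer_lineages(cells, "GC", refs)
        res2 = eco.infer_lineages(cells * 11.0, "GC", refs)
        assert np.allclose(res1["pcc"], res2["pcc"])

    def test_no_gene_overlap_is_an_error(self, refs):
        cells = pd.DataFrame(
            np.ones((2, 5)), columns=[f"other{i}" for i in range(5)]
        )
        with pytest.raises(ValueError, match="overlap"):
            eco.infer_lineages(cells, "GC", refs)


class TestMetaplasia:
    def _assignments(self, props, refs, cancer="GC", n=40, seed=0):
        rng = np.random.default_rng(seed)
        frames, samples = [], []
        gi_lin = ["Gastric chief", "Gastric parietal"]
        int_lin = ["Intestinal enterocyte", "Intestinal goblet"]
        for si, p in enumerate(props):
            n_int = round(p * n)
            lins = [int_lin[i % 2] for i in range(n_int)] + [
                gi_lin[i % 2] for i in range(n - n_int)
            ]
            rows = [
                np.clip(
                    refs.profiles[l].to_numpy() + rng.normal(0, 0.2, refs.profiles.shape[0]),
                    0,
                    None,
                )
                for l in lins
            ]
            idx = [f"S{si}_c{i}" for i in range(n)]
            frames.append(
                pd.DataFrame(rows, index=idx, columns=refs.profiles.index)
            )
            samples += [f"S{si}"] * n
        expr = pd.concat(frames)
        res = eco.infer_lineages(expr, cancer, refs)
        return res, pd.Series(samples, index=expr.index)

    def test_bimodal_cohort_split_exactly(self, refs):
        props = [0.05] * 4 + [0.6] * 4
        res, sample_of = self._assignments(props, refs, seed=6)
        out = eco.classify_metaplasia(res, refs, sample_of, threshold="auto")
        expected = ["non-metaplastic"] * 4 + ["metaplastic"] * 4
        assert list(out.loc[[f"S{i}" for i in range(8)], "group"]) == expected

    def test_zero_intestinal_sample_never_metaplastic(self, refs):
        res, sample_of = self._assignments([0.0, 0.5], refs, seed=7)
        out = eco.classify_metaplasia(res, refs, sample_of, threshold=0.01)
        assert out.loc["S0", "group"] == "non-metaplastic"

    def test_threshold_one_requires_pure_intestinal(self, refs):
        res, sample_of = self._assignments([0.5, 1.0], refs, seed=8)
        out = eco.classify_metaplasia(res, refs, sample_of, threshold=1.0)
        assert out.loc["S0", "group"] == "non-metaplastic"
        assert out.loc["S1", "group"] == "metaplastic"

    def test_oesophageal_counts_gastric_and_intestinal(self, refs):
        # EC sample whose cells match gastric lineages -> metaplastic
        res, sample_of = self._assignments([0.0], refs, cancer="EC", seed=9)
        out = eco.classify_metaplasia(res, refs, sample_of, threshold=0.5)
        assert out.loc["S0", "metaplastic_proportion"] == pytest.approx(1.0)
        assert out.loc["S0", "group"] == "metaplastic"
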