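import numpy as np
import pandas as pd
import pytest

from admixcnv import (
    ManifestEntry,
    SampleManifest,
    SimConfig,
    build_cnvrs,
    classify_aic,
    code_biallelic,
    fst_matrix,
    og_specific_cnvrs,
    pairwise_fst,
    simulate_dataset,
)
from admixcnv.popgen_stats import aic_frequency_table

from conftest import make_segment


def geno_from_states(states_a, states_b):
    """Genotypes for two populations from per-population state matrices."""
    a = np.asarray(states_a)
    b = np.asarray(states_b)
    df = pd.DataFrame(
        np.hstack([a, b]),
        index=[f"L{i}" for i in range(a.shape[0])],
        columns=[f"A{i}" for i in range(a.shape[1])]
        + [f"B{i}" for i in range(b.shape[1])],
    )
    manifest = SampleManifest(
        [ManifestEntry(f"A{i}", "popA", "other") for i in range(a.shape[1])]
        + [ManifestEntry(f"B{i}", "popB", "other") for i in range(b.shape[1])]
    )
    return code_biallelic(df), manifest


def brute_force_theta(geno, manifest, pop_a, pop_b):
    """Independent scalar-loop Weir-Cockerham variance components."""
    idx = {s: i for i, s in enumerate(geno.samples)}
    groups = [
        [idx[s] for s in manifest.samples_in(p)] for p in (pop_a, pop_b)
    ]
    sum_a = sum_b = sum_c = 0.0
    r = 2
    for l in range(geno.n_loci):
        pairs = [
            [
                (int(geno.a1[l, i]), int(geno.a2[l, i]))
                for i in members if geno.a1[l, i] >= 0
            ]
            for members in groups
        ]
        n1, n2 = len(pairs[0]), len(pairs[1])
        if n1 < 2 or n2 < 2:
            continue
        for allele in (0, 1, 2):
            dos1 = [(x == allele) + (y == allele) for x, y in pairs[0]]
            dos2 = [(x == allele) + (y == allele) for x, y in pairs[1]]
            if sum(dos1) + sum(dos2) == 0:
                continue
            p1 = sum(dos1) / (2 * n1)
            p2 = sum(dos2) / (2 * n2)
            h1 = sum(1 for d in dos1 if d == 1) / n1
            h2 = sum(1 for d in dos2 if d == 1) / n2
            n_bar = (n1 + n2) / r
            n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
            p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
            s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / (
                (r - 1) * n_bar
            )
            h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
            inner = p_bar * (1 - p_bar) - s2 * (r - 1) / r
            a = (n_bar / n_c) * (s2 - (inner - h_bar / 4) / (n_bar - 1))
            b = (n_bar / (n_bar - 1)) * (
                inner - h_bar * (2 * n_bar - 1) / (4 * n_bar)
            )
            c = h_bar / 2
            sum_a += a
            sum_b += b
            sum_c += c
    return sum_a / (sum_a + sum_b + sum_c)


class TestPairwiseFst:
    def test_panmictic_populations_near_zero(self):
        # two independent samples drawn from one state distribution
        rng = np.random.default_rng(1)
        a = rng.choice([0, 1, 2, 3, 4], size=(200, 20))
        b = rng.choice([0, 1, 2, 3, 4], size=(200, 20))
        geno, manifest = geno_from_states(a, b)
        res = pairwise_fst(geno, manifest, "popA", "popB")
        assert abs(res.theta) < 0.02

    def test_fixed_difference_gives_exactly_one(self):
        a = np.zeros((50, 10), dtype=int)       # all 0/0
        b = np.full((50, 10), 4, dtype=int)     # all 2/2
        geno, manifest = geno_from_states(a, b)
        res = pairwise_fst(geno, manifest, "popA", "popB")
        assert res.theta == 1.0

    def test_matches_independent_variance_components(self):
        """Small worked table vs a scalar-loop oracle, to 1e-12."""
        a = np.array([[0, 1, 1, 2], [2, 3, 4, 2]])
        b = np.array([[1, 2, 2, 2], [4, 4, 3, 3]])
        geno, manifest = geno_from_states(a, b)
        ours = pairwise_fst(geno, manifest, "popA", "popB").theta
        oracle = brute_force_theta(geno, manifest, "popA", "popB")
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(3):
            a = rng.choice([0, 1, 2, 3, 4], size=(6, 5))
            b = rng.choice([0, 1, 2, 3, 4], size=(6, 5))
            geno, manifest = geno_from_states(a, b)
            ours = pairwise_fst(geno, manifest, "popA", "popB").theta
            oracle = brute_force_theta(geno, manifest, "popA", "popB")
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(2)
        a = rng.choice([0, 1, 2], size=(50, 8))
        b = rng.choice([2, 3, 4], size=(50, 8))
        geno, manifest = geno_from_states(a, b)
        ab = pairwise_fst(geno, manifest, "popA", "popB").theta
        ba = pairwise_fst(geno, manifest, "popB", "popA").theta
        assert ab == ba

    def test_single_sample_population_rejected(self):
        geno, manifest = geno_from_states(np.array([[1]]), np.array([[3]]))
        with pytest.raises(ValueError, match=">= 2"):
            pairwise_fst(geno, manifest, "popA", "popB")

    def test_monomorphic_table_rejected(self):
        a = np.full((5, 4), 2, dtype=int)
        geno, manifest = geno_from_states(a, a)
        with pytest.raises(ValueError, match="polymorphic"):
            pairwise_fst(geno, manifest, "popA", "popB")

    @pytest.mark.parametrize("theta_true", [0.05, 0.16, 0.3])
    def test_balding_nichols_recovery(self, theta_true):
        cfg = SimConfig(
            n_loci=500, theta=theta_true, seed=0,
            populations=(("A", "ancestral_indian", 25),
                         ("B", "ancestral_african", 25),
                         ("OG", "admixed", 2)),
        )
        ds = simulate_dataset(cfg)
        res = pairwise_fst(code_biallelic(ds.states), ds.manifest, "A", "B")
        assert abs(res.theta - theta_true) <= 0.03

    def test_label_permutation_null_centered_on_zero(self):
        rng = np.random.default_rng(4)
        states = rng.choice([0, 1, 2, 3, 4], size=(100, 24))
        samples = [f"S{i}" for i in range(24)]
        df = pd.DataFrame(states, index=[f"L{i}" for i in range(100)],
                          columns=samples)
        geno = code_biallelic(df)
        thetas = []
        for _ in range(200):
            perm = rng.permutation(samples)
            manifest = SampleManifest(
                [ManifestEntry(s, "popA" if i < 12 else "popB", "other")
                 for i, s in enumerate(perm)]
            )
            thetas.append(pairwise_fst(geno, manifest, "popA", "popB").theta)
        assert abs(np.mean(thetas)) < 0.01


class TestFstMatrix:
    def test_symmetric_zero_diagonal(self, noisefree_dataset):
        ds = noisefree_dataset
        mat = fst_matrix(code_biallelic(ds.states.iloc[:80]), ds.manifest)
        v = mat.values.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0.0)


class TestClassifyAic:
    def test_stated_rule_examples(self):
        table = pd.DataFrame(
            {"f_og": [0.50, 0.30, 0.40], "f_ind": [0.48, 0.00, 0.38],
             "f_afr": [0.05, 0.00, 0.42]},
            index=["R1", "R2", "R3"],
        )
        out = classify_aic(table)
        assert out.loc["R1", "aic_class"] == "indian_close"
        assert out.loc["R2", "aic_class"] == "unique"
        assert out.loc["R3", "aic_class"] == "unassigned"

    def test_african_close(self):
        table = pd.DataFrame({"f_og": [0.40], "f_ind": [0.05], "f_afr": [0.35]})
        assert classify_aic(table)["aic_class"].iloc[0] == "african_close"

    def test_multiple_african_columns_averaged(self):
        table = pd.DataFrame(
            {"f_og": [0.40], "f_ind": [0.05],
             "f_afr_yri": [0.30], "f_afr_lwk": [0.40]}
        )
        out = classify_aic(table)
        assert out["f_afr"].iloc[0] == pytest.approx(0.35)
        assert out["aic_class"].iloc[0] == "african_close"

    def test_only_absolute_differences_matter(self):
        up = pd.DataFrame({"f_og": [0.6], "f_ind": [0.55], "f_afr": [0.1]})
        down = pd.DataFrame({"f_og": [0.4], "f_ind": [0.45], "f_afr": [0.9]})
        assert (classify_aic(up)["aic_class"] == classify_aic(down)["aic_class"]).all()

    def test_frequency_outside_unit_interval_rejected(self):
        table = pd.DataFrame({"f_og": [1.2], "f_ind": [0.1], "f_afr": [0.1]})
        with pytest.raises(ValueError, match="outside"):
            classify_aic(table)

    def test_every_row_gets_exactly_one_class(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {"f_og": rng.random(50), "f_ind": rng.random(50),
             "f_afr": rng.random(50)}
        )
        out = classify_aic(table)
        assert out["aic_class"].isin(
            ["indian_close", "african_close", "unique", "unassigned"]
        ).all()


class TestOgSpecific:
    def _cnvrs(self, tiny_manifest, carriers_by_region):
        segs = []
        for j, carriers in enumerate(carriers_by_region):
            for s in carriers:
                segs.append(
                    make_segment(sample_id=s, start=j * 10_000,
                                 end=j * 10_000 + 5_000)
                )
        return build_cnvrs(segs, tiny_manifest, min_freq=0.0)

    def test_specific_and_private_split(self, tiny_manifest):
        # region 0: admixed only; region 1: admixed + ancestral; S5 is admixed
        cnvrs = self._cnvrs(tiny_manifest, [["S5"], ["S5", "S1"]])
        specific, private = og_specific_cnvrs(cnvrs, tiny_manifest, "OG")
        assert [cnvrs.by_id(i).start for i in specific] == [0]
        assert private == specific

    def test_ancestral_only_region_in_neither_list(self, tiny_manifest):
        cnvrs = self._cnvrs(tiny_manifest, [["S3"]])
        specific, private = og_specific_cnvrs(cnvrs, tiny_manifest, "OG")
        assert specific == [] and private == []

    def test_private_subset_of_specific(self, tiny_manifest):
        # 'other'-role carrier keeps the region specific but not private
        from admixcnv import SampleManifest
        manifest = SampleManifest(
            tiny_manifest.entries + [ManifestEntry("S6", "CEU", "other")]
        )
        segs = [make_segment(sample_id="S5", start=0, end=5_000),
                make_segment(sample_id="S6", start=0, end=5_000)]
        cnvrs = build_cnvrs(segs, manifest, min_freq=0.0)
        specific, private = og_specific_cnvrs(cnvrs, manifest, "OG")
        assert len(specific) == 1 and private == []
        assert set(private) <= set(specific)

    def test_unknown_population_rejected(self, tiny_manifest):
        cnvrs = self._cnvrs(tiny_manifest, [["S5"]])
        with pytest.raises(KeyError):
            og_specific_cnvrs(cnvrs, tiny_manifest, "NOPE")


class TestAicFrequencyTable:
    def test_gain_loss_regions_excluded(self, noisefree_dataset, kept_segments):
        ds = noisefree_dataset
        cnvrs = build_cnvrs(kept_segments, ds.manifest)
        table = aic_frequency_table(cnvrs, ds.manifest)
        classes = {c.id: c.cnvr_class for c in cnvrs.cnvrs}
        assert all(classes[i] != "gain_loss" for i in table.index)
        assert set(table.columns) >= {"f_og", "f_ind", "f_afr"}

    def test_frequencies_come_from_matching_class_matrix(self, noisefree_dataset,
                                                         kept_segments):
        ds = noisefree_dataset
        cnvrs = build_cnvrs(kept_segments, ds.manifest)
        table = aic_frequency_table(cnvrs, ds.manifest)
        for cnvr_id, row in table.iterrows():
            freq = cnvrs.del_freq if row["cnvr_class"] == "del" else cnvrs.dup_freq
            assert row["f_og"] == freq.loc[cnvr_id, "OG"]
            assert row["f_ind"] == freq.loc[cnvr_id, "IND"]
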