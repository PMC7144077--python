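import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_gm
from polykaryo.io_formats import MISSING, QMatrix
from polykaryo.popgen import (
    allele_frequencies,
    amova_phipt,
    classify_admixture,
    filter_variants,
    fst_scan,
    gene_diversity,
    genotype_squared_distances,
    minor_allele_catalog,
    nei_da_distance,
    phipt_from_distances,
    pic,
)
from polykaryo.simulate import (
    GenotypeSimConfig,
    simulate_genotypes,
)


def freq_frame(p_alt):
    p_alt = np.asarray(p_alt, dtype=float)
    return pd.DataFrame(
        {
            "p_ref": 1 - p_alt,
            "p_alt": p_alt,
            "n_called": np.full(len(p_alt), 10),
            "missing_fraction": 0.0,
            "hom_ref_fraction": 0.0,
            "hom_alt_fraction": 0.0,
        }
    )


class TestDiversity:
    def test_he_pic_maxima_at_balanced_frequencies(self):
        f = freq_frame([0.5])
        assert gene_diversity(f).iloc[0] == pytest.approx(0.500, abs=1e-12)
        assert pic(f).iloc[0] == pytest.approx(0.375, abs=1e-12)

    def test_monomorphic_locus_zero(self):
        f = freq_frame([0.0, 1.0])
        assert (gene_diversity(f) == 0).all()
        assert (pic(f) == 0).all()

    def test_rare_allele_values_match_hand_evaluation(self):
        # He at p ~ 1%: 2pq; PIC: He - 2 p^2 q^2
        f = freq_frame([0.0105, 0.01])
        assert gene_diversity(f).iloc[0] == pytest.approx(
            2 * 0.0105 * 0.9895, abs=1e-12
        )
        assert pic(f).iloc[1] == pytest.approx(
            1 - 0.01**2 - 0.99**2 - 2 * 0.01**2 * 0.99**2, abs=1e-12
        )
        # the biallelic caps bracket these: 0.021 <= He <= 0.5 band shape
        assert gene_diversity(f).iloc[0] == pytest.approx(0.0208, abs=5e-4)
        assert pic(f).iloc[1] == pytest.approx(0.0196, abs=5e-5)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_brute_force_oracle_and_ordering(self, p_alt):
        """He and PIC match direct evaluation of their defining sums."""
        freqs = np.array([1 - p_alt, p_alt])
        he_direct = 1.0 - np.sum(freqs**2)
        pic_direct = he_direct - sum(
            2 * freqs[i] ** 2 * freqs[j] ** 2
            for i in range(2)
            for j in range(i + 1, 2)
        )
        f = freq_frame([p_alt])
        assert gene_diversity(f).iloc[0] == pytest.approx(he_direct, abs=1e-12)
        assert pic(f).iloc[0] == pytest.approx(pic_direct, abs=1e-12)
        assert pic(f).iloc[0] <= gene_diversity(f).iloc[0] + 1e-15

    def test_zero_call_locus_undefined(self):
        gm = make_gm([[MISSING, MISSING], [0, 1]])
        freq = allele_frequencies(gm)
        assert np.isnan(gene_diversity(freq).iloc[0])
        assert np.isnan(pic(freq).iloc[0])


class TestFilter:
    def _toy(self):
        # 10 loci x 10 samples: loci 0-1 indels; locus 2 30% missing;
        # locus 3 monomorphic (below any MAF floor); rest clean and common
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(10, 10))
        calls[2, :3] = MISSING
        calls[3, :] = 0
        # ensure other loci are common and well called
        calls[4:, 0] = 1
        is_indel = [True, True] + [False] * 8
        return make_gm(calls, is_indel=is_indel)

    def test_toy_counts(self):
        gm = self._toy()
        out = filter_variants(gm)
        assert out.n_loci == 6

    def test_identity_when_disabled(self):
        gm = self._toy()
        out = filter_variants(gm, maf_min=0.0, max_missing=1.0, drop_indels=False)
        # maf_min=0 still drops strictly-zero-MAF loci per the strict rule
        assert out.n_loci == 9
        out2 = filter_variants(gm, maf_min=-1, max_missing=1.0, drop_indels=False)
        assert out2.n_loci == 10

    def test_maf_strictness_at_boundary(self):
        # 50 diploid samples: one het -> MAF exactly 0.01 -> dropped (strict >)
        calls = np.zeros((2, 50), dtype=np.int8)
        calls[0, 0] = 1
        calls[1, :2] = 1  # MAF 0.02 -> kept
        gm = make_gm(calls)
        out = filter_variants(gm)
        assert out.n_loci == 1 and out.variants["pos"].iloc[0] == 20

    def test_idempotent_and_order_independent(self):
        gm = self._toy()
        once = filter_variants(gm)
        twice = filter_variants(once)
        assert once.variants.equals(twice.variants)
        rng = np.random.default_rng(1)
        perm = rng.permutation(gm.n_loci)
        gm_shuffled = make_gm(
            gm.calls[perm],
            is_indel=list(gm.variants["is_indel"].to_numpy()[perm]),
        )
        out_shuffled = filter_variants(gm_shuffled)
        kept = set(map(tuple, once.variants[["pos"]].to_numpy()))
        # compare by original row content (calls), order-free
        assert sorted(map(tuple, filter_variants(gm).calls.tolist())) == sorted(
            map(tuple, out_shuffled.calls.tolist())
        )

    def test_filter_log_records_order(self):
        log = []
        filter_variants(self._toy(), log=log)
        assert "missing" in log[1] and "MAF" in log[2] and "indel" in log[3]


class TestNeiDistance:
    def test_identical_homozygotes_zero(self):
        gm = make_gm([[0, 0], [2, 2], [0, 0]])
        d = nei_da_distance(gm)
        assert d.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_homozygotes_one(self):
        gm = make_gm([[0, 2], [0, 2], [2, 0]])
        d = nei_da_distance(gm)
        assert d.data[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_hom_vs_het_single_locus(self):
        gm = make_gm([[2, 1]])
        d = nei_da_distance(gm)
        assert d.data[0, 1] == pytest.approx(1 - np.sqrt(0.5), abs=1e-12)

    def test_missing_loci_skipped_pairwise(self):
        gm = make_gm([[0, MISSING], [0, 0], [2, 2]])
        d = nei_da_distance(gm)
        assert d.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_no_shared_loci_error(self):
        gm = make_gm([[0, MISSING], [MISSING, 0]])
        with pytest.raises(ValueError, match="no shared called loci"):
            nei_da_distance(gm)


class TestAmova:
    def test_hand_computed_components(self, two_pop_gm):
        """PhiPT on the 2x2 toy equals the AMOVA worked out by hand:
        SS_total = 6, SS_within = 1, n0 = 2, sigma_among = 2.25,
        sigma_within = 0.5, PhiPT = 9/11."""
        res = amova_phipt(two_pop_gm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        r = res[0]
        assert r.sigma_among == pytest.approx(2.25, abs=1e-12)
        assert r.sigma_within == pytest.approx(0.5, abs=1e-12)
        assert r.phipt == pytest.approx(9 / 11, abs=1e-12)

    def test_identical_populations_zero(self):
        calls = np.array([[0, 1, 0, 1], [2, 1, 2, 1], [1, 0, 1, 0]])
        gm = make_gm(calls)
        res = amova_phipt(gm, {"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        assert res[0].phipt == pytest.approx(0.0, abs=1e-12)

    def test_fixed_opposite_populations_one(self):
        calls = np.array([[0, 0, 2, 2]] * 5)
        gm = make_gm(calls)
        res = amova_phipt(gm, {"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        assert res[0].phipt == pytest.approx(1.0)

    def test_small_population_rejected(self, two_pop_gm):
        with pytest.raises(ValueError, match="fewer than 2"):
            amova_phipt(two_pop_gm, {"a1": "A", "a2": "B", "b1": "B", "b2": "B"})

    def test_pooled_then_split_population_near_zero(self):
        """Random label splits of one panmictic population give |PhiPT| < 0.02."""
        rng = np.random.default_rng(42)
        p = rng.uniform(0.1, 0.9, size=200)
        calls = rng.binomial(2, p[:, None], size=(200, 40)).astype(np.int8)
        gm = make_gm(calls, sample_ids=[f"s{i}" for i in range(40)])
        d2 = genotype_squared_distances(gm)
        raws = []
        for _ in range(100):
            labels = np.array(["A"] * 20 + ["B"] * 20)
            rng.shuffle(labels)
            raws.append(phipt_from_distances(d2, labels).phipt_raw)
        assert np.max(np.abs(raws)) < 0.02

    def test_permutation_p_value_detects_structure(self):
        rng = np.random.default_rng(3)
        calls = np.vstack([
            np.hstack([rng.binomial(2, 0.1, (50, 10)),
                       rng.binomial(2, 0.9, (50, 10))]),
        ]).astype(np.int8)
        gm = make_gm(calls, sample_ids=[f"s{i}" for i in range(20)])
        pops = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
        res = amova_phipt(gm, pops, permutations=199, seed=1)
        assert res[0].p_value == pytest.approx(1 / 200, abs=1e-9)


class TestFstScan:
    def test_identical_populations_all_zero(self):
        calls = np.tile(np.array([[0, 1, 0, 1]]), (20, 1)).astype(np.int8)
        pos = np.arange(1, 21) * 100_000
        gm = make_gm(calls, pos=pos)
        track = fst_scan(gm, {"s0": "A", "s1": "A", "s2": "B", "s3": "B"},
                         window_bp=500_000)
        assert (track["phipt"].dropna() == 0).all()

    def test_window_larger_than_genome_matches_global(self, two_pop_gm):
        pops = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        track = fst_scan(two_pop_gm, pops, window_bp=10**9)
        global_phi = amova_phipt(two_pop_gm, pops)[0].phipt
        assert len(track) == 1
        assert track["phipt"].iloc[0] == pytest.approx(global_phi, abs=1e-12)

    def test_empty_windows_emitted_as_missing(self):
        calls = np.tile(np.array([[0, 0, 2, 2]]), (4, 1)).astype(np.int8)
        pos = [100, 200, 3_000_100, 3_000_200]
        gm = make_gm(calls, pos=pos)
        track = fst_scan(gm, {"s0": "A", "s1": "A", "s2": "B", "s3": "B"},
                         window_bp=1_000_000)
        assert len(track) == 4
        assert track["n_loci"].tolist() == [2, 0, 0, 2]
        assert track["phipt"].isna().tolist() == [False, True, True, False]

    def test_divergent_region_is_argmax(self):
        from polykaryo.simulate import fst_for_target_phipt

        f = fst_for_target_phipt(0.02)
        cfg = GenotypeSimConfig(
            n_per_pop={"A": 20, "B": 20}, pop_fst={"A": f, "B": f},
            n_loci=1000, missing_rate=0.0,
            chrom_lengths={"Csa06": 20_000_000},
            divergent_region=("Csa06", 6_000_000, 9_000_000, 0.5),
        )
        gm, _, _, truth = simulate_genotypes(cfg, seed=7)
        track = fst_scan(gm, truth.pop_labels, window_bp=1_000_000)
        best = track.loc[track["phipt"].idxmax()]
        assert 6_000_000 <= best["start"] and best["end"] <= 9_000_000


class TestMinorAlleles:
    def test_hand_enumerated_venn(self):
        # 3 groups x 7 samples each (1/7 ~ 0.143; use threshold 0.2)
        # locus 0: rare hom-alt in G1 only; locus 1: rare hom-alt in G1+G2;
        # locus 2: rare in all three; locus 3: common everywhere;
        # locus 4: absent everywhere (freq 0 -> excluded); locus 5: rare in G3
        n = 7
        g1 = np.zeros((6, n), np.int8)
        g2 = np.zeros((6, n), np.int8)
        g3 = np.zeros((6, n), np.int8)
        g1[0, 0] = 2
        g1[1, 0] = 2
        g2[1, 0] = 2
        for g in (g1, g2, g3):
            g[2, 0] = 2
            g[3, :] = 2  # hom fraction 1 -> not minor
        g3[5, 0] = 2
        calls = np.hstack([g1, g2, g3])
        ids = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)] + [
            f"c{i}" for i in range(n)]
        gm = make_gm(calls, sample_ids=ids)
        groups = {s: ("G1" if s[0] == "a" else "G2" if s[0] == "b" else "G3")
                  for s in ids}
        cat = minor_allele_catalog(gm, groups, hom_threshold=0.2)
        assert cat.venn[frozenset({"G1"})] == 1
        assert cat.venn[frozenset({"G1", "G2"})] == 1
        assert cat.venn[frozenset({"G1", "G2", "G3"})] == 1
        assert cat.venn[frozenset({"G3"})] == 1
        assert frozenset({"G2"}) not in cat.venn
        assert sum(cat.venn.values()) == cat.union_size == 4

    def test_absent_allele_excluded(self):
        calls = np.zeros((3, 30), np.int8)
        ids = [f"s{i}" for i in range(30)]
        gm = make_gm(calls, sample_ids=ids)
        groups = {s: "G1" if i < 15 else "G2" for i, s in enumerate(ids)}
        cat = minor_allele_catalog(gm, groups)
        assert cat.union_size == 0

    def test_brute_force_enumeration_on_random_matrix(self):
        rng = np.random.default_rng(9)
        n_loci, per_group = 60, 25
        calls = rng.choice([MISSING, 0, 1, 2], p=[0.05, 0.5, 0.25, 0.2],
                           size=(n_loci, 3 * per_group)).astype(np.int8)
        ids = [f"s{i}" for i in range(3 * per_group)]
        gm = make_gm(calls, sample_ids=ids)
        groups = {s: f"G{i // per_group}" for i, s in enumerate(ids)}
        cat = minor_allele_catalog(gm, groups, hom_threshold=0.1)
        # independent locus-by-locus enumeration
        for gname in ("G0", "G1", "G2"):
            cols = [i for i, s in enumerate(ids) if groups[s] == gname]
            expected = set()
            for l in range(n_loci):
                vals = [calls[l, c] for c in cols if calls[l, c] != MISSING]
                for hom in (0, 2):
                    frac = sum(v == hom for v in vals) / len(vals)
                    if 0 < frac < 0.1:
                        expected.add(l)
            assert cat.sets[gname] == expected
        assert sum(cat.venn.values()) == cat.union_size

    def test_empty_group_rejected(self, two_pop_gm):
        with pytest.raises(ValueError, match="no samples"):
            minor_allele_catalog(
                two_pop_gm,
                {"a1": "A", "a2": "A", "b1": "A", "b2": "A", "ghost": "B"},
            )


class TestAdmixture:
    def test_threshold_rule(self):
        q = QMatrix(pd.DataFrame(
            [[0.8, 0.1, 0.1], [0.5, 0.3, 0.2], [0.7, 0.2, 0.1]],
            index=["A", "B", "C"], columns=["CG1", "CG2", "CG3"]))
        out = classify_admixture(q, cutoff=0.70)
        assert out["A"] == "CG1"
        assert out["B"] == "ADMIXED"
        assert out["C"] == "CG1"  # boundary: max == cutoff assigns
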