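"""Map interpolation, IBD grids, LOD scans and peak classification."""

import numpy as np
import pandas as pd
import pytest

from pedigrowth.linkage import (GeneticMap, classify_peaks, estimate_ibd_from_markers,
                                fit_linkage_at, genome_scan, ibd_from_descent,
                                lod_score, power_simulation)
from pedigrowth.pedigree import kinship_matrix
from pedigrowth.simulate import (SimConfig, adult_phenotyped_ids, gene_drop,
                                 genotypes_from_descent, ibd_matrix_at,
                                 simulate_pedigree, simulate_trait)


@pytest.fixture(scope="module")
def linkage_colony():
    cfg = SimConfig(seed=21, carrying_capacity=60, n_founder_females=10,
                    n_founder_males=4, chrom_lengths=(100.0, 100.0))
    ped = simulate_pedigree(cfg)
    ids = adult_phenotyped_ids(ped, cfg)
    order, phi_full = kinship_matrix(ped)
    pos = {v: k for k, v in enumerate(order)}
    phi = phi_full[np.ix_([pos[i] for i in ids], [pos[i] for i in ids])]
    return cfg, ped, ids, (order, phi_full), phi


class TestGeneticMap:
    @pytest.fixture()
    def gmap(self):
        return GeneticMap(pd.DataFrame({
            "chrom": [1, 1, 1, 2, 2],
            "bp": [0, 2_000_000, 10_000_000, 0, 5_000_000],
            "cm": [0.0, 2.0, 7.0, 0.0, 6.0]}))

    def test_anchor_exact(self, gmap):
        assert gmap.interpolate_cm(1, 2_000_000) == pytest.approx(2.0)

    def test_midway_linear(self, gmap):
        assert gmap.interpolate_cm(1, 1_000_000) == pytest.approx(1.0)

    def test_clamped_beyond_ends(self, gmap):
        assert gmap.interpolate_cm(1, 99_000_000) == pytest.approx(7.0)
        assert gmap.interpolate_cm(1, -5) == pytest.approx(0.0)

    def test_unknown_chromosome(self, gmap):
        with pytest.raises(KeyError):
            gmap.interpolate_cm(9, 100)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            GeneticMap(pd.DataFrame({"chrom": [1, 1], "bp": [10, 10], "cm": [0, 1]}))

    def test_tsv_roundtrip(self, gmap, tmp_path):
        gmap.anchors.to_csv(tmp_path / "map.tsv", sep="\t", index=False)
        again = GeneticMap.from_tsv(tmp_path / "map.tsv")
        assert again.interpolate_cm(2, 2_500_000) == pytest.approx(3.0)


class TestOracleIBD:
    def test_parent_offspring_half_everywhere(self, trio_records):
        from pedigrowth.pedigree import Pedigree
        ped = Pedigree.from_records(trio_records)
        cfg = SimConfig(seed=1, chrom_lengths=(100.0,))
        descent = gene_drop(ped, cfg, np.random.default_rng(1))
        for pos in (0.0, 33.0, 99.9):
            pi = ibd_matrix_at(descent, 0, pos, ["kid", "dad"])
            assert pi[0, 1] == pytest.approx(0.5)
            assert pi[0, 0] == pytest.approx(1.0)  # non-inbred self

    def test_fullsib_genomewide_mean(self, trio_records):
        from pedigrowth.pedigree import Pedigree
        recs = trio_records + [
            {"id": f"sib{k}", "sire": "dad", "dam": "mom", "sex": "F",
             "birth_date": "2006-01-01"} for k in range(2)]
        ped = Pedigree.from_records(recs)
        cfg = SimConfig(seed=2, chrom_lengths=tuple([100.0] * 6))
        vals = []
        for rep in range(40):
            descent = gene_drop(ped, cfg, np.random.default_rng(rep))
            for c in range(6):
                for pos in np.arange(5.0, 100.0, 10.0):
                    pi = ibd_matrix_at(descent, c, pos, ["kid", "sib0"])
                    vals.append(pi[0, 1])
        vals = np.asarray(vals)
        assert set(np.unique(vals)) <= {0.0, 0.5, 1.0}
        se = vals.std() / np.sqrt(len(vals) / 10)  # conservative eff. sample size
        assert abs(vals.mean() - 0.5) < 3 * se

    def test_grid_mean_approaches_expectation(self, linkage_colony):
        cfg, ped, ids, (order, phi_full), phi = linkage_colony
        sub = ids[:20]
        pos = {v: k for k, v in enumerate(order)}
        phi_sub = phi_full[np.ix_([pos[i] for i in sub], [pos[i] for i in sub])]
        acc = np.zeros((20, 20))
        reps = 300
        for rep in range(reps):
            descent = gene_drop(ped, cfg, np.random.default_rng(rep + 1000),
                                chroms=[0])
            acc += ibd_matrix_at(descent, 0, 50.0, sub)
        mean_pi = acc / reps
        err = np.abs(mean_pi - 2 * phi_sub)
        assert err.max() < 0.12  # 3-4 MC SDs at 300 drops

    def test_missing_descent_id(self, linkage_colony):
        cfg, ped, ids, _, _ = linkage_colony
        descent = gene_drop(ped, cfg, np.random.default_rng(0), chroms=[0])
        with pytest.raises(KeyError):
            ibd_matrix_at(descent, 0, 10.0, ["not-an-id"])


class TestMarkerIBD:
    def test_tracks_oracle_for_relatives(self, linkage_colony):
        cfg, ped, ids, (order, phi_full), phi = linkage_colony
        rng = np.random.default_rng(3)
        descent = gene_drop(ped, cfg, rng)
        sub = ids[:60]
        pos = {v: k for k, v in enumerate(order)}
        phi_sub = phi_full[np.ix_([pos[i] for i in sub], [pos[i] for i in sub])]
        G, gmap = genotypes_from_descent(descent, cfg, rng, ids=sub)
        est = estimate_ibd_from_markers(G, gmap, phi_sub, window_cm=20.0,
                                        grid_step=50.0)
        oracle = ibd_from_descent(descent, sub, positions={0: [50.0]})
        a = est.pi_at(0, 50.0)
        b = oracle.pi_at(0, 50.0)
        iu = np.triu_indices(len(sub), 1)
        related = 2 * phi_sub[iu] > 0.2  # close kin carry the signal
        r = np.corrcoef(a[iu][related], b[iu][related])[0, 1]
        assert r > 0.5

    def test_unrelated_centered_at_zero(self):
        from pedigrowth.pedigree import Pedigree
        recs = [{"id": f"f{i}", "sire": "0", "dam": "0", "sex": "M"}
                for i in range(30)]
        ped = Pedigree.from_records(recs)
        cfg = SimConfig(seed=4, chrom_lengths=(100.0,), n_markers_per_chrom=300)
        rng = np.random.default_rng(4)
        descent = gene_drop(ped, cfg, rng)
        G, gmap = genotypes_from_descent(descent, cfg, rng)
        phi = 0.5 * np.eye(30)
        est = estimate_ibd_from_markers(G, gmap, phi, window_cm=30.0, grid_step=50.0)
        iu = np.triu_indices(30, 1)
        assert np.abs(est.pi_at(0, 50.0)[iu]).mean() < 0.08

    def test_monomorphic_markers_error(self):
        G = pd.DataFrame(np.zeros((10, 20)), index=[f"i{k}" for k in range(10)])
        gmap = pd.DataFrame({"marker": range(20), "chrom": 0,
                             "cm": np.linspace(0, 100, 20)})
        with pytest.raises(ValueError):
            estimate_ibd_from_markers(G, gmap, 0.5 * np.eye(10))


class TestLOD:
    def test_equal_likelihoods_zero(self):
        assert lod_score(-5.0, -5.0) == 0.0

    def test_unit_conversion(self):
        # Lambda = 2(lnL_a - lnL_0) = 15.2  =>  LOD = 15.2 / (2 ln 10) = 3.30
        assert lod_score(-10.0 + 15.2 / 2, -10.0) == pytest.approx(3.30, abs=0.005)

    def test_negative_clipped(self):
        assert lod_score(-6.0, -5.0) == 0.0

    def test_collinear_pi_flagged(self, linkage_colony):
        cfg, ped, ids, (order, phi_full), phi = linkage_colony
        y = np.random.default_rng(5).normal(size=len(ids))
        with pytest.warns(UserWarning):
            fit = fit_linkage_at(y, None, phi, 2 * phi)
        assert fit.collinear

    def test_planted_qtl_recovered(self, linkage_colony):
        cfg, ped, ids, (order, phi_full), phi = linkage_colony
        cfg_q = SimConfig(**{**cfg.__dict__, "h2": 0.35, "h2q": 0.3})
        rng = np.random.default_rng(6)
        descent = gene_drop(ped, cfg_q, rng, chroms=[0])
        y, truth = simulate_trait(ped, cfg_q, rng, ids=ids, descent=descent,
                                  phi=(order, phi_full))
        pi = ibd_matrix_at(descent, 0, cfg_q.qtl_cm, ids)
        alt = fit_linkage_at(y.to_numpy(), None, phi, pi)
        assert alt.share("qtl") == pytest.approx(0.3, abs=0.18)


class TestScanAndPeaks:
    def test_scan_deterministic_and_qtl_localised(self, linkage_colony):
        cfg, ped, ids, (order, phi_full), phi = linkage_colony
        cfg_q = SimConfig(**{**cfg.__dict__, "h2": 0.3, "h2q": 0.35})
        rng = np.random.default_rng(7)
        descent = gene_drop(ped, cfg_q, rng)
        y, _ = simulate_trait(ped, cfg_q, rng, ids=ids, descent=descent,
                              phi=(order, phi_full))
        ibd = ibd_from_descent(descent, ids, grid_step=10.0)
        scan1 = genome_scan(y.to_numpy(), None, phi, ibd)
        scan2 = genome_scan(y.to_numpy(), None, phi, ibd)
        assert np.allclose(scan1.table["lod"], scan2.table["lod"], equal_nan=True)
        best = scan1.table.loc[scan1.table["lod"].idxmax()]
        assert best["chrom"] == cfg_q.qtl_chrom
        assert abs(best["cm"] - cfg_q.qtl_cm) <= 20.0
        assert (scan1.table["h2q"].dropna() >= 0).all()
        assert ((scan1.table["h2q"] + scan1.table["h2r"]).dropna() <= 1 + 1e-9).all()

    def test_flat_scan_empty_table(self):
        table = pd.DataFrame({"chrom": [1] * 5, "cm": np.arange(5.0),
                              "lod": np.zeros(5)})
        assert classify_peaks(table).empty

    def test_single_suggestive_position(self):
        table = pd.DataFrame({"chrom": [10] * 3, "cm": [108.0, 109.0, 110.0],
                              "lod": [0.2, 2.27, 0.3]})
        peaks = classify_peaks(table)
        assert len(peaks) == 1
        row = peaks.iloc[0]
        assert row["class"] == "suggestive"
        assert row["max_lod"] == pytest.approx(2.27)
        assert row["cm_peak"] == 109.0

    def test_significant_class(self):
        table = pd.DataFrame({"chrom": [1] * 3, "cm": [0.0, 1.0, 2.0],
                              "lod": [0.0, 3.4, 0.0]})
        peaks = classify_peaks(table)
        assert list(peaks["class"]) == ["significant"]

    def test_contiguous_run_merged(self):
        table = pd.DataFrame({"chrom": [1] * 6, "cm": np.arange(6.0),
                              "lod": [0, 2.0, 2.5, 3.5, 2.0, 0]})
        peaks = classify_peaks(table)
        assert len(peaks) == 1
        assert peaks.iloc[0]["cm_start"] == 1.0 and peaks.iloc[0]["cm_end"] == 4.0
        assert peaks.iloc[0]["class"] == "significant"


class TestPowerSimulation:
    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            power_simulation(SimConfig(seed=0), reps=10)

    def test_monotone_in_h2q_small_colony(self):
        cfg = SimConfig(seed=31, carrying_capacity=60, n_founder_females=10,
                        n_founder_males=4, chrom_lengths=(100.0,))
        powers = []
        for h2q in (0.0, 0.3):
            res = power_simulation(cfg, h2_total=0.65, h2q=h2q, reps=50, seed=1)
            powers.append(res["power"])
        assert powers[0] <= 0.1  # near the type-I rate at LOD 3.3
        assert powers[1] >= powers[0]
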