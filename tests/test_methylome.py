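import numpy as np
import pandas as pd
import pytest

from pollenpipe.methylome import (
    EpialleleThresholds,
    TissueExpression,
    classify_epiallele,
    classify_epialleles,
    count_expressed_by_threshold,
    flag_cds_te_overlap,
    read_bed,
    select_mpgs,
    summarize_gene_methylation,
    write_bed,
)


def _sites(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "context", "methylated_reads", "total_reads"])


class TestSummarize:
    def test_single_cg_site(self):
        sites = _sites([("chr1", 50, "CG", 4, 8)])
        out = summarize_gene_methylation(sites, {"g1": [("chr1", 0, 100)]})
        assert out.loc["g1", "cg_level"] == pytest.approx(0.5)
        assert out.loc["g1", "informative_cg"] == 1

    def test_zero_coverage_sites_uninformative(self):
        sites = _sites([("chr1", 50, "CG", 0, 0), ("chr1", 60, "CHG", 0, 0)])
        out = summarize_gene_methylation(sites, {"g1": [("chr1", 0, 100)]})
        assert out.loc["g1", "informative_cg"] == 0
        assert out.loc["g1", "informative_chg"] == 0

    def test_read_weighted_mean(self):
        # 9/10 and 0/90 -> weighted level 9/100, not per-site mean 0.45
        sites = _sites([("chr1", 10, "CG", 9, 10), ("chr1", 20, "CG", 0, 90)])
        out = summarize_gene_methylation(sites, {"g1": [("chr1", 0, 100)]})
        assert out.loc["g1", "cg_level"] == pytest.approx(0.09)

    def test_chh_ignored(self):
        sites = _sites([("chr1", 10, "CHH", 5, 5)])
        out = summarize_gene_methylation(sites, {"g1": [("chr1", 0, 100)]})
        assert out.loc["g1", "informative_cg"] == 0

    def test_site_outside_cds_warns(self):
        sites = _sites([("chr1", 500, "CG", 1, 2)])
        with pytest.warns(UserWarning, match="outside"):
            out = summarize_gene_methylation(sites, {"g1": [("chr1", 0, 100)]})
        assert out.loc["g1", "informative_cg"] == 0

    def test_halfopen_boundaries(self):
        # interval [100,200): 1-based positions 101..200 inside, 100 and 201 outside
        cds = {"g1": [("chr1", 100, 200)]}
        inside = _sites([("chr1", 101, "CG", 1, 1), ("chr1", 200, "CG", 1, 1)])
        out = summarize_gene_methylation(inside, cds)
        assert out.loc["g1", "informative_cg"] == 2
        outside = _sites([("chr1", 100, "CG", 1, 1), ("chr1", 201, "CG", 1, 1)])
        with pytest.warns(UserWarning):
            out = summarize_gene_methylation(outside, cds)
        assert out.loc["g1", "informative_cg"] == 0

    def test_generator_recovery(self, methylome_sim):
        sites, cds, _, _, truth = methylome_sim
        out = summarize_gene_methylation(sites, cds)
        assert (out["informative_cg"] >= 0).all()
        # spot-check a clean teM gene's level against its class band
        tem = [g for g, c in truth.epialleles.items() if c == "teM"][0]
        assert out.loc[tem, "cg_level"] > 0.45

    def test_meth_exceeding_total_rejected(self):
        sites = _sites([("chr1", 10, "CG", 5, 2)])
        with pytest.raises(ValueError):
            summarize_gene_methylation(sites, {"g1": [("chr1", 0, 100)]})


class TestClassify:
    def test_tem_rule(self):
        assert classify_epiallele(0.45, 0.43, 35, 33) == "teM"

    def test_insufficient_sites(self):
        assert classify_epiallele(0.9, 0.9, 10, 50) == "insufficient"
        assert classify_epiallele(0.9, 0.9, 29, 30) == "insufficient"
        assert classify_epiallele(0.9, 0.9, 30, 30) == "teM"

    def test_tem_boundary_inclusive(self):
        assert classify_epiallele(0.40, 0.40, 50, 50) == "teM"

    def test_gbm_um_ambiguous(self):
        assert classify_epiallele(0.70, 0.01, 50, 50) == "gbM"
        assert classify_epiallele(0.01, 0.01, 50, 50) == "UM"
        assert classify_epiallele(0.20, 0.20, 50, 50) == "ambiguous"

    def test_classes_exhaustive_and_exclusive(self, rng):
        thresholds = EpialleleThresholds()
        valid = {"teM", "gbM", "UM", "ambiguous", "insufficient"}
        for _ in range(500):
            cls = classify_epiallele(
                rng.uniform(0, 1), rng.uniform(0, 1), rng.integers(0, 100), rng.integers(0, 100),
                thresholds,
            )
            assert cls in valid

    def test_recovery_on_synthetic(self, methylome_sim):
        sites, cds, _, _, truth = methylome_sim
        out = summarize_gene_methylation(sites, cds)
        classes = classify_epialleles(out)
        truth_series = pd.Series(truth.epialleles).reindex(classes.index)
        assert (classes == truth_series).all()

    def test_all_um_mix_yields_no_tem(self):
        from pollenpipe.synthetic_data import simulate_methylome_and_tissue_tpm

        sites, cds, _, _, _ = simulate_methylome_and_tissue_tpm(
            n_genes=60, class_mix={"UM": 1.0}, n_mpg=0, insufficient_frac=0.0, seed=7
        )
        classes = classify_epialleles(summarize_gene_methylation(sites, cds))
        assert (classes != "teM").all()


class TestTeOverlap:
    def test_single_base_overlap_flagged(self):
        flags = flag_cds_te_overlap({"g1": [("chr1", 100, 200)]}, [("chr1", 199, 300)])
        assert flags["g1"]

    def test_adjacent_halfopen_not_flagged(self):
        flags = flag_cds_te_overlap({"g1": [("chr1", 100, 200)]}, [("chr1", 200, 300)])
        assert not flags["g1"]

    def test_no_tes_on_chrom(self):
        flags = flag_cds_te_overlap({"g1": [("chr1", 100, 200)]}, [("chr2", 0, 1000)])
        assert not flags["g1"]

    def test_nested_te_found(self):
        # a short TE hidden behind a long earlier one (needs running-max ends)
        flags = flag_cds_te_overlap(
            {"g1": [("chr1", 500, 600)]}, [("chr1", 0, 1000), ("chr1", 10, 20)]
        )
        assert flags["g1"]

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            flag_cds_te_overlap({"g1": [("chr1", 200, 100)]}, [])

    def test_matches_bruteforce_oracle(self, rng):
        genes = {
            f"g{i}": [("chr1", int(s), int(s) + int(l))]
            for i, (s, l) in enumerate(zip(rng.integers(0, 5000, 40), rng.integers(1, 200, 40)))
        }
        tes = [
            ("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 5000, 30), rng.integers(1, 300, 30))
        ]
        flags = flag_cds_te_overlap(genes, tes)
        for gene, ivals in genes.items():
            (chrom, a, b), = ivals
            brute = any(max(a, s) < min(b, e) for _, s, e in tes)
            assert flags[gene] == brute


class TestThresholdSweep:
    def test_monotone_non_increasing(self, methylome_sim):
        _, _, _, tissue_expr, truth = methylome_sim
        tem = [g for g, c in truth.epialleles.items() if c == "teM"]
        sweep = count_expressed_by_threshold(tissue_expr.tpm, tem)
        for tissue in sweep.columns:
            assert (np.diff(sweep[tissue].to_numpy()) <= 0).all()

    def test_threshold_inclusive(self):
        tpm = pd.DataFrame({"anther": [100.0, 99.9]}, index=["g1", "g2"])
        sweep = count_expressed_by_threshold(tpm, ["g1", "g2"], thresholds=[100])
        assert sweep.loc[100, "anther"] == 1

    def test_anther_count_at_100_covers_mpgs(self, methylome_sim):
        _, _, _, tissue_expr, truth = methylome_sim
        tem = [g for g, c in truth.epialleles.items() if c == "teM"]
        sweep = count_expressed_by_threshold(tissue_expr.tpm, tem)
        assert sweep.loc[100, "anther"] >= len(truth.mpg_genes)


class TestSelectMpgs:
    def _expr(self, rows, veg_n=8):
        tissues = ["anther", "tassel"] + [f"v{i}" for i in range(veg_n)]
        tpm = pd.DataFrame(rows, columns=tissues)
        return TissueExpression(tpm=tpm, anther="anther", tassel="tassel", vegetative=tissues[2:])

    def test_clean_selection(self):
        expr = self._expr({"g1": [100.0, 50.0] + [9.0] * 8}.values())
        expr.tpm.index = ["g1"]
        classes = pd.Series({"g1": "teM"})
        assert select_mpgs(expr, classes, pseudocount=0.01) == ["g1"]

    def test_single_tissue_failure(self):
        expr = self._expr([[100.0, 0.0] + [0.0] * 7 + [11.0]])
        expr.tpm.index = ["g1"]
        classes = pd.Series({"g1": "teM"})
        assert select_mpgs(expr, classes, pseudocount=0.01) == []

    def test_requires_tem(self):
        expr = self._expr([[1000.0, 1.0] + [0.0] * 8])
        expr.tpm.index = ["g1"]
        assert select_mpgs(expr, pd.Series({"g1": "UM"})) == []

    def test_tassel_excluded_from_comparison(self):
        # high tassel must not disqualify
        expr = self._expr([[100.0, 99.0] + [1.0] * 8])
        expr.tpm.index = ["g1"]
        assert select_mpgs(expr, pd.Series({"g1": "teM"})) == ["g1"]

    def test_exact_recovery_on_synthetic(self, methylome_sim):
        sites, cds, te, tissue_expr, truth = methylome_sim
        classes = classify_epialleles(summarize_gene_methylation(sites, cds))
        overlap = flag_cds_te_overlap(cds, te)
        mpgs = select_mpgs(tissue_expr, classes, te_overlap=overlap)
        assert mpgs == sorted(truth.mpg_genes)

    def test_monotone_in_fold(self, methylome_sim):
        sites, cds, te, tissue_expr, truth = methylome_sim
        classes = classify_epialleles(summarize_gene_methylation(sites, cds))
        prev = None
        for fold in (5.0, 10.0, 50.0, 500.0):
            got = set(select_mpgs(tissue_expr, classes, fold=fold))
            if prev is not None:
                assert got <= prev
            prev = got

    def test_missing_vegetative_tissue_errors(self):
        tpm = pd.DataFrame({"anther": [1.0], "tassel": [1.0]}, index=["g1"])
        with pytest.raises(ValueError):
            TissueExpression(tpm=tpm, anther="anther", tassel="tassel", vegetative=["v0"])


class TestBedIO:
    def test_roundtrip(self, tmp_path):
        ivals = [("chr1", 0, 100, "g1"), ("chr2", 50, 60, "g2")]
        path = tmp_path / "x.bed"
        write_bed(ivals, path)
        assert read_bed(path) == ivals
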