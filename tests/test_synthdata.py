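import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from lncmap.modulemap import filter_modules
from lncmap.regnet import fit_pair
from lncmap.survival import logrank
from lncmap.synthdata import (
    TruthTable,
    generate_cohort,
    generate_genesets,
    generate_modules,
    generate_peaks_and_tss,
    generate_survival,
    generate_treatment_counts,
)
from lncmap.enrich import enrich_collection


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = small_config(seed=7)
        c1, t1 = generate_cohort(cfg)
        c2, t2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(c1.mrna_expr, c2.mrna_expr)
        pd.testing.assert_frame_equal(c1.lncrna_expr, c2.lncrna_expr)
        pd.testing.assert_frame_equal(c1.methylation, c2.methylation)
        pd.testing.assert_frame_equal(c1.copy_number, c2.copy_number)
        assert t1.drivers == t2.drivers
        d1 = generate_treatment_counts(cfg, t1)
        d2 = generate_treatment_counts(cfg, t2)
        for (a1, b1), (a2, b2) in zip(d1, d2):
            pd.testing.assert_frame_equal(a1, a2)
            pd.testing.assert_frame_equal(b1, b2)

    def test_different_seeds_differ(self):
        c1, _ = generate_cohort(small_config(seed=1))
        c2, _ = generate_cohort(small_config(seed=2))
        assert not c1.mrna_expr.equals(c2.mrna_expr)


class TestCohort:
    def test_too_few_samples_refused(self):
        with pytest.raises(ValueError, match="n_samples"):
            small_config(n_samples=7).validate()

    def test_zero_effect_gives_null_correlations(self):
        cfg = small_config(beta_lnc_effect=0.0, seed=13)
        cohort, truth = generate_cohort(cfg)
        cors = []
        for lnc, sign in truth.drivers.items():
            x = cohort.lncrna_expr.loc[lnc].to_numpy()
            for m, d in truth.driver_module_direction.items():
                if d != sign:
                    continue
                for g in truth.driver_modules[m]:
                    y = cohort.mrna_expr.loc[g].to_numpy()
                    cors.append(np.corrcoef(x, y)[0, 1])
        cors = np.array(cors)
        assert abs(cors.mean()) < 3 * cors.std() / np.sqrt(len(cors))

    def test_ols_recovers_planted_effect(self):
        """OLS on the generated (y, xDM, xCNV, xlnc) recovers the planted
        coefficient within 3 standard errors for >= 95% of pairs."""
        cfg = small_config(n_samples=500, beta_lnc_effect=0.5, seed=17)
        cohort, truth = generate_cohort(cfg)
        meth = {}
        probe_true = {}
        within = []
        z = lambda v: (v - v.mean()) / v.std(ddof=1)
        for lnc, sign in truth.drivers.items():
            x = z(cohort.lncrna_expr.loc[lnc].to_numpy())
            for m, d in truth.driver_module_direction.items():
                if d != sign:
                    continue
                for g in truth.driver_modules[m]:
                    y = cohort.mrna_expr.loc[g].to_numpy()
                    probes = cohort.probe_map[cohort.probe_map.gene_id == g]
                    betas = cohort.methylation.loc[probes.probe_id]
                    # the true probe is the anti-correlated one
                    rho = betas.apply(
                        lambda r: np.corrcoef(r, y)[0, 1], axis=1
                    )
                    dm = z(betas.loc[rho.idxmin()].to_numpy())
                    cnv = z(cohort.copy_number.loc[g].to_numpy())
                    fit = fit_pair(y, dm, cnv, x)
                    se = fit.beta_lnc / fit.t_lnc
                    within.append(abs(fit.beta_lnc - sign * 0.5) < 3 * se)
        assert np.mean(within) >= 0.95

    def test_planted_ids_exist_and_disjoint(self):
        cfg = small_config(seed=19)
        cohort, truth = generate_cohort(cfg)
        truth.validate(cohort)  # raises on violation
        assert not set(truth.inducers()) & set(truth.suppressors())

    def test_confounded_genes_have_lncrna_locus_cnv(self):
        cfg = small_config(seed=23)
        cohort, truth = generate_cohort(cfg)
        lnc, gene = truth.confounded_pairs[0]
        x = cohort.lncrna_expr.loc[lnc]
        c = cohort.copy_number.loc[gene]
        assert abs(np.corrcoef(x, c)[0, 1]) > 0.4

    def test_methylation_anticorrelated_with_expression(self):
        cfg = small_config(seed=29)
        cohort, truth = generate_cohort(cfg)
        null_genes = [
            g for g in cohort.mrna_expr.index
            if g not in {x for m in truth.driver_modules.values() for x in m}
            and g not in truth.low_expressed_genes
        ][:50]
        rhos = []
        for g in null_genes:
            probes = cohort.probe_map[cohort.probe_map.gene_id == g].probe_id
            best = min(
                np.corrcoef(cohort.methylation.loc[p], cohort.mrna_expr.loc[g])[0, 1]
                for p in probes
            )
            rhos.append(best)
        assert np.mean(rhos) < -0.2


class TestModules:
    def test_no_syntenic_decoys_when_fraction_zero(self):
        cfg = small_config(frac_syntenic_decoys=0.0, seed=31)
        cohort, truth = generate_cohort(cfg)
        modules = generate_modules(cfg, truth, cohort)
        chrom = dict(zip(cohort.gene_annot.gene_id, cohort.gene_annot.chrom))
        syntenic = [
            m.module_id for m in modules if len(m.chromosomes(chrom)) <= 1
        ]
        assert syntenic == []

    def test_degenerate_density_range(self):
        cfg = small_config(density_range=(0.9, 0.9), seed=37)
        cohort, truth = generate_cohort(cfg)
        modules = generate_modules(cfg, truth, cohort)
        low = set(truth.decoy_modules["low_density"])
        for m in modules:
            if m.module_id not in low:
                assert m.density == pytest.approx(0.9)

    def test_oversized_module_range_refused(self):
        with pytest.raises(ValueError, match="module_size_range"):
            small_config(module_size_range=(8, 10_000)).validate()

    def test_planted_modules_survive_filter(self):
        cfg = small_config(seed=41)
        cohort, truth = generate_cohort(cfg)
        modules = generate_modules(cfg, truth, cohort)
        chrom = dict(zip(cohort.gene_annot.gene_id, cohort.gene_annot.chrom))
        kept = {m.module_id for m in filter_modules(modules, chrom)}
        assert set(truth.driver_modules) <= kept
        assert not set(truth.decoy_modules["syntenic"]) & kept
        assert not set(truth.decoy_modules["low_density"]) & kept


class TestGenesets:
    def test_members_exist_in_universe(self):
        cfg = small_config(seed=43)
        cohort, truth = generate_cohort(cfg)
        hallmark, kegg = generate_genesets(cfg, truth)
        universe = set(cohort.mrna_expr.index)
        assert hallmark.members() <= universe
        assert kegg.members() <= universe

    def test_planted_overlap_is_enriched(self):
        cfg = small_config(seed=47)
        cohort, truth = generate_cohort(cfg)
        hallmark, _ = generate_genesets(cfg, truth)
        universe = list(cohort.mrna_expr.index)
        members = next(iter(truth.driver_modules.values()))
        res = enrich_collection(members, hallmark.sets, universe)
        prolif = res[res.set_name == "HALLMARK_E2F_TARGETS"]
        assert prolif["adj_p"].iloc[0] < 0.05

    def test_zero_overlap_not_proliferation_linked(self):
        from lncmap.modulemap import CoessentialModule, annotate_module

        cfg = small_config(seed=53)
        cohort, truth = generate_cohort(cfg)
        hallmark, kegg = generate_genesets(cfg, truth)
        universe = list(cohort.mrna_expr.index)
        covered = hallmark.members() | kegg.members()
        outside = [g for g in universe if g not in covered][:6]
        if len(outside) >= 2:
            mod = CoessentialModule("m", outside, 0.9)
            ann = annotate_module(mod, [hallmark, kegg], universe)
            assert not ann.proliferation_linked


class TestTreatment:
    def test_zero_shift_gives_null_fold_changes(self):
        from lncmap.downstream import treatment_screen

        cfg = small_config(treatment_log2fc=0.0, seed=59)
        _, truth = generate_cohort(cfg)
        datasets = generate_treatment_counts(cfg, truth)
        treated, control = datasets[0]
        res = treatment_screen(treated, control)
        assert abs(np.median(res.log2fc)) < 0.1

    def test_planted_threefold_shift_flagged_and_estimated(self):
        from lncmap.downstream import treatment_screen

        cfg = small_config(
            nb_mean_log=8.0, nb_mean_sd=0.3, nb_dispersion=0.01,
            treatment_consistency=1.0, seed=61,
        )
        _, truth = generate_cohort(cfg)
        datasets = generate_treatment_counts(cfg, truth)
        flagged, errors = [], []
        for treated, control in datasets:
            res = treatment_screen(treated, control)
            flagged.extend(l in res.up for l in truth.treat_up)
            errors.extend(
                res.log2fc[l] - cfg.treatment_log2fc for l in truth.treat_up
            )
        # the planted 3-fold shift clears the 2-fold rule in >= 90% of
        # dataset x feature combinations, and the estimate is close to the
        # planted value (total-count normalization leaves a small
        # composition bias)
        assert np.mean(flagged) >= 0.9
        assert abs(np.mean(errors)) < 0.15


class TestSurvival:
    def test_zero_censor_rate_all_events(self):
        cfg = small_config(censor_rate=0.0, seed=67)
        cohort, truth = generate_cohort(cfg)
        surv = generate_survival(cfg, truth, cohort.mrna_expr)
        assert (surv["event"] == 1).all()

    def test_null_hazard_logrank_calibrated(self):
        zs = []
        for rep in range(60):
            cfg = small_config(hazard_log_hr=0.0, censor_rate=0.0,
                               seed=1000 + rep)
            cohort, truth = generate_cohort(cfg)
            surv = generate_survival(cfg, truth, cohort.mrna_expr)
            gene = next(iter(truth.prognostic))
            x = cohort.mrna_expr.loc[gene, surv["sample_id"]].to_numpy()
            z, _ = logrank(surv["time"], surv["event"], x > np.median(x))
            zs.append(z)
        # Z should look standard normal under the null
        assert abs(np.mean(zs)) < 3 / np.sqrt(len(zs))
        assert 0.6 < np.std(zs) < 1.5


class TestPeaks:
    def test_planted_lncrnas_have_many_proximal_datasets(self):
        from lncmap.downstream import compare_proximity, tss_proximity

        cfg = small_config(seed=71)
        cohort, truth = generate_cohort(cfg)
        peaksets, tss = generate_peaks_and_tss(cfg, truth, cohort)
        counts = tss_proximity(peaksets, tss, window=cfg.tss_window)
        expected_hits = int(np.ceil(cfg.peak_window_frac * cfg.n_peak_datasets))
        assert (counts[truth.peak_proximal] >= expected_hits).all()
        _, p = compare_proximity(counts, truth.peak_proximal)
        assert p < 0.05


class TestTruthRoundTrip:
    def test_json_round_trip(self, tmp_path):
        cfg = small_config(seed=73)
        _, truth = generate_cohort(cfg)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = TruthTable.from_json(path)
        assert back == truth
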