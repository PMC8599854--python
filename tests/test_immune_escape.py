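import numpy as np
import pandas as pd
import pytest

from ithseq.immune_escape import (
    call_hla_loh, filter_neoantigen_binders, ifng_loss_burden,
    loh_enrichment_comparison, lost_allele_binding_fraction,
    neoantigen_ith_summary, tumor_hla_loh_status,
)


def neo(pos, ic50, allele="A*02:01", gene="GA"):
    return {"patient_id": "P", "chrom": "chr1", "pos": pos, "ref": "C", "alt": "T",
            "gene": gene, "peptide": "KLMNPQRST", "allele": allele, "ic50_nm": ic50}


class TestBinderFilter:
    def test_strict_500_threshold(self):
        calls = pd.DataFrame([neo(1, 499.0), neo(2, 500.0), neo(3, 500.1)])
        kept = filter_neoantigen_binders(calls)
        assert kept["pos"].tolist() == [1]

    def test_empty_input_empty_output(self):
        assert len(filter_neoantigen_binders(pd.DataFrame(columns=["ic50_nm"]))) == 0


class TestNeoantigenIth:
    def _labels(self, mapping):
        return pd.DataFrame({"label": pd.Series(mapping),
                             "clonal": {k: v == "trunk" for k, v in mapping.items()}})

    def test_fraction_over_distinct_mutations(self):
        binders = pd.DataFrame([neo(1, 100.0), neo(1, 200.0), neo(2, 100.0)])
        labels = self._labels({"chr1:1:C>T": "trunk", "chr1:2:C>T": "private"})
        out = neoantigen_ith_summary(binders, labels)
        assert out["n_mutations"] == 2
        assert out["trunk_fraction"] == pytest.approx(0.5)

    def test_all_trunk(self):
        binders = pd.DataFrame([neo(i, 10.0) for i in range(1, 9)] +
                               [neo(i, 10.0) for i in (9, 10)])
        labels = self._labels({f"chr1:{i}:C>T": ("trunk" if i <= 8 else "private")
                               for i in range(1, 11)})
        assert neoantigen_ith_summary(binders, labels)["trunk_fraction"] == pytest.approx(0.8)

    def test_unlabeled_mutation_errors_with_key(self):
        binders = pd.DataFrame([neo(99, 10.0)])
        with pytest.raises(KeyError, match="chr1:99:C>T"):
            neoantigen_ith_summary(binders, self._labels({"chr1:1:C>T": "trunk"}))

    def test_no_binders(self):
        out = neoantigen_ith_summary(pd.DataFrame(), self._labels({}))
        assert out["n_binders"] == 0 and np.isnan(out["trunk_fraction"])


class TestLohEnrichment:
    def _loh(self, genes_with_loh, pat="P", reg="R1"):
        rows = [{"patient_id": pat, "region_id": reg, "gene": g,
                 "loh_class": "CNN_LOH" if g in genes_with_loh else "none"}
                for g in [f"G{i}" for i in range(30)]]
        return pd.DataFrame(rows)

    def test_stated_ratio(self):
        neo_genes = {f"G{i}" for i in range(20)}
        loh = self._loh({f"G{i}" for i in range(4)})
        df, _ = loh_enrichment_comparison(loh, {"P": set(loh["gene"])}, {"P": neo_genes})
        assert df.iloc[0]["neo_fraction"] == pytest.approx(0.20)

    def test_equal_fractions_give_p_one(self):
        # one LOH gene in each half -> neo and non-neo fractions identical
        loh = pd.concat([self._loh({"G0", "G15"}, reg=f"R{i}") for i in range(4)],
                        ignore_index=True)
        genes = set(loh["gene"])
        neo_genes = {f"G{i}" for i in range(15)}
        df, test = loh_enrichment_comparison(loh, {"P": genes}, {"P": neo_genes})
        assert np.allclose(df["neo_fraction"], df["other_fraction"])
        assert test["p_value"] == 1.0

    def test_all_genes_neoantigen_associated_gives_missing_other_fraction(self):
        loh = self._loh({"G0"})
        genes = set(loh["gene"])
        df, _ = loh_enrichment_comparison(loh, {"P": genes}, {"P": genes})
        assert df["other_fraction"].isna().all()

    def test_planted_enrichment_detected(self):
        """CNN-LOH planted twice as often in neoantigen genes across 20
        samples yields a significant paired difference in most replicates."""
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            frames = []
            for s in range(20):
                genes = [f"G{i}" for i in range(60)]
                neo_genes = set(genes[:30])
                loh_genes = {g for g in genes
                             if rng.random() < (0.30 if g in neo_genes else 0.15)}
                frames.append(pd.DataFrame([
                    {"patient_id": f"P{s}", "region_id": "R1", "gene": g,
                     "loh_class": "CNN_LOH" if g in loh_genes else "none"}
                    for g in genes]))
            loh = pd.concat(frames, ignore_index=True)
            mut = {f"P{s}": {f"G{i}" for i in range(60)} for s in range(20)}
            neo_map = {f"P{s}": {f"G{i}" for i in range(30)} for s in range(20)}
            _, test = loh_enrichment_comparison(loh, mut, neo_map)
            hits += test["p_value"] < 0.05
        assert hits >= 20  # >= 80%


class TestIfngLoss:
    def _calls(self, loss_counts):
        rows = []
        for s, (n_ifng, n_other) in enumerate(loss_counts):
            ifng = ["JAK1", "JAK2", "B2M", "STAT1", "IRF1", "IFNG", "IFNGR1", "IFNGR2"]
            for i, g in enumerate(ifng):
                rows.append({"patient_id": f"P{s}", "region_id": "R1", "gene": g,
                             "state": "loss" if i < n_ifng else "neutral"})
            for i in range(n_other):
                rows.append({"patient_id": f"P{s}", "region_id": "R1",
                             "gene": f"G{i}", "state": "loss"})
        return pd.DataFrame(rows)

    def test_no_losses_flagged_undefined(self):
        calls = self._calls([(0, 0), (0, 0)])
        df, corr = ifng_loss_burden(calls)
        assert (df["ifng_loss_count"] == 0).all() and np.isnan(corr["rho"])

    def test_monotone_coupling_gives_rho_one(self):
        # loss count deterministically increasing with burden
        calls = self._calls([(0, 0), (1, 5), (2, 10), (3, 20), (4, 40)])
        _, corr = ifng_loss_burden(calls)
        assert corr["rho"] == pytest.approx(1.0)

    def test_empty_gene_set_errors(self):
        with pytest.raises(ValueError):
            ifng_loss_burden(self._calls([(1, 1)]), ifng_genes=())


class TestHlaLoh:
    def _cn(self, cn_a, cn_b, bins=20, pat="P", reg="R1"):
        rows = []
        for allele, vals in (("A*01:01", cn_a), ("A*02:01", cn_b)):
            arr = vals if hasattr(vals, "__len__") else [vals] * bins
            for i, v in enumerate(arr):
                rows.append({"patient_id": pat, "region_id": reg, "gene": "HLA-A",
                             "allele": allele, "bin": i, "cn": v})
        return pd.DataFrame(rows)

    def test_clear_loss_called(self):
        calls = call_hla_loh(self._cn(0.1, 1.9))
        byallele = calls.set_index("allele")
        assert byallele.loc["A*01:01", "lost"]
        assert not byallele.loc["A*02:01", "lost"]

    def test_balanced_alleles_not_lost(self):
        calls = call_hla_loh(self._cn(1.0, 1.0))
        assert not calls["lost"].any()

    def test_low_median_without_significance_not_lost(self):
        rng = np.random.default_rng(0)
        # wildly overlapping noisy bins: median < 0.5 but imbalance p large
        a = rng.uniform(0.0, 1.2, 6)
        a = a - a.mean() + 0.4
        b = rng.uniform(0.0, 1.2, 6)
        b = b - b.mean() + 0.55
        calls = call_hla_loh(self._cn(list(a), list(b), bins=6))
        row = calls.set_index("allele").loc["A*01:01"]
        if row["p_value"] >= 0.01:
            assert not row["lost"]

    def test_boundary_median_half_not_lost(self):
        calls = call_hla_loh(self._cn(0.5, 1.5))
        assert not calls.set_index("allele").loc["A*01:01", "lost"]
        calls2 = call_hla_loh(self._cn(0.499, 1.5))
        assert calls2.set_index("allele").loc["A*01:01", "lost"]

    def test_few_bins_flagged_low_confidence(self):
        calls = call_hla_loh(self._cn(0.1, 1.9, bins=4))
        assert calls["low_confidence"].all()

    def test_trunk_status_requires_all_regions(self):
        cn = pd.concat([
            self._cn(0.1, 1.9, reg="R1"), self._cn(0.1, 1.9, reg="R2")],
            ignore_index=True)
        status = tumor_hla_loh_status(call_hla_loh(cn))
        assert status.iloc[0]["hla_loh_status"] == "trunk"
        cn_branch = pd.concat([
            self._cn(0.1, 1.9, reg="R1"), self._cn(1.0, 1.0, reg="R2")],
            ignore_index=True)
        status = tumor_hla_loh_status(call_hla_loh(cn_branch))
        assert status.iloc[0]["hla_loh_status"] == "branch"


class TestLostAlleleBinding:
    def _hla(self, lost):
        return pd.DataFrame([{
            "patient_id": "P", "region_id": "R1", "gene": "HLA-A",
            "allele": "A*01:01", "median_allele_cn": 0.1, "p_value": 1e-6,
            "lost": lost, "low_confidence": False}])

    def test_half_binders_on_lost_allele(self):
        binders = pd.DataFrame([neo(i, 100.0, allele="A*01:01") for i in range(5)] +
                               [neo(i + 5, 100.0, allele="B*07:02") for i in range(5)])
        out = lost_allele_binding_fraction(binders, self._hla(True))
        assert out.iloc[0]["lost_allele_fraction"] == pytest.approx(0.5)

    @pytest.mark.parametrize("allele,expected", [("A*01:01", 1.0), ("B*07:02", 0.0)])
    def test_extremes(self, allele, expected):
        binders = pd.DataFrame([neo(1, 100.0, allele=allele)])
        out = lost_allele_binding_fraction(binders, self._hla(True))
        assert out.iloc[0]["lost_allele_fraction"] == expected

    def test_samples_without_loh_excluded(self):
        binders = pd.DataFrame([neo(1, 100.0)])
        assert len(lost_allele_binding_fraction(binders, self._hla(False))) == 0


def test_no_noise_cohort_recovers_planted_hla_loh(clean_cohort):
    _, cohort, truth = clean_cohort
    for pat, b in cohort.bundles.items():
        calls = call_hla_loh(b.hla_allele_cn)
        lost = set(calls[calls["lost"]]["allele"])
        expected = set(truth.hla_loh[truth.hla_loh["patient_id"] == pat]["allele"])
        assert lost == expected
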