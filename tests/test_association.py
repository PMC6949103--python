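"""Drug-sensitivity correlation (Fisher Z) and immune signature scoring."""

import math

import numpy as np
import pandas as pd
import pytest

from clockscape import AnalysisConfig, OmicsMatrix
from clockscape.association import (
    ImmuneSignature,
    default_signatures,
    drug_correlation,
    immune_correlation,
    score_immune_signatures,
)
from clockscape.core import CORE_CLOCK_GENES
from clockscape.simulate import PlantedTruth, generate_cohort


def _pair_matrices(rng, r, n=60, gene="CLOCK", drug="drug_01"):
    z1 = rng.standard_normal(n)
    z2 = r * z1 + math.sqrt(1 - r**2) * rng.standard_normal(n)
    cols = [f"cl{i}" for i in range(n)]
    expr = OmicsMatrix(pd.DataFrame([np.exp(z1)], index=[gene], columns=cols), kind="expression")
    auc = OmicsMatrix(pd.DataFrame([z2], index=[drug], columns=cols), kind="auc")
    return expr, auc


class TestDrugCorrelation:
    def test_null_pair(self, rng):
        expr, auc = _pair_matrices(rng, 0.0)
        cfg = AnalysisConfig(gene_panel=("CLOCK",))
        rec = drug_correlation(expr, auc, cfg)[0]
        assert rec.label == "none"
        assert rec.fisher_z == pytest.approx(math.atanh(rec.pearson_r), abs=1e-12)

    def test_fisher_p_close_to_exact_t_for_moderate_n(self, rng):
        expr, auc = _pair_matrices(rng, 0.3, n=60)
        cfg = AnalysisConfig(gene_panel=("CLOCK",))
        fisher = drug_correlation(expr, auc, cfg, p_method="fisher")[0]
        exact = drug_correlation(expr, auc, cfg, p_method="exact")[0]
        assert fisher.p_value == pytest.approx(exact.p_value, rel=0.10)

    def test_perfect_correlation_sentinel(self, caplog, rng):
        n = 20
        cols = [f"cl{i}" for i in range(n)]
        x = np.linspace(1, 5, n)
        expr = OmicsMatrix(pd.DataFrame([x], index=["CLOCK"], columns=cols), kind="expression")
        # AUC exactly affine in log2(x + 1), the scale the estimator uses
        auc = OmicsMatrix(pd.DataFrame([2 * np.log2(x + 1) + 1], index=["d"], columns=cols), kind="auc")
        with caplog.at_level("WARNING", logger="clockscape"):
            rec = drug_correlation(expr, auc, AnalysisConfig(gene_panel=("CLOCK",)))[0]
        assert rec.fisher_z == np.inf
        assert rec.p_value == 0.0

    def test_small_overlap_gives_missing(self, rng):
        expr, auc = _pair_matrices(rng, 0.5, n=5)
        rec = drug_correlation(expr, auc, AnalysisConfig(gene_panel=("CLOCK",)))[0]
        assert np.isnan(rec.pearson_r)

    def test_planted_resistance_and_sensitivity_labels(self):
        # strong planted effects so labels are deterministic at one seed;
        # power at the weaker rho = 0.4 is measured in the acceptance suite
        truth = PlantedTruth(
            drug_pairs=[("CLOCK", "drug_01", 0.6), ("PER2", "drug_03", -0.6)]
        )
        cfg = AnalysisConfig(seed=23)
        b = generate_cohort(cfg, truth=truth)
        recs = drug_correlation(b.cell_line_expression, b.auc, cfg)
        by_key = {(r.gene, r.drug): r for r in recs}
        assert by_key[("CLOCK", "drug_01")].label == "resistance"
        assert by_key[("PER2", "drug_03")].label == "sensitivity"

    def test_z_score_definition(self, rng):
        expr, auc = _pair_matrices(rng, 0.4, n=50)
        rec = drug_correlation(expr, auc, AnalysisConfig(gene_panel=("CLOCK",)))[0]
        assert rec.z_score == pytest.approx(rec.fisher_z * math.sqrt(rec.n - 3), abs=1e-12)


def loop_signature_oracle(expr_values, signatures):
    logx = np.log2(expr_values + 1.0)
    out = {}
    for sig in signatures:
        rows = []
        for g in sig.marker_genes:
            if g not in logx.index:
                continue
            x = logx.loc[g]
            rows.append((x - x.mean()) / x.std(ddof=1))
        out[sig.cell_type] = (
            pd.concat(rows, axis=1).mean(axis=1) if rows else pd.Series(np.nan, index=logx.columns)
        )
    return pd.DataFrame(out).T


class TestImmuneSignatures:
    def test_single_marker_equals_zscored_gene(self, rng):
        cols = [f"s{i}" for i in range(12)]
        vals = np.abs(rng.normal(10, 3, size=12))
        expr = OmicsMatrix(pd.DataFrame([vals], index=["CD8A"], columns=cols), kind="expression")
        sig = ImmuneSignature("CD8+ T cells", ("CD8A",))
        scores = score_immune_signatures(expr, [sig])
        logx = np.log2(vals + 1)
        expected = (logx - logx.mean()) / logx.std(ddof=1)
        assert np.allclose(scores.values.loc["CD8+ T cells"], expected)

    def test_identical_markers_give_shared_vector(self, rng):
        cols = [f"s{i}" for i in range(10)]
        vals = np.abs(rng.normal(5, 1, size=10))
        expr = OmicsMatrix(
            pd.DataFrame([vals, vals], index=["M1", "M2"], columns=cols), kind="expression"
        )
        sig = ImmuneSignature("X", ("M1", "M2"))
        scores = score_immune_signatures(expr, [sig])
        logx = np.log2(vals + 1)
        expected = (logx - logx.mean()) / logx.std(ddof=1)
        assert np.allclose(scores.values.loc["X"], expected)

    def test_matches_loop_oracle(self, rng):
        genes = [f"g{i}" for i in range(15)]
        cols = [f"s{i}" for i in range(20)]
        expr = OmicsMatrix(
            pd.DataFrame(np.abs(rng.normal(8, 2, size=(15, 20))), index=genes, columns=cols),
            kind="expression",
        )
        sigs = [
            ImmuneSignature("A", ("g0", "g1", "g2")),
            ImmuneSignature("B", ("g3", "g4")),
            ImmuneSignature("C", ("g5", "g6", "g7", "g8")),
        ]
        scores = score_immune_signatures(expr, sigs)
        oracle = loop_signature_oracle(expr.values, sigs)
        assert np.allclose(scores.values.to_numpy(), oracle.loc[scores.feature_ids, scores.sample_ids].to_numpy(), atol=1e-12)

    def test_unobserved_signature_missing_row(self, caplog, rng):
        cols = [f"s{i}" for i in range(8)]
        expr = OmicsMatrix(
            pd.DataFrame([np.abs(rng.normal(size=8))], index=["g0"], columns=cols),
            kind="expression",
        )
        with caplog.at_level("WARNING", logger="clockscape"):
            scores = score_immune_signatures(expr, [ImmuneSignature("X", ("a", "b"))])
        assert scores.values.loc["X"].isna().all()

    def test_default_markers_disjoint_from_clock_panel(self):
        for sig in default_signatures():
            assert not set(sig.marker_genes) & set(CORE_CLOCK_GENES)


class TestImmuneCorrelation:
    def test_monotone_transform_invariance(self, rng):
        cols = [f"s{i}" for i in range(30)]
        x = np.abs(rng.normal(10, 2, size=30))
        y = rng.normal(size=30)
        expr = OmicsMatrix(pd.DataFrame([x], index=["CLOCK"], columns=cols), kind="expression")
        scores = OmicsMatrix(pd.DataFrame([y], index=["CD8+ T cells"], columns=cols), kind="expression")
        scores_t = OmicsMatrix(pd.DataFrame([np.exp(y)], index=["CD8+ T cells"], columns=cols), kind="expression")
        cfg = AnalysisConfig(gene_panel=("CLOCK",))
        a = immune_correlation(expr, scores, cfg)[0]
        b = immune_correlation(expr, scores_t, cfg)[0]
        assert a.effect == pytest.approx(b.effect, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_permutation_breaks_pairing(self, default_cohort):
        cfg = AnalysisConfig(seed=11)
        expr = default_cohort.expression.subset_samples(default_cohort.tumor_ids)
        scores = default_cohort.immune_scores
        perm = scores.values.sample(frac=1.0, axis=1, random_state=0)
        perm.columns = scores.sample_ids
        recs = immune_correlation(expr, OmicsMatrix(perm, kind="expression"), cfg)
        rhos = [abs(r.effect) for r in recs if np.isfinite(r.effect)]
        assert np.mean(rhos) < 0.15

    def test_planted_pair_significant(self, default_cohort):
        cfg = AnalysisConfig(seed=11)
        expr = default_cohort.expression.subset_samples(default_cohort.tumor_ids)
        recs = immune_correlation(expr, default_cohort.immune_scores, cfg)
        by_key = {(r.gene, r.target): r for r in recs}
        rec = by_key[("CLOCK", "CD8+ T cells")]
        assert rec.effect > 0.2
        assert rec.fdr < cfg.fdr_threshold
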