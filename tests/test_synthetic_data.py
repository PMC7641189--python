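import numpy as np
import pandas as pd
import pytest

from plaquemap.io_formats import ValidationError
from plaquemap.synthetic_data import (
    GwasFixtureDesign,
    Population,
    SimulationDesign,
    TruthTable,
    gene_names,
    plant_candidate_set,
    plaque_preset,
    simulate_counts,
    simulate_gwas,
)


def _two_pop_design(**kw):
    pops = [
        Population("A", 30, list(range(0, 5)), kw.pop("fold", 4.0)),
        Population("B", 30, list(range(5, 10)), kw.pop("fold_b", 4.0)),
    ]
    return SimulationDesign(n_genes=50, populations=pops, seed=kw.pop("seed", 0), **kw)


class TestSimulateCounts:
    def test_same_seed_bit_identical(self):
        a, _, _ = simulate_counts(_two_pop_design(seed=5))
        b, _, _ = simulate_counts(_two_pop_design(seed=5))
        assert (a.counts != b.counts).nnz == 0

    def test_different_seed_differs(self):
        a, _, _ = simulate_counts(_two_pop_design(seed=5))
        b, _, _ = simulate_counts(_two_pop_design(seed=6))
        assert (a.counts != b.counts).nnz > 0

    def test_extreme_fold_confines_markers(self):
        # fold → ∞ approximated by 1e6: marker counts outside the home
        # population are negligible relative to inside it
        cm, clusters, truth = simulate_counts(_two_pop_design(fold=1e6, fold_b=1e6, seed=2))
        dense = cm.dense()
        labels = np.asarray([clusters.mapping[b] for b in cm.barcodes])
        for pop, rows in (("A", range(0, 5)), ("B", range(5, 10))):
            inside = dense[np.ix_(list(rows), labels == pop)].sum()
            outside = dense[np.ix_(list(rows), labels != pop)].sum()
            assert outside < 1e-4 * inside

    def test_nonmarker_mean_matches_generative_moments(self):
        # moment oracle: replay the documented rng draw order to recover
        # μ_g and s_c, then check the empirical mean of non-marker genes
        # against s̄·μ_g within 3 standard errors
        pops = [
            Population(f"P{j}", 60, list(range(j * 10, (j + 1) * 10)), 4.0)
            for j in range(5)
        ]
        d = SimulationDesign(n_genes=2000, populations=pops, dispersion=0.5, seed=11)
        cm, _, truth = simulate_counts(d)
        rng = np.random.default_rng(11)
        mu = rng.lognormal(d.baseline_mean_logmu, d.baseline_mean_logsigma, d.n_genes)
        s = rng.lognormal(0.0, d.libsize_logsigma, 300)
        dense = cm.dense()
        marker_idx = {cm.genes.index(g) for g in truth.marker_genes}
        checked = violations = 0
        for gi in range(60, 160):  # a slice of non-marker genes
            assert gi not in marker_idx
            cell_means = s * mu[gi]
            expected = cell_means.mean()
            var = (cell_means + d.dispersion * cell_means**2).sum() / 300**2
            observed = dense[gi].mean()
            checked += 1
            violations += abs(observed - expected) > 3 * np.sqrt(var)
        # ~0.3% of genes may exceed 3 SE by chance; allow a small margin
        assert checked == 100 and violations <= 3

    def test_mixed_cells_labelled_and_counted(self):
        d = _two_pop_design(mixed_fraction=0.25, seed=3)
        cm, clusters, _ = simulate_counts(d)
        n_mixed = sum(1 for v in clusters.mapping.values() if v == "Mixed")
        assert len(cm.barcodes) == 80 and n_mixed == 20  # 25% of the final matrix

    def test_mixed_parent_assignment(self):
        d = _two_pop_design(mixed_fraction=0.25, mixed_assignment="parent", seed=3)
        _, clusters, _ = simulate_counts(d)
        assert set(clusters.mapping.values()) == {"A", "B"}

    def test_marker_index_out_of_range_fatal(self):
        pops = [Population("A", 5, [60], 4.0), Population("B", 5, [1], 4.0)]
        with pytest.raises(ValidationError, match="≥ n_genes"):
            simulate_counts(SimulationDesign(n_genes=50, populations=pops))

    def test_overlapping_markers_fatal(self):
        pops = [Population("A", 5, [1], 4.0), Population("B", 5, [1], 4.0)]
        with pytest.raises(ValidationError, match="overlap"):
            simulate_counts(SimulationDesign(n_genes=50, populations=pops))


class TestPlaquePreset:
    def test_composition(self):
        cm, clusters, truth = simulate_counts(plaque_preset(seed=1))
        sizes = {l: clusters.size_of(l) for l in clusters.labels}
        total = sum(sizes.values())
        assert total == 3282 and len(sizes) == 14
        t_frac = sum(v for k, v in sizes.items() if k.startswith(("CD4T", "CD8T"))) / total
        my_frac = sum(v for k, v in sizes.items() if k.startswith(("Mac", "DC", "Mast"))) / total
        assert t_frac == pytest.approx(0.524, abs=0.01)
        assert my_frac == pytest.approx(0.185, abs=0.01)
        assert sizes["Mixed.2"] / total == pytest.approx(0.10, abs=0.01)
        assert len(truth.marker_genes) == 13 * 20


class TestSimulateGwas:
    def _fixture(self, planted, decoy_density=0.0, seed=0, n_genes=40):
        genes = gene_names(n_genes)
        return GwasFixtureDesign(
            genes=genes,
            chrom_lengths={"chr1": 7_000_000, "chr2": 7_000_000},
            planted_genes=planted,
            decoy_density=decoy_density,
            seed=seed,
        ), genes

    def test_zero_decoys_exact_variants(self):
        fix, genes = self._fixture([genes_i for genes_i in gene_names(40)[:3]])
        gwas, _, planted = simulate_gwas(fix)
        assert len(gwas) == 3
        assert (gwas.table["pval"] < 5e-8).all()
        assert planted == gene_names(40)[:3]

    def test_planted_variant_inside_gene_body(self):
        fix, genes = self._fixture(gene_names(40)[:5], seed=4)
        gwas, annot, planted = simulate_gwas(fix)
        ann = annot.table.set_index("gene")
        for gene in planted:
            row = gwas.table[gwas.table["variant_id"] == f"rs_sig_{gene}"].iloc[0]
            g = ann.loc[gene]
            # 1-based pos inside 0-based half-open [start, end)
            assert g["start"] < row["pos"] <= g["end"]
            assert row["chrom"] == g["chrom"]

    def test_decoys_are_null(self):
        fix, _ = self._fixture(gene_names(40)[:2], decoy_density=10.0, seed=1)
        gwas, _, _ = simulate_gwas(fix)
        decoys = gwas.table[gwas.table["variant_id"].str.startswith("rs_null")]
        assert len(decoys) == 140  # 10/Mb × 14 Mb
        assert (decoys["pval"] > 5e-8).all()

    def test_too_many_loci_fatal(self):
        fix, _ = self._fixture(gene_names(40)[:2])
        fix.n_loci = 3
        with pytest.raises(ValidationError, match="n_loci"):
            simulate_gwas(fix)

    def test_sig_range_must_be_genomewide(self):
        fix, _ = self._fixture(gene_names(40)[:2])
        fix.sig_pval_range = (1e-9, 1e-7)
        with pytest.raises(ValidationError, match="below"):
            simulate_gwas(fix)


class TestPlantCandidateSet:
    @pytest.fixture()
    def truth(self):
        genes = gene_names(200)
        rows = [
            {"gene": genes[j * 20 + i], "population": f"P{j}", "fold": 4.0}
            for j in range(3)
            for i in range(20)
        ]
        return TruthTable(genes, pd.DataFrame(rows))

    def test_zero_frac_disjoint_from_markers(self, truth):
        cand = plant_candidate_set(truth, "P1", 30, 0.0, seed=1)
        assert not set(cand) & truth.marker_genes

    def test_full_frac_subset_of_target(self, truth):
        cand = plant_candidate_set(truth, "P1", 15, 1.0, seed=1)
        assert set(cand) <= set(truth.markers_of("P1"))

    def test_exact_target_count(self, truth):
        cand = plant_candidate_set(truth, "P2", 30, 0.4, seed=3)
        assert len(cand) == 30
        assert len(set(cand) & set(truth.markers_of("P2"))) == 12

    def test_null_draw_covers_all_genes(self, truth):
        cand = plant_candidate_set(truth, None, 150, 0.0, seed=5)
        assert len(cand) == 150 and len(set(cand)) == 150

    def test_insufficient_markers_fatal(self, truth):
        with pytest.raises(ValidationError, match="markers"):
            plant_candidate_set(truth, "P1", 100, 0.5, seed=1)
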