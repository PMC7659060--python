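"""Generator contracts: determinism, conservation, divergence control,
pseudogene mechanisms and expression profile shapes."""

import filecmp

import numpy as np
import pytest

from famsurvey.duplication import CODON_TO_AA, STOP_CODONS, ng86_kaks
from famsurvey.expression import PATTERN_CLASSES
from famsurvey.io_formats import ValidationError
from famsurvey.synthetic_data import (
    CLASS_PROFILES,
    GroundTruth,
    SimConfig,
    simulate_expression,
    simulate_family,
)


class TestSimConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"wgd_target_ks": -0.1},
            {"pseudogene_fraction": 1.0},
            {"efficiency": 2.5},
            {"efficiency": 1.0},
            {"n_chromosomes": 3},
            {"tandem_cluster_sizes": (1,)},
        ],
    )
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SimConfig(**kwargs)

    def test_oversized_tandem_cluster_rejected(self):
        with pytest.raises(ValidationError, match="capacity"):
            simulate_family(
                SimConfig(n_ancestral_genes=4, n_chromosomes=4,
                          tandem_cluster_sizes=(10,))
            )


class TestSimulateFamily:
    def test_same_seed_byte_identical(self, tmp_path):
        for sub in ("one", "two"):
            config = SimConfig(seed=42)
            bundle = simulate_family(config)
            bundle.write(tmp_path / sub)
            matrix, qpcr = simulate_expression(bundle.ground_truth,
                                               config=config)
            matrix.to_tsv(tmp_path / sub / "expression.tsv")
            qpcr.to_tsv(tmp_path / sub / "qpcr.tsv")
        files = [p.name for p in (tmp_path / "one").iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "one", tmp_path / "two", files, shallow=False
        )
        assert not mismatch and not errors
        assert sorted(match) == sorted(files)

    def test_conservation_of_gene_counts(self, bundle, sim_config):
        extra = sum(s - 1 for s in sim_config.tandem_cluster_sizes)
        expected = 2 * (sim_config.n_ancestral_genes + extra)
        assert len(bundle.cds) == expected
        assert len(bundle.proteins) == expected
        assert len(bundle.ground_truth.pseudogenes) == round(
            sim_config.pseudogene_fraction * expected
        )

    def test_members_translate_without_internal_stops(self, bundle):
        pseudo = bundle.ground_truth.pseudogenes
        for gene_id, cds in bundle.cds:
            if gene_id in pseudo:
                continue
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            assert all(c not in STOP_CODONS for c in codons)
            assert all(c in CODON_TO_AA for c in codons)

    def test_zero_divergence_gives_identical_pairs(self):
        bundle = simulate_family(
            SimConfig(seed=3, wgd_target_ks=0.0, pseudogene_fraction=0.0,
                      tandem_cluster_sizes=())
        )
        cds = dict(bundle.cds)
        for pair in bundle.ground_truth.wgd_pairs():
            assert cds[pair.gene_a] == cds[pair.gene_b]
            assert pair.true_ks == 0.0

    def test_wgd_pairs_have_controlled_divergence(self, bundle, sim_config):
        cds = dict(bundle.cds)
        estimates = [
            ng86_kaks(cds[p.gene_a], cds[p.gene_b]).Ks
            for p in bundle.ground_truth.wgd_pairs()
        ]
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - sim_config.wgd_target_ks) <= 3 * se

    def test_tandem_pairs_more_diverged_than_wgd(self, bundle, sim_config):
        truth = bundle.ground_truth
        tandem = [p.true_ks for p in truth.duplicate_pairs
                  if p.origin == "tandem"]
        wgd = [p.true_ks for p in truth.wgd_pairs(False)]
        assert tandem, "default config should produce tandem arrays"
        assert np.mean(tandem) > np.mean(wgd)

    def test_pseudogene_mechanisms_both_present(self, bundle):
        reasons = set(bundle.ground_truth.pseudogenes.values())
        assert reasons == {"truncation", "domain_deletion"}
        proteins = dict(bundle.proteins)
        hits = {}
        for hit in bundle.domain_hits:
            hits.setdefault(hit.protein_id, []).append(hit)
        for gene, reason in bundle.ground_truth.pseudogenes.items():
            if reason == "truncation":
                assert len(proteins[gene]) < 150
            else:
                catalytic = [
                    h for h in hits[gene]
                    if h.domain in ("peptidase_C1",
                                    "peptidase_C1A_cathepsinB")
                ]
                assert catalytic and all(
                    h.coverage < 0.6 for h in catalytic
                )

    def test_domain_hits_stay_within_proteins(self, bundle):
        lengths = {p: len(s) for p, s in bundle.proteins}
        for hit in bundle.domain_hits:
            assert 1 <= hit.start <= hit.end <= lengths[hit.protein_id]

    def test_every_truth_gene_exists_in_fasta(self, bundle):
        ids = {g for g, _ in bundle.cds}
        truth = bundle.ground_truth
        for pair in truth.duplicate_pairs:
            assert pair.gene_a in ids and pair.gene_b in ids
            assert pair.true_ks >= 0
        assert set(truth.pseudogenes) <= ids
        assert set(truth.group_assignment) == ids


class TestSimulateExpression:
    def _truth(self, classes):
        return GroundTruth(expression_class=classes)

    def test_noise_free_profiles_match_design(self):
        truth = self._truth({f"g{i}": c for i, c in
                             enumerate(PATTERN_CLASSES)})
        config = SimConfig(seed=1, qpcr_noise_sd=0.0)
        _, qpcr = simulate_expression(truth, config=config)
        q = qpcr.quantities()
        for gene, cls in truth.expression_class.items():
            sub = q[q.gene_id == gene].sort_index()
            quantities = sub["quantity"].to_numpy()
            folds = quantities / quantities[0]
            assert np.allclose(folds, CLASS_PROFILES[cls], rtol=1e-6)

    def test_senescence_profile_monotone_with_max_last(self):
        truth = self._truth({"g": "senescence_up"})
        _, qpcr = simulate_expression(
            truth, config=SimConfig(seed=2, qpcr_noise_sd=0.0)
        )
        sub = qpcr.quantities().query("gene_id == 'g'")
        quantities = sub["quantity"].to_numpy()
        assert np.all(np.diff(quantities) > 0)

    def test_reference_gene_flat_ct_without_noise(self):
        truth = self._truth({"g": "flat"})
        _, qpcr = simulate_expression(
            truth, config=SimConfig(seed=3, qpcr_noise_sd=0.0)
        )
        for ref in truth.reference_genes:
            cts = qpcr.data.query("gene_id == @ref")["ct"]
            assert cts.nunique() == 1

    def test_unknown_class_rejected(self):
        with pytest.raises(ValidationError, match="unknown class"):
            simulate_expression(self._truth({"g": "chaotic"}),
                                config=SimConfig(seed=1))

    def test_rns_genes_recorded_and_present(self):
        truth = self._truth(
            {f"g{i}": "flat" for i in range(40)}
        )
        matrix, _ = simulate_expression(truth, config=SimConfig(seed=4))
        assert truth.rns_genes
        assert truth.rns_genes <= set(matrix.values.index)
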