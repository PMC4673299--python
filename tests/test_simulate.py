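import numpy as np
import pytest

from lncoexp import (SimulationParams, generate_annotation,
                     generate_expression, generate_gene_sets, generate_qpcr)
from lncoexp.network import genomic_distance
from lncoexp.qpcr import delta_delta_ct


class TestGenerateExpression:
    def test_determinism_bitwise(self, tiny_params):
        m1, d1, t1 = generate_expression(tiny_params, 123)
        m2, d2, t2 = generate_expression(tiny_params, 123)
        assert np.array_equal(m1.values, m2.values)
        assert np.array_equal(m1.flags, m2.flags)
        assert t1.de_probes == t2.de_probes
        assert t1.module_assignment == t2.module_assignment

    def test_different_seeds_differ(self, tiny_params):
        m1, _, _ = generate_expression(tiny_params, 1)
        m2, _, _ = generate_expression(tiny_params, 2)
        assert not np.array_equal(m1.values, m2.values)

    def test_shape_and_design(self, tiny_params):
        matrix, design, _ = generate_expression(tiny_params, 0)
        n = tiny_params.n_lncrna + tiny_params.n_mrna
        assert matrix.shape == (n, 2 * tiny_params.n_patients)
        assert len(design.pairs()) == tiny_params.n_patients

    def test_zero_de_fraction_plants_only_modules(self):
        params = SimulationParams(n_lncrna=50, n_mrna=50, module_size=4,
                                  de_fraction=0.0)
        _, _, truth = generate_expression(params, 5)
        assert set(truth.de_probes) == {
            p for p, m in truth.module_assignment.items() if m > 0}

    def test_oversized_modules_rejected(self):
        params = SimulationParams(n_lncrna=10, n_mrna=10, n_modules=3,
                                  module_size=10)
        with pytest.raises(ValueError, match="module"):
            generate_expression(params, 0)

    def test_planted_effect_calibration_closed_form(self):
        """With only replicate noise, realized log2FC of DE probes is an
        unbiased estimate of the planted effect with known standard
        error noise_sd*sqrt(2/3) per probe."""
        params = SimulationParams(n_lncrna=400, n_mrna=400, de_effect_log2=3,
                                  noise_sd=0.5, patient_sd=0.0,
                                  de_patient_sd=0.0, module_size=4)
        effects = []
        for seed in range(8):
            matrix, design, truth = generate_expression(params, seed)
            t_idx = [matrix.sample_ids.index(s)
                     for s in design.samples("tumor")]
            n_idx = [matrix.sample_ids.index(s)
                     for s in design.samples("normal")]
            fc = (matrix.values[:, t_idx].mean(axis=1)
                  - matrix.values[:, n_idx].mean(axis=1))
            idx = {p: i for i, p in enumerate(matrix.probe_ids)}
            effects += [abs(fc[idx[p]])
                        for p, m in truth.module_assignment.items() if m == 0
                        and p in truth.de_probes]
        effects = np.array(effects)
        se = 0.5 * np.sqrt(2 / 3) / np.sqrt(len(effects))
        assert abs(effects.mean() - 3.0) < 3 * se

    def test_module_members_nearly_collinear(self, tiny_params):
        matrix, _, truth = generate_expression(tiny_params, 11)
        frame = matrix.to_frame()
        rs = []
        members = truth.module_members(1)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                rs.append(abs(np.corrcoef(frame.loc[a], frame.loc[b])[0, 1]))
        assert np.median(rs) >= 0.99

    def test_flags_follow_threshold(self):
        params = SimulationParams(n_lncrna=50, n_mrna=50, module_size=4,
                                  flag_absent_threshold=8.0)
        matrix, _, _ = generate_expression(params, 3)
        assert np.array_equal(matrix.flags == "A",
                              matrix.values < 8.0)


class TestGenerateAnnotation:
    def test_single_chromosome_spacing_exceeds_100kb(self):
        params = SimulationParams(n_lncrna=10, n_mrna=10, module_size=4,
                                  n_chromosomes=1, cis_fraction=0.0)
        ann = generate_annotation(params, 0)
        ann = sorted(ann, key=lambda a: a.start)
        gaps = [b.start - a.end for a, b in zip(ann, ann[1:])]
        assert min(gaps) > 100_000

    def test_full_cis_fraction_places_module_pairs_close(self):
        params = SimulationParams(n_lncrna=30, n_mrna=30, module_size=6,
                                  cis_fraction=1.0)
        _, _, truth = generate_expression(params, 4)
        ann = {a.probe_id: a for a in generate_annotation(params, 4, truth)}
        anchor = ann[truth.module_members(1, "lncRNA")[0]]
        for mrna in truth.module_members(1, "mRNA"):
            assert ann[mrna].chrom == anchor.chrom
            assert genomic_distance(anchor, ann[mrna]) <= 100_000

    def test_determinism(self, tiny_params):
        a1 = generate_annotation(tiny_params, 9)
        a2 = generate_annotation(tiny_params, 9)
        assert a1 == a2

    def test_spans_non_overlapping(self, tiny_params):
        _, _, truth = generate_expression(tiny_params, 2)
        ann = generate_annotation(tiny_params, 2, truth)
        by_chrom: dict[str, list] = {}
        for a in ann:
            by_chrom.setdefault(a.chrom, []).append(a)
        for records in by_chrom.values():
            records.sort(key=lambda a: a.start)
            for a, b in zip(records, records[1:]):
                assert a.end <= b.start


class TestGenerateGeneSets:
    def test_linked_sets_contain_module_mrnas(self, tiny_params):
        _, _, truth = generate_expression(tiny_params, 6)
        terms, tfs = generate_gene_sets(truth, tiny_params, 6)
        for coll, links in ((terms, truth.term_links),
                            (tfs, truth.tf_links)):
            assert len(links) == tiny_params.n_modules
            for sid, m in links.items():
                assert set(truth.module_members(m, "mRNA")) <= coll.sets[sid]
                assert len(coll.sets[sid]) == tiny_params.set_size

    def test_set_size_smaller_than_module_rejected(self):
        params = SimulationParams(n_lncrna=50, n_mrna=50, module_size=20,
                                  set_size=5)
        _, _, truth = generate_expression(params, 0)
        with pytest.raises(ValueError, match="set_size"):
            generate_gene_sets(truth, params, 0)

    def test_unlinked_set_overlap_near_hypergeometric_mean(self, tiny_params):
        """Random sets overlap a module like a uniform draw: mean k over
        seeds approximates n*K/N."""
        overlaps = []
        for seed in range(30):
            _, _, truth = generate_expression(tiny_params, seed)
            terms, _ = generate_gene_sets(truth, tiny_params, seed)
            module = set(truth.module_members(1, "mRNA"))
            unlinked = [sid for sid in terms.sets
                        if sid not in truth.term_links]
            for sid in unlinked:
                overlaps.append(len(terms.sets[sid] & module))
        n, K, N = tiny_params.set_size, 3, tiny_params.n_mrna
        expected = n * K / N
        sd = np.sqrt(expected)   # conservative spread bound
        assert abs(np.mean(overlaps) - expected) < 3 * sd / np.sqrt(
            len(overlaps))


class TestGenerateQpcr:
    def test_zero_noise_recovers_planted_effect_exactly(self, tiny_params):
        import dataclasses
        params = dataclasses.replace(tiny_params, ct_noise_sd=0.0,
                                     qpcr_patient_sd=0.0)
        _, _, truth = generate_expression(params, 8)
        probe = next(iter(truth.de_probes))
        table = generate_qpcr(truth, params, 8, [probe])
        rel = delta_delta_ct(table, "GAPDH", probe)
        assert len(rel) == params.qpcr_n_patients
        for r in rel:
            assert r.log2_fold == pytest.approx(truth.de_probes[probe],
                                                abs=1e-12)

    def test_planted_effect_four_gives_fold_sixteen(self, tiny_params):
        import dataclasses
        params = dataclasses.replace(tiny_params, ct_noise_sd=0.0,
                                     qpcr_patient_sd=0.0)
        _, _, truth = generate_expression(params, 8)
        probe = next(iter(truth.all_probes))
        truth.de_probes[probe] = 4.0
        table = generate_qpcr(truth, params, 8, [probe])
        rel = delta_delta_ct(table, "GAPDH", probe)
        assert rel[0].fold_change == pytest.approx(16.0)
        assert rel[0].delta_delta_ct == pytest.approx(-4.0)

    def test_null_probe_gives_unit_fold(self, tiny_params):
        import dataclasses
        params = dataclasses.replace(tiny_params, ct_noise_sd=0.0)
        _, _, truth = generate_expression(params, 8)
        null_probe = next(p for p in truth.all_probes
                          if p not in truth.de_probes)
        table = generate_qpcr(truth, params, 8, [null_probe])
        rel = delta_delta_ct(table, "GAPDH", null_probe)
        assert all(r.fold_change == pytest.approx(1.0) for r in rel)

    def test_unknown_probe_rejected(self, tiny_params):
        _, _, truth = generate_expression(tiny_params, 8)
        with pytest.raises(ValueError, match="ghost"):
            generate_qpcr(truth, tiny_params, 8, ["ghost"])

    def test_determinism(self, tiny_params):
        _, _, truth = generate_expression(tiny_params, 8)
        t1 = generate_qpcr(truth, tiny_params, 8)
        t2 = generate_qpcr(truth, tiny_params, 8)
        assert t1.equals(t2)
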