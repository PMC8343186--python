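import numpy as np
import pytest
from hypothesis import given, strategies as st

from quadhet import segregation as seg
from quadhet.errors import ConfigError
from quadhet.io import DEFAULT_BRCA2_DOMAINS, DomainTable, MISSING
from quadhet.simulate import (
    SimulationConfig,
    plant_compound_het,
    simulate_annotations,
    simulate_family_genotypes,
)

from conftest import make_annotation, make_matrix


class TestLabelInheritance:
    @pytest.mark.parametrize("child,mother,father,label", [
        (1, 1, 0, "maternal"),
        (1, 0, 1, "paternal"),
        (1, 0, 0, "de_novo"),
        (1, 1, 1, "biparental_ambiguous"),
        (1, 2, 0, "maternal"),
        (2, 1, 1, "biparental_ambiguous"),
        (0, 1, 1, "untransmitted"),
        (0, 0, 0, "untransmitted"),
        (1, MISSING, 0, "unresolvable_missing"),
        (MISSING, 1, 0, "unresolvable_missing"),
        (1, 1, MISSING, "unresolvable_missing"),
    ])
    def test_examples(self, child, mother, father, label):
        assert seg.label_inheritance(child, mother, father) == label

    @given(st.sampled_from([0, 1, 2, MISSING]),
           st.sampled_from([0, 1, 2, MISSING]),
           st.sampled_from([0, 1, 2, MISSING]))
    def test_total_function(self, c, m, f):
        assert seg.label_inheritance(c, m, f) in seg.INHERITANCE_LABELS


def toy_fixture():
    """Six hand-crafted sites for the maternal cascade oracle.

    s0/s1: rare nonsynonymous/stopgain shared-maternal in driver gene DRV1
    s2:    common nonsynonymous shared-maternal in DRV1
    s3:    rare synonymous, mother-only, untransmitted
    s4:    paternal-origin site
    s5:    de novo in both children
    """
    matrix = make_matrix([
        [0, 1, 1, 1],
        [0, 1, 1, 1],
        [0, 1, 1, 1],
        [0, 1, 0, 0],
        [1, 0, 1, 1],
        [0, 0, 1, 1],
    ])
    keys = matrix.site_keys()
    ann = {
        keys[0]: make_annotation(keys[0], "DRV1", "exonic_nonsynonymous",
                                 {"a": 0.001, "b": 0.002}),
        keys[1]: make_annotation(keys[1], "DRV1", "stopgain",
                                 {"a": 0.0005, "b": None}),
        keys[2]: make_annotation(keys[2], "DRV1", "exonic_nonsynonymous",
                                 {"a": 0.3, "b": 0.25}),
        keys[3]: make_annotation(keys[3], "G2", "synonymous",
                                 {"a": 0.001, "b": 0.001}),
        keys[4]: make_annotation(keys[4], "DRV1", "exonic_nonsynonymous",
                                 {"a": 0.002, "b": 0.002}),
        keys[5]: make_annotation(keys[5], "G3", "stopgain",
                                 {"a": 0.001, "b": 0.001}),
    }
    return matrix, ann, keys


class TestBranchFilter:
    def test_toy_cascade_oracle(self, quad_pedigree):
        matrix, ann, keys = toy_fixture()
        res = seg.branch_filter(matrix, ann, quad_pedigree,
                                seg.maternal_criteria(), ["DRV1"])
        assert list(res.step_counts.values()) == [3, 2, 2, 2]
        assert res.survivors == [keys[0], keys[1]]

    def test_disabled_filters_identity(self, quad_pedigree):
        matrix, ann, keys = toy_fixture()
        crit = seg.BranchCriteria(parent="mother", maf_threshold=None)
        res = seg.branch_filter(matrix, ann, quad_pedigree, crit)
        assert res.survivors == [keys[0], keys[1], keys[2]]
        assert list(res.step_counts.values()) == [3, 3, 3, 3]

    def test_empty_matrix(self, quad_pedigree):
        matrix = make_matrix(np.empty((0, 4), dtype=np.int8))
        res = seg.branch_filter(matrix, {}, quad_pedigree,
                                seg.maternal_criteria(), ["DRV1"])
        assert res.survivors == []
        assert list(res.step_counts.values()) == [0, 0, 0, 0]

    def test_driver_screen_without_drivers_fatal(self, quad_pedigree):
        matrix, ann, _ = toy_fixture()
        with pytest.raises(ConfigError):
            seg.branch_filter(matrix, ann, quad_pedigree,
                              seg.maternal_criteria(), [])

    def test_all_missing_af_passes(self, quad_pedigree):
        matrix = make_matrix([[0, 1, 1, 1]])
        k = matrix.site_keys()[0]
        ann = {k: make_annotation(k, "DRV1", "stopgain", {"a": None, "b": None})}
        res = seg.branch_filter(matrix, ann, quad_pedigree,
                                seg.maternal_criteria(), ["DRV1"])
        assert res.survivors == [k]

    def test_conservative_missing_fails_shared(self, quad_pedigree):
        matrix = make_matrix([[0, MISSING, 1, 1]])
        res = seg.branch_filter(matrix, {}, quad_pedigree,
                                seg.BranchCriteria("mother", maf_threshold=None))
        assert res.survivors == []
        permissive = seg.BranchCriteria("mother", maf_threshold=None,
                                        missing_policy="permissive")
        res2 = seg.branch_filter(matrix, {}, quad_pedigree, permissive)
        assert len(res2.survivors) == 1

    def test_other_parent_carrier_excluded(self, quad_pedigree):
        matrix = make_matrix([[1, 1, 1, 1]])
        res = seg.branch_filter(matrix, {}, quad_pedigree,
                                seg.BranchCriteria("mother", maf_threshold=None))
        assert res.survivors == []

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_threshold(self, quad_pedigree, seed):
        cfg = SimulationConfig(seed=seed, n_sites=500)
        matrix, af = simulate_family_genotypes(cfg, quad_pedigree)
        matrix, _ = plant_compound_het(matrix, cfg)
        ann = simulate_annotations(matrix, cfg, af)
        prev = None
        for thr in (0.001, 0.01, 0.05):
            crit = seg.BranchCriteria("mother", maf_threshold=thr)
            cur = set(seg.branch_filter(matrix, ann, quad_pedigree, crit).survivors)
            if prev is not None:
                assert prev <= cur
            prev = cur

    @pytest.mark.parametrize("seed", range(5))
    def test_whitelist_shrink_monotone(self, quad_pedigree, seed):
        cfg = SimulationConfig(seed=seed, n_sites=500)
        matrix, af = simulate_family_genotypes(cfg, quad_pedigree)
        ann = simulate_annotations(matrix, cfg, af)
        wide = seg.BranchCriteria("mother", maf_threshold=0.05,
                                  consequence_whitelist=seg.EXONIC_WHITELIST)
        narrow = seg.BranchCriteria("mother", maf_threshold=0.05,
                                    consequence_whitelist=frozenset({"stopgain"}))
        s_wide = set(seg.branch_filter(matrix, ann, quad_pedigree, wide).survivors)
        s_narrow = set(seg.branch_filter(matrix, ann, quad_pedigree, narrow).survivors)
        assert s_narrow <= s_wide

    @pytest.mark.parametrize("seed", range(5))
    def test_parent_swap_symmetry(self, quad_pedigree, seed):
        cfg = SimulationConfig(seed=seed, n_sites=300)
        matrix, _ = simulate_family_genotypes(cfg, quad_pedigree)
        swapped = make_matrix(matrix.dosage[:, [1, 0, 2, 3]])
        swapped.sites = matrix.sites
        as_mother = seg.branch_filter(matrix, {}, quad_pedigree,
                                      seg.BranchCriteria("mother", maf_threshold=None))
        as_father = seg.branch_filter(swapped, {}, quad_pedigree,
                                      seg.BranchCriteria("father", maf_threshold=None))
        assert as_mother.survivors == as_father.survivors


def brute_force_compound_het(maternal, paternal, annotations):
    """Oracle: exhaustive enumeration over (gene, maternal site, paternal
    site) triples; overlapping sites are excluded from both branches."""
    overlap = set(maternal) & set(paternal)
    mat = [k for k in maternal if k not in overlap and k in annotations]
    pat = [k for k in paternal if k not in overlap and k in annotations]
    found = {}
    for sm in mat:
        for sp in pat:
            g = annotations[sm].gene
            if sm != sp and g == annotations[sp].gene:
                found.setdefault(g, (set(), set()))
                found[g][0].add(sm)
                found[g][1].add(sp)
    return found


class TestDetectCompoundHet:
    def test_forced_by_definition(self):
        ann = {
            "s1": make_annotation("s1", "g1"),
            "s2": make_annotation("s2", "g2"),
            "s3": make_annotation("s3", "g1"),
        }
        out = seg.detect_compound_het(["s1", "s2"], ["s3"], ann)
        assert [(c.gene, c.maternal_alleles, c.paternal_alleles) for c in out] == \
            [("g1", ["s1"], ["s3"])]

    def test_disjoint_genes_empty(self):
        ann = {"s1": make_annotation("s1", "g1"), "s2": make_annotation("s2", "g2")}
        assert seg.detect_compound_het(["s1"], ["s2"], ann) == []

    def test_overlapping_site_excluded(self):
        ann = {"s1": make_annotation("s1", "g1"), "s2": make_annotation("s2", "g1")}
        assert seg.detect_compound_het(["s1"], ["s1", "s2"], ann) == []
        out = seg.detect_compound_het(["s1", "s2"], ["s2", "s1"], ann)
        assert out == []

    def test_lof_sorts_first(self):
        ann = {
            "a1": make_annotation("a1", "gA", "exonic_nonsynonymous"),
            "a2": make_annotation("a2", "gA", "exonic_nonsynonymous"),
            "b1": make_annotation("b1", "gB", "stopgain"),
            "b2": make_annotation("b2", "gB", "exonic_nonsynonymous"),
        }
        out = seg.detect_compound_het(["a1", "b1"], ["a2", "b2"], ann)
        assert [c.gene for c in out] == ["gB", "gA"]
        assert out[0].has_lof and not out[1].has_lof

    @pytest.mark.parametrize("seed", range(20))
    def test_random_instances_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_sites = int(rng.integers(5, 50))
        n_genes = int(rng.integers(1, 8))
        keys = [f"s{i}" for i in range(n_sites)]
        ann = {k: make_annotation(k, f"g{rng.integers(n_genes)}") for k in keys}
        maternal = [k for k in keys if rng.random() < 0.3]
        paternal = [k for k in keys if rng.random() < 0.3]
        expected = brute_force_compound_het(maternal, paternal, ann)
        got = seg.detect_compound_het(maternal, paternal, ann)
        assert {c.gene for c in got} == set(expected)
        for c in got:
            assert set(c.maternal_alleles) == expected[c.gene][0]
            assert set(c.paternal_alleles) == expected[c.gene][1]


class TestPredictorConsensus:
    def test_all_benign(self):
        rec = make_annotation("s", calls={p: "benign" for p in
                                          ("SIFT", "PolyPhen2", "MutationTaster", "M-CAP")})
        call = seg.predictor_consensus(rec)
        assert call.verdict == "benign"
        assert (call.n_damaging, call.n_available) == (0, 4)

    def test_majority_of_available(self):
        rec = make_annotation("s", calls={"SIFT": "damaging",
                                          "PolyPhen2": "damaging",
                                          "MutationTaster": "benign"})
        call = seg.predictor_consensus(rec)
        assert call.verdict == "damaging"
        assert (call.n_damaging, call.n_available) == (2, 3)

    def test_tie_uncertain(self):
        rec = make_annotation("s", calls={"SIFT": "damaging", "PolyPhen2": "benign"})
        assert seg.predictor_consensus(rec).verdict == "uncertain"

    def test_nothing_available_uncertain(self):
        assert seg.predictor_consensus(make_annotation("s")).verdict == "uncertain"


class TestDomains:
    def test_truncation_at_871(self):
        res = seg.truncation_retained_domains(871, DEFAULT_BRCA2_DOMAINS)
        assert res.retained == ["PALB2 binding", "P/CAF binding"]
        assert res.partial == []

    def test_truncation_at_1(self):
        res = seg.truncation_retained_domains(1, DEFAULT_BRCA2_DOMAINS)
        assert res.retained == [] and res.partial == []

    def test_truncation_beyond_length(self):
        res = seg.truncation_retained_domains(100_000, DEFAULT_BRCA2_DOMAINS)
        assert len(res.retained) == 6

    def test_partial_overlap_reported(self):
        table = DomainTable([("mid", 10, 30)])
        res = seg.truncation_retained_domains(20, table)
        assert res.retained == [] and res.partial == ["mid"]

    def test_empty_table(self):
        res = seg.truncation_retained_domains(871, DomainTable([]))
        assert res.retained == [] and res.partial == []

    @pytest.mark.parametrize("residue,expected", [
        (372, ["P/CAF binding"]),
        (289, []),
        (290, ["P/CAF binding"]),
        (453, ["P/CAF binding"]),
        (454, []),
    ])
    def test_locate(self, residue, expected):
        assert seg.locate_in_domain(residue, DEFAULT_BRCA2_DOMAINS) == expected


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_planted_gene_recovered(self, quad_pedigree, seed):
        cfg = SimulationConfig(seed=seed)
        matrix, af = simulate_family_genotypes(cfg, quad_pedigree)
        matrix, truth = plant_compound_het(matrix, cfg)
        ann = simulate_annotations(matrix, cfg, af)
        drivers = [cfg.planted_gene, "ALK", "TP53"]
        mat = seg.branch_filter(matrix, ann, quad_pedigree,
                                seg.maternal_criteria(), drivers)
        pat = seg.branch_filter(matrix, ann, quad_pedigree,
                                seg.paternal_criteria(), drivers)
        cands = seg.detect_compound_het(mat.survivors, pat.survivors, ann, drivers)
        genes = [c.gene for c in cands]
        assert truth.gene in genes
        hit = cands[genes.index(truth.gene)]
        assert truth.maternal_site_key in hit.maternal_alleles
        assert truth.paternal_site_key in hit.paternal_alleles
        assert hit.has_lof and hit.driver_gene
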