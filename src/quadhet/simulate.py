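"""Synthetic fixture bundles: pedigree, genotypes, annotations, driver list,
gene sets and expression counts, with a planted causal compound-het gene.

Everything is driven by one ``SimulationConfig``; sub-stage RNG streams are
derived deterministically from the single seed, so an identical config
always produces a byte-identical bundle.

The allele-frequency spectrum and gene model are deliberate stand-ins (no
distributional description of real cohort data is reproduced): a mixture of
a rare component below 1% and a common component, with genes as contiguous
bins of sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import yaml

from .errors import ConfigError, StageError
from .io import (
    AnnotationRecord,
    ExpressionMatrix,
    GeneSetCollection,
    GenotypeMatrix,
    Pedigree,
    PedigreeMember,
    PREDICTORS,
    VariantSite,
    write_annotations,
    write_counts,
    write_gene_list,
    write_gene_sets,
    write_pedigree,
    write_vcf,
)

_BASES = np.array(list("ACGT"))

DEFAULT_CONSEQUENCE_PROPORTIONS: dict[str, float] = {
    "exonic_nonsynonymous": 0.25,
    "synonymous": 0.30,
    "noncoding": 0.30,
    "stopgain": 0.05,
    "frameshift": 0.04,
    "startloss": 0.01,
    "other": 0.05,
}

#: AF source names emulating a two-cohort annotation sidecar.
AF_SOURCES = ("1kg_asian", "exac")

DEFAULT_DRIVERS = ("ALK", "TP53", "MYCN")


@dataclass
class SimulationConfig:
    seed: int  # required: no silent nondeterminism
    n_sites: int = 2000
    sites_per_gene: int = 10
    rare_fraction: float = 0.85
    rare_af_range: tuple[float, float] = (0.0005, 0.01)
    common_af_range: tuple[float, float] = (0.01, 0.5)
    consequence_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_PROPORTIONS))
    de_novo_rate: float = 0.0
    planted_gene: str = "BRCA2"
    planted_maternal_af: float = 0.005  # must stay below 0.01 (rare branch)
    planted_paternal_af: float = 0.28  # common missense, no MAF restriction
    damaging_prob_lof: float = 0.9
    damaging_prob_other: float = 0.2
    predictor_missing_prob: float = 0.15
    # expression side
    n_expression_samples: int = 20  # per group
    n_expression_genes: int = 1000
    nb_dispersion: float = 0.1
    expression_effect_size: float = 4.0
    planted_pathways: tuple[str, ...] = ("DDR",)
    germline_proxy_samples: tuple[str, ...] = ("C1",)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is required")
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.sites_per_gene < 2:
            raise ConfigError("sites_per_gene must be >= 2 (compound het needs 2)")
        total = sum(self.consequence_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"consequence proportions sum to {total}, not 1")
        if not (0.0 <= self.de_novo_rate <= 1.0):
            raise ConfigError("de_novo_rate outside [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if not (0.0 < self.planted_maternal_af < 0.01):
            raise ConfigError("planted maternal AF must lie in (0, 0.01)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("rare_af_range", "common_af_range", "planted_pathways",
                    "germline_proxy_samples"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # one stream per stage, all derived from the single bundle seed
    return np.random.default_rng([config.seed, stage])


def default_quad_pedigree() -> Pedigree:
    """Father F1, mother M1, affected daughter C1, affected son C2."""
    return Pedigree([
        PedigreeMember("FAM1", "F1", "0", "0", "male", "unaffected"),
        PedigreeMember("FAM1", "M1", "0", "0", "female", "unaffected"),
        PedigreeMember("FAM1", "C1", "F1", "M1", "female", "affected"),
        PedigreeMember("FAM1", "C2", "F1", "M1", "male", "affected"),
    ])


def gene_assignment(config: SimulationConfig) -> list[str]:
    """Gene symbol per site: contiguous bins, planted gene at the middle bin."""
    n_genes = -(-config.n_sites // config.sites_per_gene)
    names = [f"G{i:04d}" for i in range(n_genes)]
    names[n_genes // 2] = config.planted_gene
    return [names[i // config.sites_per_gene] for i in range(config.n_sites)]


def planted_site_indices(config: SimulationConfig) -> tuple[int, int]:
    """(maternal, paternal) site indices: first two sites of the planted bin."""
    genes = gene_assignment(config)
    idx = [i for i, g in enumerate(genes) if g == config.planted_gene]
    if len(idx) < 2:
        raise StageError(f"planted gene {config.planted_gene!r} has < 2 sites")
    return idx[0], idx[1]


def simulate_family_genotypes(config: SimulationConfig, pedigree: Pedigree,
                              ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw quad genotypes: Hardy-Weinberg parents, Mendelian children.

    Returns the matrix (sample order = pedigree order) and the true
    population AF per site.  Planted-site AFs are overridden from config so
    the downstream annotation stage stays consistent with the plant.
    """
    if len(pedigree.members) != 4 or len(pedigree.affected_children) != 2:
        raise ConfigError("genotype simulation expects a quad pedigree")
    n = config.n_sites
    rng = _rng(config, 1)

    lo_r, hi_r = config.rare_af_range
    lo_c, hi_c = config.common_af_range
    is_rare = rng.random(n) < config.rare_fraction
    af = np.where(is_rare, rng.uniform(lo_r, hi_r, n), rng.uniform(lo_c, hi_c, n))
    i_mat, i_pat = planted_site_indices(config)
    af[i_mat] = config.planted_maternal_af
    af[i_pat] = config.planted_paternal_af

    father = rng.binomial(2, af)
    mother = rng.binomial(2, af)
    children = []
    for _ in pedigree.affected_children:
        from_father = (rng.random(n) < father / 2.0).astype(np.int8)
        from_mother = (rng.random(n) < mother / 2.0).astype(np.int8)
        if config.de_novo_rate > 0:
            flip = rng.random(n) < config.de_novo_rate
            which = rng.integers(0, 2, n)  # which transmitted allele mutates
            from_father = np.where(flip & (which == 0), 1 - from_father, from_father)
            from_mother = np.where(flip & (which == 1), 1 - from_mother, from_mother)
        children.append(from_father + from_mother)

    by_sample = {pedigree.father_id: father, pedigree.mother_id: mother}
    for cid, dose in zip(pedigree.affected_children, children):
        by_sample[cid] = dose
    dosage = np.stack([by_sample[s] for s in pedigree.sample_ids], axis=1)

    ref_idx = rng.integers(0, 4, n)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + rng.integers(1, 4, n)) % 4]
    sites = [VariantSite("1", 10_000 + 100 * i, str(ref[i]), str(alt[i]))
             for i in range(n)]
    return GenotypeMatrix(sites, list(pedigree.sample_ids),
                          dosage.astype(np.int8)), af


@dataclass(frozen=True)
class PlantedTruth:
    gene: str
    maternal_site_key: str
    paternal_site_key: str


def plant_compound_het(matrix: GenotypeMatrix, config: SimulationConfig,
                       ) -> tuple[GenotypeMatrix, PlantedTruth]:
    """Force the causal genotype pattern onto the two planted sites.

    Maternal site: mother het, father hom-ref, both children het.  Paternal
    site: mirrored.  Idempotent; the input matrix is modified in place and
    returned together with the truth record.
    """
    i_mat, i_pat = planted_site_indices(config)
    if max(i_mat, i_pat) >= matrix.n_sites:
        raise StageError("matrix smaller than planted site indices")
    ped_order = matrix.samples  # F1, M1, C1, C2 order from the quad pedigree
    if len(ped_order) != 4:
        raise StageError("planting expects a 4-sample matrix")
    matrix.dosage[i_mat] = [0, 1, 1, 1]
    matrix.dosage[i_pat] = [1, 0, 1, 1]
    return matrix, PlantedTruth(config.planted_gene,
                                matrix.sites[i_mat].key,
                                matrix.sites[i_pat].key)


def simulate_annotations(matrix: GenotypeMatrix, config: SimulationConfig,
                         true_af: np.ndarray) -> dict[str, AnnotationRecord]:
    """Annotation sidecar records for every site in the matrix.

    Observed AFs are the true AFs under bounded multiplicative noise
    (+/-20%); predictor damaging-call probability is enriched for stop-gain
    and planted sites.  The planted maternal site is always stop-gain with
    every AF source below 0.01; the planted paternal site is always an
    exonic missense at its configured common frequency.
    """
    n = matrix.n_sites
    if len(true_af) != n:
        raise StageError("true_af length mismatch")
    rng = _rng(config, 2)
    genes = gene_assignment(config)[:n]
    i_mat, i_pat = planted_site_indices(config)

    props = config.consequence_proportions
    cons = rng.choice(list(props), size=n, p=list(props.values()))
    cons[i_mat] = "stopgain"
    cons[i_pat] = "exonic_nonsynonymous"

    noise = rng.uniform(0.8, 1.2, size=(n, len(AF_SOURCES)))
    afs = np.clip(true_af[:, None] * noise, 1e-6, 1.0)
    afs[i_mat] = np.minimum(afs[i_mat], 0.0099)  # planted maternal stays rare

    lof_like = (cons == "stopgain")
    lof_like[[i_mat, i_pat]] = True
    p_damaging = np.where(lof_like, config.damaging_prob_lof,
                          config.damaging_prob_other)
    available = rng.random((n, len(PREDICTORS))) >= config.predictor_missing_prob
    damaging = rng.random((n, len(PREDICTORS))) < p_damaging[:, None]

    records: dict[str, AnnotationRecord] = {}
    for i, site in enumerate(matrix.sites):
        calls = {p: ("damaging" if damaging[i, j] else "benign")
                 for j, p in enumerate(PREDICTORS) if available[i, j]}
        records[site.key] = AnnotationRecord(
            site_key=site.key,
            gene=genes[i],
            consequence=str(cons[i]),
            af_sources={s: float(afs[i, j]) for j, s in enumerate(AF_SOURCES)},
            predictor_calls=calls,
        )
    return records


def default_gene_sets(config: SimulationConfig, n_decoy_sets: int = 9,
                      set_size: int = 50) -> GeneSetCollection:
    """Planted pathway set(s) plus decoy sets over the expression genes."""
    sets: dict[str, list[str]] = {}
    for name in config.planted_pathways:
        sets[name] = [f"{name}_{j:04d}" for j in range(set_size - 1)]
        sets[name].append(config.planted_gene)
    for i in range(n_decoy_sets):
        sets[f"PW{i:02d}"] = [f"PW{i:02d}_{j:04d}" for j in range(set_size)]
    return GeneSetCollection(sets)


def expression_gene_names(config: SimulationConfig,
                          gene_sets: GeneSetCollection) -> list[str]:
    names: list[str] = []
    for members in gene_sets.sets.values():
        for g in members:
            if g not in names:
                names.append(g)
    i = 0
    while len(names) < config.n_expression_genes:
        names.append(f"BG{i:04d}")
        i += 1
    return names


def simulate_expression(config: SimulationConfig,
                        gene_sets: GeneSetCollection,
                        effect_size: float | None = None,
                        ) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Negative-binomial counts with a planted pathway-level group effect.

    Two groups of ``n_expression_samples``; genes in the planted pathways
    get their case-group mean multiplied by the effect size.  Returns the
    matrix and a sample -> group label map.
    """
    if effect_size is None:
        effect_size = config.expression_effect_size
    rng = _rng(config, 3)
    genes = expression_gene_names(config, gene_sets)
    n_genes, n_per = len(genes), config.n_expression_samples
    if n_per < 2:
        raise ConfigError("n_expression_samples must be >= 2 per group")

    planted = set().union(*(gene_sets.sets[p] for p in config.planted_pathways
                            if p in gene_sets.sets))
    base_mean = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n_genes)
    shift = np.array([effect_size if g in planted else 1.0 for g in genes])

    samples = [f"case_{i:03d}" for i in range(n_per)] + \
              [f"ctrl_{i:03d}" for i in range(n_per)]
    mu = np.concatenate([np.tile((base_mean * shift)[:, None], (1, n_per)),
                         np.tile(base_mean[:, None], (1, n_per))], axis=1)
    # NB with var = mu + alpha * mu^2  <=>  shape r = 1/alpha, p = r/(r+mu)
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    labels = {s: ("case" if s.startswith("case") else "control") for s in samples}
    return ExpressionMatrix(genes, samples, counts), labels


# ---------------------------------------------------------------------------
# bundle writer


BUNDLE_FILES = {
    "pedigree": "family.ped",
    "vcf": "variants.vcf",
    "annotations": "annotations.tsv",
    "drivers": "drivers.txt",
    "gene_sets": "gene_sets.gmt",
    "counts": "counts.tsv",
    "groups": "sample_groups.tsv",
    "truth": "truth.tsv",
    "meta": "bundle_meta.yaml",
}


def simulate_bundle(config: SimulationConfig):
    """Run every simulation stage in memory; returns a dict of artifacts."""
    pedigree = default_quad_pedigree()
    matrix, true_af = simulate_family_genotypes(config, pedigree)
    matrix, truth = plant_compound_het(matrix, config)
    annotations = simulate_annotations(matrix, config, true_af)
    gene_sets = default_gene_sets(config)
    expression, labels = simulate_expression(config, gene_sets)
    drivers = [config.planted_gene] + [d for d in DEFAULT_DRIVERS
                                       if d != config.planted_gene]
    return {
        "pedigree": pedigree,
        "matrix": matrix,
        "true_af": true_af,
        "truth": truth,
        "annotations": annotations,
        "drivers": drivers,
        "gene_sets": gene_sets,
        "expression": expression,
        "group_labels": labels,
    }


def write_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete fixture bundle (text files only) into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    b = simulate_bundle(config)
    paths = {k: out / v for k, v in BUNDLE_FILES.items()}

    write_pedigree(b["pedigree"], paths["pedigree"])
    write_vcf(b["matrix"], paths["vcf"])
    write_annotations(b["annotations"], paths["annotations"])
    write_gene_list(b["drivers"], paths["drivers"])
    write_gene_sets(b["gene_sets"], paths["gene_sets"])
    write_counts(b["expression"], paths["counts"])
    with open(paths["groups"], "w") as fh:
        fh.write("sample\tgroup\n")
        for s, g in b["group_labels"].items():
            fh.write(f"{s}\t{g}\n")
    t = b["truth"]
    with open(paths["truth"], "w") as fh:
        fh.write("gene\tmaternal_site\tpaternal_site\n")
        fh.write(f"{t.gene}\t{t.maternal_site_key}\t{t.paternal_site_key}\n")
    meta = {
        "seed": config.seed,
        "germline_proxy_samples": list(config.germline_proxy_samples),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    paths["meta"].write_text(yaml.safe_dump(meta, sort_keys=True))
    return paths
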