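"""Parental-origin labelling, branch filter cascades and the two-hit
compound-heterozygous gene intersection.

The maternal branch of the default ("paper") configuration keeps sites that
are carried by both affected children and the mother but not the father,
then applies the rare-MAF filter, an exonic consequence whitelist and a
cancer-driver gene screen.  The paternal branch keeps shared father-origin
sites with no further restriction.  Genes with surviving alleles from both
branches at distinct sites are compound-heterozygous candidates: opposite
single-parent origin guarantees the trans configuration without phasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, StageError
from .io import (
    MISSING,
    AnnotationRecord,
    DomainTable,
    GenotypeMatrix,
    LOF_CONSEQUENCES,
    PREDICTORS,
    Pedigree,
)

logger = logging.getLogger(__name__)

INHERITANCE_LABELS = (
    "maternal",
    "paternal",
    "biparental_ambiguous",
    "de_novo",
    "untransmitted",
    "unresolvable_missing",
)

#: consequence classes retained by the exonic whitelist (missense plus
#: truncating / start-loss classes).
EXONIC_WHITELIST = frozenset(
    {"exonic_nonsynonymous", "stopgain", "frameshift", "startloss"}
)


def label_inheritance(child_dosage: int, mother_dosage: int,
                      father_dosage: int) -> str:
    """Classify the parental origin of a child's alt allele at one site.

    Total over dosages in {0, 1, 2, MISSING}; never raises.
    """
    if MISSING in (child_dosage, mother_dosage, father_dosage):
        return "unresolvable_missing"
    if child_dosage == 0:
        return "untransmitted"
    mother_carrier = mother_dosage >= 1
    father_carrier = father_dosage >= 1
    if mother_carrier and father_carrier:
        return "biparental_ambiguous"
    if mother_carrier:
        return "maternal"
    if father_carrier:
        return "paternal"
    return "de_novo"


@dataclass(frozen=True)
class BranchCriteria:
    """One branch of the filter cascade (named for its origin parent)."""

    parent: str  # "mother" | "father"
    maf_threshold: float | None = 0.01  # None = no MAF limitation
    maf_sources: tuple[str, ...] | None = None  # None = all available sources
    consequence_whitelist: frozenset[str] | None = None  # None = no restriction
    driver_screen: bool = False
    require_other_parent_noncarrier: bool = True
    missing_policy: str = "conservative"  # or "permissive"

    def __post_init__(self) -> None:
        if self.parent not in ("mother", "father"):
            raise ConfigError(f"branch parent must be mother/father, got {self.parent!r}")
        if self.maf_threshold is not None and not (0.0 < self.maf_threshold <= 1.0):
            raise ConfigError(f"maf_threshold {self.maf_threshold} outside (0, 1]")
        if self.missing_policy not in ("conservative", "permissive"):
            raise ConfigError(f"unknown missing_policy {self.missing_policy!r}")


def maternal_criteria(maf_threshold: float | None = 0.01) -> BranchCriteria:
    """Default strict branch: rare, exonic-consequence, driver-screened."""
    return BranchCriteria(parent="mother", maf_threshold=maf_threshold,
                          consequence_whitelist=EXONIC_WHITELIST, driver_screen=True)


def paternal_criteria() -> BranchCriteria:
    """Default fallback branch: shared paternal-origin sites, no MAF limit."""
    return BranchCriteria(parent="father", maf_threshold=None)


@dataclass
class BranchResult:
    criteria: BranchCriteria
    survivors: list[str]  # site keys, matrix order
    step_counts: dict[str, int]  # survivor count after each cascade step


def _passes_maf(rec: AnnotationRecord | None, criteria: BranchCriteria,
                key: str) -> bool:
    if criteria.maf_threshold is None:
        return True
    if rec is None:
        logger.warning("%s: no annotation; MAF filter passed by default", key)
        return True
    sources = criteria.maf_sources or tuple(rec.af_sources)
    available = [rec.af_sources[s] for s in sources
                 if rec.af_sources.get(s) is not None]
    if not available:
        logger.warning("%s: all AF sources missing; treated as rare", key)
        return True
    return all(af < criteria.maf_threshold for af in available)


def branch_filter(matrix: GenotypeMatrix,
                  annotations: Mapping[str, AnnotationRecord],
                  pedigree: Pedigree,
                  criteria: BranchCriteria,
                  driver_genes: Iterable[str] | None = None) -> BranchResult:
    """Apply the ordered cascade and report per-step survivor counts.

    Steps: (1) shared — carrier dosage in all affected children and the
    branch parent, with the other parent non-carrier; (2) MAF — every
    available configured AF source below threshold (all-missing passes);
    (3) consequence whitelist; (4) driver-gene screen.
    """
    drivers = set(driver_genes) if driver_genes is not None else None
    if criteria.driver_screen and not drivers:
        raise ConfigError("driver screen enabled but driver gene list is empty")

    branch_parent = (pedigree.mother_id if criteria.parent == "mother"
                     else pedigree.father_id)
    other_parent = (pedigree.father_id if criteria.parent == "mother"
                    else pedigree.mother_id)
    required = [matrix.sample_index(s)
                for s in [branch_parent, *pedigree.affected_children]]
    other_idx = matrix.sample_index(other_parent)

    d = matrix.dosage
    permissive = criteria.missing_policy == "permissive"
    if matrix.n_sites:
        req = d[:, required]
        carrier = (req >= 1) | (req == MISSING) if permissive else (req >= 1)
        shared = carrier.all(axis=1)
        if criteria.require_other_parent_noncarrier:
            od = d[:, other_idx]
            noncar = (od == 0) | (od == MISSING) if permissive else (od == 0)
            shared &= noncar
    else:
        shared = np.zeros(0, dtype=bool)

    keys = matrix.site_keys()
    step1 = [keys[i] for i in np.flatnonzero(shared)]
    counts = {"shared": len(step1)}

    step2 = [k for k in step1 if _passes_maf(annotations.get(k), criteria, k)]
    counts["maf"] = len(step2)

    if criteria.consequence_whitelist is None:
        step3 = step2
    else:
        step3 = [k for k in step2
                 if (annotations[k].consequence if k in annotations else "other")
                 in criteria.consequence_whitelist]
    counts["consequence"] = len(step3)

    if criteria.driver_screen:
        step4 = [k for k in step3
                 if k in annotations and annotations[k].gene in drivers]
    else:
        step4 = step3
    counts["driver"] = len(step4)

    return BranchResult(criteria, step4, counts)


# ---------------------------------------------------------------------------
# predictor consensus


@dataclass(frozen=True)
class ConsensusCall:
    calls: tuple[tuple[str, str], ...]  # (predictor, call) for available calls
    n_damaging: int
    n_available: int
    verdict: str  # damaging | benign | uncertain


def predictor_consensus(record: AnnotationRecord) -> ConsensusCall:
    """Majority vote over the available calls of the four predictors.

    Damaging iff more than half of the available calls are damaging; benign
    iff fewer than half; uncertain on an exact tie or when nothing is
    available.
    """
    calls = tuple((p, record.predictor_calls[p]) for p in PREDICTORS
                  if p in record.predictor_calls)
    n_avail = len(calls)
    n_dam = sum(1 for _, c in calls if c == "damaging")
    if n_avail == 0 or n_dam * 2 == n_avail:
        verdict = "uncertain"
    elif n_dam * 2 > n_avail:
        verdict = "damaging"
    else:
        verdict = "benign"
    return ConsensusCall(calls, n_dam, n_avail, verdict)


# ---------------------------------------------------------------------------
# compound-het intersection


@dataclass
class CandidateGene:
    gene: str
    maternal_alleles: list[str]  # site keys
    paternal_alleles: list[str]
    driver_gene: bool = False
    has_lof: bool = False
    consensus_damaging: bool = False


def detect_compound_het(maternal_survivors: Sequence[str],
                        paternal_survivors: Sequence[str],
                        annotations: Mapping[str, AnnotationRecord],
                        driver_genes: Iterable[str] | None = None,
                        ) -> list[CandidateGene]:
    """Intersect the two branches at the gene level (two-hit rule).

    A gene qualifies with >= 1 maternal-origin and >= 1 paternal-origin
    surviving allele at distinct sites.  A site present in both survivor
    sets cannot be single-parent-origin in both and is dropped from both
    with a warning.  Output is sorted by (has_lof desc, gene symbol).
    """
    overlap = set(maternal_survivors) & set(paternal_survivors)
    if overlap:
        logger.warning("sites in both branches excluded from both: %s",
                       sorted(overlap))
    maternal = [k for k in maternal_survivors if k not in overlap]
    paternal = [k for k in paternal_survivors if k not in overlap]

    def by_gene(keys: Sequence[str]) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for k in keys:
            rec = annotations.get(k)
            if rec is None:
                logger.warning("%s: survivor without annotation; dropped", k)
                continue
            out.setdefault(rec.gene, []).append(k)
        return out

    mat, pat = by_gene(maternal), by_gene(paternal)
    drivers = set(driver_genes) if driver_genes is not None else set()

    candidates = []
    for gene in set(mat) & set(pat):
        alleles = mat[gene] + pat[gene]
        recs = [annotations[k] for k in alleles]
        candidates.append(CandidateGene(
            gene=gene,
            maternal_alleles=mat[gene],
            paternal_alleles=pat[gene],
            driver_gene=gene in drivers,
            has_lof=any(r.consequence in LOF_CONSEQUENCES for r in recs),
            consensus_damaging=any(
                predictor_consensus(r).verdict == "damaging" for r in recs),
        ))
    candidates.sort(key=lambda c: (not c.has_lof, c.gene))
    return candidates


# ---------------------------------------------------------------------------
# protein-domain mapping


@dataclass(frozen=True)
class TruncationResult:
    retained: list[str]  # fully upstream of the stop residue
    partial: list[str]  # overlapping the stop residue


def truncation_retained_domains(stop_residue: int,
                                domains: DomainTable) -> TruncationResult:
    """Domains retained by a premature stop at ``stop_residue``.

    Fully retained: end_residue < stop_residue.  Domains straddling the
    stop are reported separately as partial.
    """
    if stop_residue < 1:
        raise StageError(f"stop_residue must be >= 1, got {stop_residue}")
    retained = [n for n, _, end in domains.entries if end < stop_residue]
    partial = [n for n, start, end in domains.entries
               if start < stop_residue <= end]
    return TruncationResult(retained, partial)


def locate_in_domain(residue: int, domains: DomainTable) -> list[str]:
    """All domains whose inclusive interval contains ``residue``."""
    if residue < 1:
        raise StageError(f"residue must be >= 1, got {residue}")
    return [n for n, start, end in domains.entries if start <= residue <= end]
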