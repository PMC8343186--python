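"""Data model and readers/writers for the formats the pipeline touches.

Formats: 6-column PED, multi-sample VCF v4.x (GT only), annotation TSV,
one-symbol-per-line gene lists, GMT gene-set collections and gene x sample
count matrices.  All tabular text is UTF-8 and tab-separated.

Coordinates are 1-based VCF positions end to end; multiallelic records are
decomposed into biallelic sites but indel left-alignment is *not* performed —
inputs are assumed normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import (
    InputFormatError,
    PedigreeAmbiguityError,
    PedigreeStructureError,
)

logger = logging.getLogger(__name__)

MISSING = -1  # dosage sentinel

CONSEQUENCES = (
    "exonic_nonsynonymous",
    "stopgain",
    "frameshift",
    "startloss",
    "synonymous",
    "noncoding",
    "other",
)
LOF_CONSEQUENCES = frozenset({"stopgain", "frameshift", "startloss"})

PREDICTORS = ("SIFT", "PolyPhen2", "MutationTaster", "M-CAP")

_SEX = {"1": "male", "2": "female"}
_AFFECTED = {"1": "unaffected", "2": "affected"}


# ---------------------------------------------------------------------------
# pedigree


@dataclass(frozen=True)
class PedigreeMember:
    family_id: str
    individual_id: str
    father_id: str  # "0" when founder
    mother_id: str
    sex: str  # male | female | unknown
    affected: str  # affected | unaffected | unknown


@dataclass
class Pedigree:
    """Quad-style pedigree with resolved parental roles.

    Roles are resolved from the affected children: every affected member
    with both parents present defines the candidate father/mother; exactly
    one of each must emerge.
    """

    members: list[PedigreeMember]
    father_id: str = field(init=False)
    mother_id: str = field(init=False)
    affected_children: list[str] = field(init=False)

    def __post_init__(self) -> None:
        ids = [m.individual_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeStructureError("duplicate individual ids in pedigree")
        known = set(ids)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid != "0" and pid not in known:
                    raise PedigreeStructureError(
                        f"{m.individual_id} references absent parent {pid!r}"
                    )
        affected = [
            m for m in self.members
            if m.affected == "affected" and m.father_id != "0" and m.mother_id != "0"
        ]
        fathers = {m.father_id for m in affected}
        mothers = {m.mother_id for m in affected}
        if len(fathers) != 1 or len(mothers) != 1:
            raise PedigreeAmbiguityError(
                "cannot resolve a unique father and mother for the affected "
                f"children (fathers={sorted(fathers)}, mothers={sorted(mothers)})"
            )
        self.father_id = next(iter(fathers))
        self.mother_id = next(iter(mothers))
        self.affected_children = [m.individual_id for m in affected]

    @property
    def sample_ids(self) -> list[str]:
        return [m.individual_id for m in self.members]


def read_pedigree(path: str | Path) -> Pedigree:
    """Parse a 6-column whitespace-separated PED file (file order kept)."""
    members: list[PedigreeMember] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise InputFormatError(f"{path}:{lineno}: expected 6 columns, got {len(cols)}")
        fam, ind, fid, mid, sex, aff = cols[:6]
        members.append(
            PedigreeMember(fam, ind, fid, mid, _SEX.get(sex, "unknown"),
                           _AFFECTED.get(aff, "unknown"))
        )
    if not members:
        raise InputFormatError(f"{path}: empty pedigree")
    return Pedigree(members)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    aff_code = {"unaffected": "1", "affected": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for m in pedigree.members:
            fh.write("\t".join([m.family_id, m.individual_id, m.father_id,
                                m.mother_id, sex_code[m.sex], aff_code[m.affected]]) + "\n")


# ---------------------------------------------------------------------------
# variant sites and genotypes


@dataclass(frozen=True, order=True)
class VariantSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str  # single alternate allele after decomposition

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputFormatError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise InputFormatError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def site_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical join key: exact string match after uppercasing alleles."""
    return f"{chrom}:{pos}:{ref.upper()}:{alt.upper()}"


@dataclass
class GenotypeMatrix:
    """Per-site, per-sample alt-allele dosages (0/1/2, MISSING = -1)."""

    sites: list[VariantSite]
    samples: list[str]
    dosage: np.ndarray  # shape (n_sites, n_samples), int8

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise InputFormatError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        valid = np.isin(self.dosage, (MISSING, 0, 1, 2))
        if not valid.all():
            raise InputFormatError("dosages must be in {0,1,2,missing}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def site_keys(self) -> list[str]:
        return [s.key for s in self.sites]


def read_variants(path: str | Path, pedigree: Pedigree) -> GenotypeMatrix:
    """Read a multi-sample VCF into a GenotypeMatrix for the pedigree samples.

    Multiallelic records are decomposed into one biallelic site per
    alternate; dosage is the per-sample count of that alternate in GT.
    Any "." allele makes the whole genotype missing.  Sites are ordered by
    position within each chromosome (chromosome order = file appearance).
    """
    vcf = VCF(str(path))
    absent = [s for s in pedigree.sample_ids if s not in vcf.samples]
    if absent:
        raise InputFormatError(f"pedigree samples missing from VCF header: {absent}")
    col = [vcf.samples.index(s) for s in pedigree.sample_ids]

    sites: list[VariantSite] = []
    rows: list[list[int]] = []
    seen: set[str] = set()
    for var in vcf:
        gts = var.genotypes  # [[a0, a1, phased], ...]
        for alt_idx, alt in enumerate(var.ALT, start=1):
            try:
                site = VariantSite(var.CHROM, var.POS, var.REF.upper(), alt.upper())
            except InputFormatError as exc:
                logger.warning("skipping malformed record: %s", exc)
                continue
            if site.key in seen:
                logger.warning("duplicate site %s; keeping first occurrence", site.key)
                continue
            seen.add(site.key)
            row = []
            for c in col:
                alleles = gts[c][:-1]
                if any(a < 0 for a in alleles):
                    row.append(MISSING)
                else:
                    row.append(sum(1 for a in alleles if a == alt_idx))
            sites.append(site)
            rows.append(row)

    # position-sort within chromosome, chromosomes in order of appearance
    chrom_rank: dict[str, int] = {}
    for s in sites:
        chrom_rank.setdefault(s.chrom, len(chrom_rank))
    order = sorted(range(len(sites)),
                   key=lambda i: (chrom_rank[sites[i].chrom], sites[i].pos,
                                  sites[i].ref, sites[i].alt))
    dosage = (np.array(rows, dtype=np.int8)[order]
              if rows else np.empty((0, len(col)), dtype=np.int8))
    return GenotypeMatrix([sites[i] for i in order], list(pedigree.sample_ids), dosage)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotypes (dosage round-trips;
    het phase is not represented)."""
    chroms: list[str] = []
    for s in matrix.sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for i, s in enumerate(matrix.sites):
            gts = "\t".join(_GT_STR[int(d)] for d in matrix.dosage[i])
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# annotations


@dataclass
class AnnotationRecord:
    """Annotation for one (site, alternate allele)."""

    site_key: str
    gene: str
    consequence: str
    af_sources: dict[str, float | None]
    predictor_calls: dict[str, str]  # predictor -> damaging | benign (absent = missing)

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            logger.warning("unknown consequence %r mapped to 'other'", self.consequence)
            self.consequence = "other"
        for src, af in self.af_sources.items():
            if af is not None and not (0.0 <= af <= 1.0):
                raise InputFormatError(f"{self.site_key}: AF {src}={af} outside [0,1]")
        bad = set(self.predictor_calls) - set(PREDICTORS)
        if bad:
            raise InputFormatError(f"{self.site_key}: unknown predictors {sorted(bad)}")
        for p, call in self.predictor_calls.items():
            if call not in ("damaging", "benign"):
                raise InputFormatError(f"{self.site_key}: bad call {p}={call!r}")


_CALL_IN = {"damaging": "damaging", "D": "damaging",
            "benign": "benign", "B": "benign", "T": "benign", "N": "benign"}
_CALL_OUT = {"damaging": "D", "benign": "B"}

_ANN_FIXED = ["chrom", "pos", "ref", "alt", "gene", "consequence"]


def read_annotations(path: str | Path) -> dict[str, AnnotationRecord]:
    """Read the annotation sidecar TSV, keyed by canonical site key.

    Expected header: chrom, pos, ref, alt, gene, consequence, one or more
    ``af_<source>`` columns and the four predictor columns (SIFT, PolyPhen2,
    MutationTaster, M-CAP; values D/B or blank/.).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in _ANN_FIXED if c not in df.columns]
    if missing_cols:
        raise InputFormatError(f"{path}: missing columns {missing_cols}")
    af_cols = [c for c in df.columns if c.startswith("af_")]
    if not af_cols:
        raise InputFormatError(f"{path}: need at least one af_<source> column")
    pred_cols = [c for c in PREDICTORS if c in df.columns]

    records: dict[str, AnnotationRecord] = {}
    for row in df.itertuples(index=False, name=None):
        # positional zip: itertuples would mangle the 'M-CAP' column name
        d = dict(zip(df.columns, row))
        key = site_key(d["chrom"], int(d["pos"]), d["ref"], d["alt"])
        if key in records:
            raise InputFormatError(f"{path}: duplicate annotation for {key}")
        afs: dict[str, float | None] = {}
        for c in af_cols:
            v = d[c].strip()
            afs[c[3:]] = None if v in ("", ".") else float(v)
        calls: dict[str, str] = {}
        for c in pred_cols:
            v = d[c].strip()
            if v in ("", "."):
                continue
            if v not in _CALL_IN:
                raise InputFormatError(f"{path}: bad predictor value {v!r} for {c}")
            calls[c] = _CALL_IN[v]
        records[key] = AnnotationRecord(key, d["gene"], d["consequence"], afs, calls)
    return records


def write_annotations(records: Mapping[str, AnnotationRecord], path: str | Path) -> None:
    sources: list[str] = []
    for rec in records.values():
        for s in rec.af_sources:
            if s not in sources:
                sources.append(s)
    header = _ANN_FIXED + [f"af_{s}" for s in sources] + list(PREDICTORS)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for rec in records.values():
            chrom, pos, ref, alt = rec.site_key.split(":")
            row = [chrom, pos, ref, alt, rec.gene, rec.consequence]
            for s in sources:
                af = rec.af_sources.get(s)
                row.append("." if af is None else repr(float(af)))
            for p in PREDICTORS:
                row.append(_CALL_OUT.get(rec.predictor_calls.get(p, ""), "."))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# gene lists and gene sets


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and #-comments ignored."""
    genes = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if len(set(genes)) != len(genes):
        raise InputFormatError(f"{path}: duplicate gene symbols")
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise InputFormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise InputFormatError(f"gene set {name!r} has duplicate members")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Standard GMT: name <tab> description <tab> member..."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 3:
            raise InputFormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        name, members = cols[0], [g for g in cols[2:] if g]
        if name in sets:
            raise InputFormatError(f"{path}: duplicate set name {name!r}")
        sets[name] = members
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na"] + list(members)) + "\n")


# ---------------------------------------------------------------------------
# expression counts


@dataclass
class ExpressionMatrix:
    genes: list[str]
    samples: list[str]
    counts: np.ndarray  # (n_genes, n_samples), nonnegative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise InputFormatError("counts shape inconsistent with genes/samples")
        if (self.counts < 0).any():
            raise InputFormatError("negative counts")
        if len(set(self.genes)) != len(self.genes):
            raise InputFormatError("duplicate gene symbols in count matrix")

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise InputFormatError(f"gene {gene!r} not in count matrix") from None


def read_counts(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise InputFormatError(f"{path}: non-numeric counts")
    if (counts < 0).any():
        raise InputFormatError(f"{path}: negative counts")
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                            counts)


def write_counts(matrix: ExpressionMatrix, path: str | Path) -> None:
    counts = matrix.counts
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(matrix.samples) + "\n")
        as_int = np.issubdtype(counts.dtype, np.integer) or bool(
            np.all(np.equal(np.mod(counts, 1), 0)))
        for i, g in enumerate(matrix.genes):
            if as_int:
                vals = "\t".join(str(int(v)) for v in counts[i])
            else:
                vals = "\t".join(repr(float(v)) for v in counts[i])
            fh.write(f"{g}\t{vals}\n")


# ---------------------------------------------------------------------------
# protein domain table


@dataclass
class DomainTable:
    """Named residue intervals (1-based, inclusive ends)."""

    entries: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for name, start, end in self.entries:
            if not (1 <= start <= end):
                raise InputFormatError(f"domain {name!r}: bad interval [{start},{end}]")


#: BRCA2 functional domains (residue coordinates, full length 3418 aa).
DEFAULT_BRCA2_DOMAINS = DomainTable([
    ("PALB2 binding", 21, 39),
    ("P/CAF binding", 290, 453),
    ("BRC repeats", 1002, 2085),
    ("Helical", 2481, 2667),
    ("OB folds", 2670, 3102),
    ("TR2", 3265, 3330),
])


def read_domain_table(path: str | Path) -> DomainTable:
    """TSV with columns: domain, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"domain": str, "start": int, "end": int})
    for c in ("domain", "start", "end"):
        if c not in df.columns:
            raise InputFormatError(f"{path}: missing column {c!r}")
    return DomainTable([(r.domain, int(r.start), int(r.end))
                        for r in df.itertuples(index=False)])
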