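import numpy as np
import pytest

from quadhet.io import AnnotationRecord, GenotypeMatrix, VariantSite
from quadhet.simulate import SimulationConfig, default_quad_pedigree, simulate_bundle


@pytest.fixture
def quad_pedigree():
    return default_quad_pedigree()


@pytest.fixture(scope="session")
def default_bundle():
    """One in-memory fixture bundle shared by read-only tests."""
    return simulate_bundle(SimulationConfig(seed=42))


def make_matrix(dosages, chrom="1", start=100, samples=("F1", "M1", "C1", "C2")):
    """Build a GenotypeMatrix from a list of per-sample dosage rows."""
    dosages = np.asarray(dosages, dtype=np.int8)
    sites = [VariantSite(chrom, start + 10 * i, "A", "C")
             for i in range(len(dosages))]
    return GenotypeMatrix(sites, list(samples), dosages)


def make_annotation(key, gene="G1", consequence="exonic_nonsynonymous",
                    afs=None, calls=None):
    return AnnotationRecord(key, gene, consequence,
                            afs if afs is not None else {"a": None, "b": None},
                            calls or {})
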