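import numpy as np
import pytest

from rvset.variant_io import Annotation, GeneVariantSet, Variant


def make_gvs(dosage, annotations=None, gene_id="g", start_pos=1):
    """Build a GeneVariantSet from a dense dosage matrix (samples x variants)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if annotations is None:
        annotations = [Annotation.LOF] * m
    variants = [
        Variant(
            variant_id=f"1:{start_pos + j}:A:T",
            chrom="1",
            pos=start_pos + j,
            annotation=Annotation(annotations[j]),
        )
        for j in range(m)
    ]
    return GeneVariantSet(
        gene_id=gene_id,
        dosage=dosage,
        variants=variants,
        sample_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def binary_fit_500(rng):
    """A 500-sample binary null fit with one covariate, ~30% cases."""
    from rvset.null_model import fit_null_glm

    x = rng.standard_normal(500)
    p = 1 / (1 + np.exp(-(-1.0 + 0.5 * x)))
    y = (rng.random(500) < p).astype(float)
    return fit_null_glm(y, x, "binary"), x
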