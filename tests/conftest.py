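import numpy as np
import pytest

from cismaxt import FeatureAnnotation, Layer, OmicsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_annotations(layer, specs):
    """specs: iterable of (feature_id, chrom, start[, end])."""
    out = []
    for s in specs:
        fid, chrom, start = s[0], s[1], s[2]
        end = s[3] if len(s) > 3 else start + 1
        out.append(FeatureAnnotation(feature_id=fid, chrom=chrom, start=start,
                                     end=end, layer=layer))
    return out


def make_matrix(values, layer, chrom="chr1", start0=100, spacing=10,
                sample_prefix="s"):
    """Small OmicsMatrix with point annotations at regular spacing."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    prefix = {Layer.EXPRESSION: "probe", Layer.SNP: "snp", Layer.CPG: "cpg"}[layer]
    anns = make_annotations(layer, [
        (f"{prefix}{i}", chrom, start0 + i * spacing) for i in range(n_feat)
    ])
    return OmicsMatrix(values=values, layer=layer, annotations=anns,
                       sample_ids=[f"{sample_prefix}{j}" for j in range(n_samp)])
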