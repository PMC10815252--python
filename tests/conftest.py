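import math

import pytest
from hypothesis import HealthCheck, settings

from edmap.effect_annotator import load_gene_models
from edmap.simulate import CausalSpec, SimConfig, make_gene_fixture
from edmap.variant_io import BulkVariant

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gene_fixture(tmp_path_factory):
    """Two-exon gene (plus strand) and its minus-strand mirror, built around
    the default causal G>A SNP at the first base of codon 217 (GGT)."""
    out = tmp_path_factory.mktemp("gene_fixture")
    return make_gene_fixture(out, causal=CausalSpec())


@pytest.fixture(scope="session")
def gene_models(gene_fixture):
    models, genome = load_gene_models(gene_fixture.gff_path, gene_fixture.fasta_path)
    return models, genome


@pytest.fixture
def mk_variant():
    def _mk(chrom="chr1", pos=100, ref="G", alt="A", ad_mut=(10, 20), ad_wt=(30, 0), qual=50.0):
        return BulkVariant(chrom=chrom, pos=pos, ref=ref, alt=alt, ad_mut=ad_mut, ad_wt=ad_wt, qual=qual)

    return _mk


def quantile_oracle(values, q):
    """Independent sort-and-interpolate empirical quantile (linear rule)."""
    s = sorted(values)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])
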