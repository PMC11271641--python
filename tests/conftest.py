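import pytest

from tsmr import HarmonizedSet, SummaryStatRecord


def make_record(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.02, p=1e-9, **kw):
    return SummaryStatRecord(
        snp_id=snp_id, effect_allele=ea, other_allele=oa, beta=beta, se=se, pvalue=p, **kw
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def hset_factory():
    def _make(beta_exp, beta_out, se_out, se_exp=None, **kw):
        if se_exp is None:
            se_exp = [1e-6] * len(beta_exp)
        return HarmonizedSet.from_arrays(beta_exp, se_exp, beta_out, se_out, **kw)

    return _make
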