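import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrkit.harmonization import HarmonizedPair
from mrkit.summary_data import GwasTable, SummaryRecord

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

_ALLELES = [("A", "G"), ("C", "A"), ("G", "T"), ("T", "C")]


def make_record(variant_id, pvalue=1e-10, beta=0.1, se=0.01, **kw):
    """A valid SummaryRecord with convenient defaults."""
    i = abs(hash(variant_id)) % len(_ALLELES)
    defaults = dict(
        variant_id=variant_id,
        effect_allele=_ALLELES[i][0],
        other_allele=_ALLELES[i][1],
        beta=beta,
        se=se,
        pvalue=pvalue,
        chrom="1",
        pos=1000,
        eaf=0.3,
        n=10_000,
    )
    defaults.update(kw)
    return SummaryRecord(**defaults)


def make_table(records, role="exposure", trait="trait"):
    return GwasTable.from_records(records, trait_id=trait, role=role)


def make_pairs(rng, L, beta=0.5, se_gamma=0.005, se_Gamma=0.03, alpha=None,
               gamma_range=(0.08, 0.15)):
    """Harmonized pairs drawn from the summary-level sampling model."""
    gamma = rng.uniform(*gamma_range, L)
    a = np.zeros(L) if alpha is None else np.asarray(alpha, dtype=float)
    g_hat = gamma + rng.standard_normal(L) * se_gamma
    G_hat = beta * gamma + a + rng.standard_normal(L) * se_Gamma
    return [
        HarmonizedPair(f"v{i:03d}", float(g_hat[i]), se_gamma, float(G_hat[i]), se_Gamma)
        for i in range(L)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
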