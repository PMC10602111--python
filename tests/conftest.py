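import numpy as np
import pandas as pd
import pytest

from t2dclust.gwas_io import AssociationStat, GwasStudy, LdPanel, VariantKey
from t2dclust.synthetic_data import (
    generate_summary_stats,
    make_planted_truth,
)


def stat(key, effect, beta, se=0.05, p=None, n=10000.0, eaf=0.3):
    if p is None:
        from scipy.stats import norm

        p = float(min(2 * norm.sf(abs(beta / se)), 1.0))
    return AssociationStat(key=key, effect_allele=effect, beta=beta, se=se, p=p, n=n, eaf=eaf)


@pytest.fixture(scope="session")
def small_truth():
    return make_planted_truth(K_true=3, n_variants=90, n_traits=24, seed=11)


@pytest.fixture(scope="session")
def small_studies(small_truth):
    return generate_summary_stats(small_truth)


@pytest.fixture(scope="session")
def small_z(small_truth, small_studies):
    return pd.DataFrame(
        np.array([[s.z for s in st.stats] for st in small_studies.trait_studies]).T,
        index=[v.vid for v in small_truth.variants],
        columns=[st.label for st in small_studies.trait_studies],
    )


@pytest.fixture()
def toy_variants():
    return [
        VariantKey("1", 1000, "A", "G", rsid="rs1"),
        VariantKey("1", 2000, "T", "C", rsid="rs2"),
        VariantKey("2", 5000, "A", "C", rsid="rs3"),
    ]


@pytest.fixture()
def empty_panel():
    return LdPanel("EUR")
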