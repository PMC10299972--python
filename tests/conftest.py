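import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def oneway_data():
    """Balanced one-way layout, 3 genotypes x 2 reps; ANOVA closed forms
    give sigma2_e = MSW = 2 and sigma2_g = (MSB - MSW)/r = 15."""
    y = np.array([10.0, 12, 14, 16, 18, 20])
    X = np.ones((6, 1))
    Z = np.kron(np.eye(3), np.ones((2, 1)))
    return y, X, Z


def make_trial_series_features(seed=0, n_total=45, n_shared=27, n_sites=5, drop_one=True):
    """Feature table mirroring an unbalanced variety-testing series: 45 genotypes in total,
    36 per year-site (2019 and 2020 sets differ by nine genotypes), five
    year-sites, optionally one row removed (the tiller outlier)."""
    rng = np.random.default_rng(seed)
    genos = [f"G{i:02d}" for i in range(n_total)]
    shared = genos[:n_shared]
    only_2019 = genos[n_shared : n_shared + 9]
    only_2020 = genos[n_shared + 9 :]
    sites_2019 = ["SiteA_2019", "SiteB_2019", "SiteC_2019"]
    sites_2020 = ["SiteA_2020", "SiteB_2020"]
    rows = []
    for ys in sites_2019 + sites_2020:
        present = shared + (only_2019 if ys.endswith("2019") else only_2020)
        for g in present:
            rows.append(
                {
                    "year_site": ys,
                    "genotype": g,
                    "n_tiller": rng.normal(1500, 300),
                    "PH_max": rng.normal(90, 8),
                    "t_PH_start": rng.normal(900, 60),
                    "yield": rng.normal(6, 1),
                }
            )
    df = pd.DataFrame(rows)
    if drop_one:
        df = df.drop(index=0).reset_index(drop=True)
    return df
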