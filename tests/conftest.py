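import numpy as np
import pandas as pd
import pytest

import crosstrait as ct


def make_sumstats(rows, trait_label="t", **attrs):
    """Build a canonical table from a list of dicts (tiny fixtures)."""
    df = pd.DataFrame(rows)
    for col in ct.CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if df["Z"].isna().all() and df["SE"].notna().any():
        df["Z"] = df["BETA"] / df["SE"]
    from crosstrait.sumstats import log10p_from_z

    df["LOG10P"] = log10p_from_z(df["Z"].to_numpy(dtype=float))
    df["P"] = df["P"].fillna(np.power(10.0, df["LOG10P"]))
    df = df[ct.CANONICAL_COLUMNS + ["LOG10P"]]
    df.attrs["trait_label"] = trait_label
    df.attrs.update(attrs)
    return df


def write_tsv(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


@pytest.fixture(scope="session")
def adult_pair():
    """One simulated adult-BMI-vs-outcome style pair, shared across tests."""
    cfg = ct.pair_config("adult_bmi_pcos", m_snps=10_000, n_regions=25, seed=0)
    return ct.simulate_pair(cfg)


@pytest.fixture(scope="session")
def null_pair():
    cfg = ct.pair_config("null", m_snps=10_000, n_regions=25, seed=1)
    return ct.simulate_pair(cfg)
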