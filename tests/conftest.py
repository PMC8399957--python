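import importlib.resources as resources

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def channel_counts() -> pd.DataFrame:
    path = resources.files("paravar.data").joinpath("channel_variant_counts.tsv")
    return pd.read_csv(path, sep="\t", comment="#")


@pytest.fixture(scope="session")
def putative_table() -> pd.DataFrame:
    path = resources.files("paravar.data").joinpath("cav12_putative_plp.tsv")
    return pd.read_csv(path, sep="\t", comment="#")


@pytest.fixture(scope="session")
def cav12_regions():
    from paravar.topology import default_cav12_regions

    return default_cav12_regions()


@pytest.fixture()
def source_tables() -> dict[str, pd.DataFrame]:
    """Small hand-written per-source tables covering the merge rules."""

    def table(rows):
        return pd.DataFrame(rows, columns=["gene", "change", "label", "af",
                                           "condition"])

    clinvar = table([
        ("GENE1", "A10T", "pathogenic", None, "long QT syndrome"),
        ("GENE1", "R20Q", "uncertain significance", None, ""),
        ("GENE1", "L30P", "likely pathogenic", None, "Timothy syndrome"),
        ("GENE1", "G40R", "pathogenic", None, ""),  # no condition -> not P/LP
        ("GENE2", "K5E", "benign", None, ""),
    ])
    gnomad = table([
        ("GENE1", "A10T", "", 0.002, ""),     # duplicate of a P/LP variant
        ("GENE1", "V50M", "", 0.0005, ""),    # benign by frequency
        ("GENE1", "P60L", "", 0.00005, ""),   # too rare -> VUS
        ("GENE2", "K5E", "", 0.01, ""),
    ])
    humsavar = table([
        ("GENE2", "D7N", "disease", None, ""),
    ])
    return {"clinvar": clinvar, "gnomad": gnomad, "humsavar": humsavar}
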