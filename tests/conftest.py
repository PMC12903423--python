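import pytest
from hypothesis import HealthCheck, settings

import plateplan as pp

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reagents():
    return pp.load_reagent_table()


@pytest.fixture()
def standard_recipe(reagents):
    """The standard acrylate condition: HEA/MBiB/CuBr2/Me6TREN/ZnTPP
    = 200/1/0.08/0.2/0.002 at [M]_f = 1 M in a 200 uL well."""
    return pp.RecipeSpec(
        composition=pp.MonomerComposition.equimolar([reagents["HEA"]]),
        initiator=reagents["MBiB"],
        ratios={"CuBr2": 0.08, "Me6TREN": 0.2, "ZnTPP": 0.002},
        dp=200,
        m_final=1.0,
        v_total=200.0,
        label="acrylate_standard",
    )


@pytest.fixture()
def bench_stocks():
    """Bench stocks: CuBr2 22.5 mM, Me6TREN 200 mM (50/25/11.5 dilutions),
    ZnTPP 4 mM (1 mM dilution), EosinY 2 mM, plus monomer/initiator stocks."""
    return pp.StockSet(
        {
            "HEA": pp.Stock("HEA", 8700.0, (), "monomers:1"),
            "MBiB": pp.Stock("MBiB", 100.0, (), "initiators:1"),
            "CuBr2": pp.Stock("CuBr2", 22.5, (), "metals:1"),
            "Me6TREN": pp.Stock("Me6TREN", 200.0, (50.0, 25.0, 11.5), "ligands:1"),
            "ZnTPP": pp.Stock("ZnTPP", 4.0, (1.0,), "pcs:1"),
            "EosinY": pp.Stock("EosinY", 2.0, (), "pcs:2"),
        }
    )


@pytest.fixture(scope="session")
def fixture_sheets(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixtures")
    return pp.make_fixture_sheets(outdir, seed=0)
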