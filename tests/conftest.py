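import numpy as np
import pandas as pd
import pytest

from gutpheno.cohort import QualVar, QuantVar, SyntheticSpec, generate_cohort


def small_spec(
    seed: int = 0,
    n_taxa: int = 24,
    planted=None,
    quant=None,
    qual=None,
    group_sizes=None,
    depth=(2000, 4000),
    conc_total: float = 30.0,
) -> SyntheticSpec:
    """Compact two-or-three group cohort spec for fast tests."""
    if group_sizes is None:
        group_sizes = {"CT": 30, "DZ": 30}
    base = np.linspace(1.0, 0.08, n_taxa)
    base = base / base.sum() * conc_total
    return SyntheticSpec(
        group_sizes=group_sizes,
        n_taxa=n_taxa,
        planted_taxa=planted or {},
        base_concentration=tuple(base),
        library_size_range=depth,
        quant_vars=tuple(quant or ()),
        qual_vars=tuple(qual or ()),
        seed=seed,
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Two-group cohort with no planted effects of any kind."""
    spec = small_spec(
        seed=11,
        quant=[QuantVar("intake_a", 50, 10), QuantVar("intake_b", 20, 5)],
        qual=[QualVar("habit", ("no", "yes"), (0.6, 0.4))],
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def signal_cohort():
    """Two-group cohort with planted taxa and phenotype shifts."""
    spec = small_spec(
        seed=21,
        planted={"DZ": [(1, 2.2), (4, -2.2), (7, 2.0)]},
        quant=[QuantVar("intake_a", 50, 10, {"DZ": 12}),
               QuantVar("intake_b", 20, 5)],
        qual=[QualVar("habit", ("no", "yes"), (0.7, 0.3), {"DZ": (0.3, 0.7)})],
        group_sizes={"CT": 40, "DZ": 40},
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_counts(array, prefix="s", taxa_prefix="t") -> pd.DataFrame:
    a = np.asarray(array)
    return pd.DataFrame(
        a,
        index=[f"{prefix}{i}" for i in range(a.shape[0])],
        columns=[f"{taxa_prefix}{j}" for j in range(a.shape[1])],
    )
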