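import numpy as np
import pandas as pd
import pytest

from placnet.datamodel import CompoundTable, ExpressionStudy, SampleTable
from placnet.simulate import SimulationDesign, generate_study


def make_sample_table(n=6, compounds=("PFOS",), seed=0, censor=None):
    """Small hand-built sample table; ``censor`` maps (compound, source) to a
    list of (row, flag) pairs."""
    rng = np.random.default_rng(seed)
    data = {
        "fetal_sex": rng.integers(0, 2, n),
        "gestational_age": 38.0 + rng.normal(0, 1, n).round(3),
        "birth_weight": 3000.0 + rng.normal(0, 300, n).round(1),
        "spontaneous_labor": rng.random(n) < 0.6,
    }
    limits = []
    for compound in compounds:
        for source in ("maternal", "fetal"):
            conc = np.round(np.exp(rng.normal(0.5, 0.4, n)), 4)
            flags = np.array(["quantified"] * n, dtype=object)
            if censor:
                for row, flag in censor.get((compound, source), []):
                    flags[row] = flag
            data[f"conc_{compound}_{source}"] = conc
            data[f"flag_{compound}_{source}"] = flags
            limits.append({"compound": compound, "source": source,
                           "lod": 0.1, "loq": 0.2})
    frame = pd.DataFrame(data, index=[f"S{i}" for i in range(n)])
    return SampleTable(frame, pd.DataFrame(limits))


def make_study(n_features=10, n_samples=6, seed=0, isoforms=2):
    """Tiny transcript-level study with deterministic counts."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 50, size=(n_features, n_samples))
    genes = [f"G{i // isoforms:03d}" for i in range(n_features)]
    tx = [f"{g}.t{i % isoforms + 1}" for i, g in enumerate(genes)]
    samples = make_sample_table(n=n_samples, seed=seed)
    counts_df = pd.DataFrame(counts, index=tx, columns=samples.sample_ids)
    tx2gene = pd.DataFrame({"transcript_id": tx, "gene_id": genes})
    return ExpressionStudy(counts_df, tx2gene, samples)


@pytest.fixture
def sample_table():
    return make_sample_table(
        censor={("PFOS", "maternal"): [(0, "below_LOD"), (1, "below_LOQ")]}
    )


@pytest.fixture
def tiny_study():
    return make_study()


@pytest.fixture(scope="session")
def reduced_result():
    """One reduced synthetic study shared across module tests."""
    return generate_study(SimulationDesign.reduced(seed=1))


def exact_cor_vectors(r, n=20, seed=0):
    """Two vectors whose sample Pearson correlation is exactly ``r``."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x
    z /= z.std()
    y = r * x + np.sqrt(1 - r**2) * z
    return x, y
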