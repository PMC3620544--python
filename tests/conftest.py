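import numpy as np
import pandas as pd
import pytest

import cvgkit as ck


@pytest.fixture
def small_sheet() -> ck.SampleSheet:
    rows = []
    for t in ("stem", "leaf", "root"):
        for k in (1, 2, 3):
            rows.append(
                {"sample_id": f"ath_{t}_r{k}", "species_id": "ath", "tissue_id": t}
            )
    return ck.SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def small_matrix(small_sheet) -> ck.ExpressionMatrix:
    rng = np.random.default_rng(7)
    samples = list(small_sheet.frame["sample_id"])
    genes = [f"g{i}" for i in range(20)]
    data = pd.DataFrame(
        rng.normal(7.0, 1.0, (len(genes), len(samples))),
        index=genes,
        columns=samples,
    )
    return ck.ExpressionMatrix(species_id="ath", data=data)


@pytest.fixture
def small_profile(small_matrix, small_sheet) -> ck.TissueProfile:
    return ck.tissue_profile(small_matrix, small_sheet)


def make_profile(means: dict[str, list[float]], n_rep: int = 3,
                 variance: float = 0.25) -> ck.TissueProfile:
    """Profile with given per-tissue gene means and constant variance."""
    tissues = sorted(means)
    genes = [f"g{i}" for i in range(len(next(iter(means.values()))))]
    m = pd.DataFrame({t: means[t] for t in tissues}, index=genes)
    v = pd.DataFrame(variance, index=genes, columns=tissues)
    n = pd.Series(n_rep, index=tissues, dtype=int)
    return ck.TissueProfile(
        species_id="ath", means=m, variances=v, n_replicates=n
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic dataset shared across tests."""
    params = ck.SimulationParams(seed=42)
    matrices, sheet, truth = ck.simulate_expression(params)
    return params, matrices, sheet, truth


@pytest.fixture(scope="session")
def tiny_obo(tmp_path_factory):
    """Synthetic 200-term DAG + annotations written once per session."""
    outdir = tmp_path_factory.mktemp("go")
    params = ck.SimulationParams(
        seed=5, genes_per_species=300, n_nonconserved_vascular=25
    )
    truth = ck.make_truth(params, np.random.default_rng(5))
    obo, annot = ck.simulate_annotations(
        params, truth, outdir / "go.obo", outdir / "annot.tsv",
        outdir / "process_map.tsv",
    )
    return params, truth, obo, annot, outdir / "process_map.tsv"
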