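"""Shared fixtures. The heavy simulation fixtures are session-scoped and
shared between the unit suites and the acceptance tests so each expensive
computation runs once."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import pleiomap as pm
from pleiomap.io import PipelineConfig, PValueMatrix, run_pipeline


@dataclass(frozen=True)
class ScenarioAFit:
    """One scenario-A replicate: simulation, (trait 1, trait 2) data and fit."""

    seed: int
    sim: pm.SimResult
    data: pm.PairData
    fit: pm.PairMixtureFit


@pytest.fixture(scope="session")
def scenario_a_fits() -> list[ScenarioAFit]:
    """20 scenario-A replicates at M=20,000 with the (1, 2) pair fitted."""
    out = []
    for seed in range(1, 21):
        sim = pm.simulate_scenario(pm.scenario_preset("A", n_snps=20_000, seed=seed))
        data = pm.PairData(
            p1=sim.pvalues.iloc[:, 0].to_numpy(),
            p2=sim.pvalues.iloc[:, 1].to_numpy(),
            snp_ids=tuple(sim.pvalues.index),
        )
        out.append(ScenarioAFit(seed=seed, sim=sim, data=data, fit=pm.fit_pair_em(data)))
    return out


@pytest.fixture(scope="session")
def null_lrt_results() -> tuple[np.ndarray, np.ndarray]:
    """(statistics, p-values) for 200 independent null pairs at M=10,000."""
    stats_, pvals = [], []
    for seed in range(200):
        sim = pm.simulate_scenario(
            pm.SimScenario(
                n_snps=10_000,
                n_pheno=2,
                signal_prop=(0.2, 0.2),
                beta_shape=(0.4, 0.4),
                seed=10_000 + seed,
            )
        )
        res = pm.lrt_pleiotropy(
            pm.PairData(
                p1=sim.pvalues.iloc[:, 0].to_numpy(),
                p2=sim.pvalues.iloc[:, 1].to_numpy(),
            )
        )
        stats_.append(res.statistic)
        pvals.append(res.pvalue)
    return np.asarray(stats_), np.asarray(pvals)


@dataclass(frozen=True)
class PipelineRun:
    scenario: str
    seed: int
    pleiotropy: pm.PleiotropyMatrix
    coords: np.ndarray
    labels: np.ndarray


def _run_scenario(name: str, seed: int) -> PipelineRun:
    sim = pm.simulate_scenario(pm.scenario_preset(name, n_snps=20_000, seed=seed))
    result = run_pipeline(
        PValueMatrix.from_frame(sim.pvalues),
        PipelineConfig(lam=0.0, epsilon=None, n_clusters=3, seed=seed, make_plot=False),
    )
    return PipelineRun(
        scenario=name,
        seed=seed,
        pleiotropy=result.pleiotropy,
        coords=result.phenomap.coords,
        labels=result.clusters.labels,
    )


@pytest.fixture(scope="session")
def scenario_pipelines() -> dict[str, list[PipelineRun]]:
    """Full pipeline runs (lam=0, auto epsilon, k=3 k-means) for scenarios
    A, C, D over seeds 1..10."""
    return {
        name: [_run_scenario(name, seed) for seed in range(1, 11)]
        for name in ("A", "C", "D")
    }


def co_membership(labels: np.ndarray) -> np.ndarray:
    """Boolean co-membership matrix, the label-permutation-invariant view."""
    labels = np.asarray(labels)
    return labels[:, None] == labels[None, :]
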