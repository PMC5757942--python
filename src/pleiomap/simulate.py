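"""Synthetic GWAS summary statistics with a controllable pleiotropic overlap structure.

Five-trait presets ``A``-``D`` mirror a standard simulation design: every trait
has a marginal signal proportion ``q_k``, designated trait pairs share an
*extra overlap* fraction ``rho`` beyond chance, signal p-values follow
``Beta(alpha_k, 1)`` and null p-values are Uniform(0, 1).

Overlap convention
------------------
For a designated pair ``(i, j, rho)`` the indicator for trait ``i`` is drawn
at rate ``q_i``; conditional on it being 1, trait ``j``'s indicator is 1 with
probability ``rho + (1 - rho) * q_j`` (chance plus the extra-overlap mass),
and conditional on it being 0 with the complementary rate
``(q_j - q_i * (rho + (1 - rho) * q_j)) / (1 - q_i)`` that keeps trait j's
marginal exactly ``q_j``. The rule reduces to independence at ``rho = 0``
(joint fraction ``q_i * q_j``, the by-chance overlap) and forces full sharing
at ``rho = 1``; designs where the complementary rate would be negative
(``q_i`` much larger than ``q_j`` with high ``rho``) are rejected up front.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimScenario",
    "LatentStates",
    "SimResult",
    "scenario_preset",
    "simulate_latent",
    "simulate_pvalues",
    "simulate_scenario",
]

_PRESET_NAMES = ("A", "B", "C", "D")


@dataclass(frozen=True)
class SimScenario:
    """Generative design for one simulated p-value matrix.

    Parameters
    ----------
    n_snps : int
        Number of SNPs (rows) M.
    n_pheno : int
        Number of phenotypes (columns) K.
    signal_prop : tuple of float
        Per-phenotype marginal association probability ``q_k``, each in (0, 1).
    overlap_pairs : tuple of (int, int, float)
        Designated pairs ``(i, j, rho)`` using 0-based phenotype indices;
        ``rho`` in [0, 1] is the extra-overlap fraction.
    beta_shape : tuple of float
        Per-phenotype Beta shape ``alpha_k`` in (0, 1) for associated p-values.
    seed : int
        Seed for the single generator used to draw latent states and p-values.
    """

    n_snps: int
    n_pheno: int
    signal_prop: tuple[float, ...]
    overlap_pairs: tuple[tuple[int, int, float], ...] = ()
    beta_shape: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError(f"n_snps must be positive, got {self.n_snps}")
        if self.n_pheno < 1:
            raise ValueError(f"n_pheno must be positive, got {self.n_pheno}")
        q = tuple(float(v) for v in self.signal_prop)
        if len(q) != self.n_pheno:
            raise ValueError("signal_prop length must equal n_pheno")
        if any(not 0.0 < v < 1.0 for v in q):
            raise ValueError("signal proportions must lie in (0, 1)")
        shape = tuple(float(v) for v in self.beta_shape) or (0.4,) * self.n_pheno
        if len(shape) != self.n_pheno:
            raise ValueError("beta_shape length must equal n_pheno")
        if any(not 0.0 < a < 1.0 for a in shape):
            raise ValueError("beta shapes must lie in (0, 1)")
        pairs = tuple((int(i), int(j), float(r)) for i, j, r in self.overlap_pairs)
        seen: set[int] = set()
        for i, j, rho in pairs:
            if i == j:
                raise ValueError(f"overlap pair ({i}, {j}) must involve two phenotypes")
            if not (0 <= i < self.n_pheno and 0 <= j < self.n_pheno):
                raise ValueError(f"overlap pair ({i}, {j}) out of range")
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"rho must lie in [0, 1], got {rho}")
            if i in seen or j in seen:
                raise ValueError("each phenotype may appear in at most one overlap pair")
            seen.update((i, j))
            if q[j] - q[i] * (rho + (1.0 - rho) * q[j]) < 0.0:
                raise ValueError(
                    f"pair ({i}, {j}, rho={rho}) cannot preserve the marginal "
                    f"q_j={q[j]}: the extra overlap exceeds it"
                )
        object.__setattr__(self, "signal_prop", q)
        object.__setattr__(self, "beta_shape", shape)
        object.__setattr__(self, "overlap_pairs", pairs)

    @property
    def phenotype_names(self) -> list[str]:
        return [f"GWAS_{k + 1}" for k in range(self.n_pheno)]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class LatentStates:
    """M x K binary matrix of per-SNP association indicators."""

    assoc: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.assoc, dtype=np.int8)
        if a.ndim != 2:
            raise ValueError("assoc must be a 2-D matrix")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("assoc entries must be 0 or 1")
        object.__setattr__(self, "assoc", a)

    @property
    def shape(self) -> tuple[int, int]:
        return self.assoc.shape


@dataclass(frozen=True)
class SimResult:
    """Latent states plus the generated p-value matrix and the scenario used."""

    latent: LatentStates
    pvalues: pd.DataFrame  # rows = SNP ids, columns = phenotype names
    scenario: SimScenario

    def write(self, outdir: str | Path, prefix: str = "sim") -> dict[str, Path]:
        """Write p-values, latent states (TSV) and the scenario (JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pvalues": outdir / f"{prefix}_pvalues.tsv",
            "latent": outdir / f"{prefix}_latent.tsv",
            "scenario": outdir / f"{prefix}_scenario.json",
        }
        self.pvalues.to_csv(paths["pvalues"], sep="\t", index_label="snp_id")
        latent = pd.DataFrame(
            self.latent.assoc, index=self.pvalues.index, columns=self.pvalues.columns
        )
        latent.to_csv(paths["latent"], sep="\t", index_label="snp_id")
        paths["scenario"].write_text(self.scenario.to_json())
        return paths


def scenario_preset(name: str, n_snps: int = 20_000, seed: int = 0) -> SimScenario:
    """Return one of the four five-phenotype benchmark designs.

    ``A``: q = 0.2 everywhere, pairs (1,2) and (3,4) with rho = 0.75.
    ``B``: same with rho = 0.25 for both pairs.
    ``C``: rho = 0.25 for (1,2) and rho = 0.75 for (3,4).
    ``D``: q = 0.2 for traits 1, 2 and 5, q = 0.05 for traits 3, 4; rho = 0.75.

    Phenotype 5 is always unpaired (the negative control) and every
    associated p-value is drawn from Beta(0.4, 1).
    """
    name = str(name).upper()
    if name not in _PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; expected one of {_PRESET_NAMES}")
    q = {
        "A": (0.2, 0.2, 0.2, 0.2, 0.2),
        "B": (0.2, 0.2, 0.2, 0.2, 0.2),
        "C": (0.2, 0.2, 0.2, 0.2, 0.2),
        "D": (0.2, 0.2, 0.05, 0.05, 0.2),
    }[name]
    rho12, rho34 = {
        "A": (0.75, 0.75),
        "B": (0.25, 0.25),
        "C": (0.25, 0.75),
        "D": (0.75, 0.75),
    }[name]
    return SimScenario(
        n_snps=n_snps,
        n_pheno=5,
        signal_prop=q,
        overlap_pairs=((0, 1, rho12), (2, 3, rho34)),
        beta_shape=(0.4,) * 5,
        seed=seed,
    )


def simulate_latent(
    scenario: SimScenario, rng: np.random.Generator | None = None
) -> LatentStates:
    """Draw the M x K association-indicator matrix under the overlap convention."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    m, k = scenario.n_snps, scenario.n_pheno
    q = np.asarray(scenario.signal_prop)
    assoc = np.empty((m, k), dtype=np.int8)
    paired = set()
    for i, j, rho in scenario.overlap_pairs:
        zi = rng.random(m) < q[i]
        # sharing rate given z_i = 1, and the complementary rate given
        # z_i = 0 that keeps trait j's marginal exactly q_j
        p_share = rho + (1.0 - rho) * q[j]
        p_rest = (q[j] - q[i] * p_share) / (1.0 - q[i])
        zj = rng.random(m) < np.where(zi, p_share, p_rest)
        assoc[:, i] = zi
        assoc[:, j] = zj
        paired.update((i, j))
    for col in range(k):
        if col not in paired:
            assoc[:, col] = rng.random(m) < q[col]
    return LatentStates(assoc=assoc)


def simulate_pvalues(
    latent: LatentStates,
    scenario: SimScenario,
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Fill in p-values: Beta(alpha_k, 1) where associated, Uniform(0, 1) otherwise."""
    if latent.shape != (scenario.n_snps, scenario.n_pheno):
        raise ValueError(
            f"latent shape {latent.shape} does not match scenario "
            f"({scenario.n_snps}, {scenario.n_pheno})"
        )
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 1)
    m, k = latent.shape
    u = rng.random((m, k))
    alpha = np.asarray(scenario.beta_shape)
    # inverse-CDF draw: u**(1/alpha) ~ Beta(alpha, 1)
    pvals = np.where(latent.assoc == 1, u ** (1.0 / alpha), u)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    snp_ids = [f"snp_{i + 1}" for i in range(m)]
    frame = pd.DataFrame(pvals, index=pd.Index(snp_ids, name="snp_id"),
                         columns=scenario.phenotype_names)
    return SimResult(latent=latent, pvalues=frame, scenario=scenario)


def simulate_scenario(scenario: SimScenario) -> SimResult:
    """Latent states and p-values from a single seeded generator."""
    rng = np.random.default_rng(scenario.seed)
    latent = simulate_latent(scenario, rng)
    return simulate_pvalues(latent, scenario, rng)
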