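"""Pairwise pleiotropy likelihood-ratio tests and the all-pairs p-value matrix.

The null hypothesis for a phenotype pair is that the two traits' association
signals are independent, i.e. ``pi11 = (pi10 + pi11) * (pi01 + pi11)``. Under
that constraint the joint likelihood factorizes exactly into the product of
the two marginal two-group mixtures, so the null is fitted as two independent
marginal EMs. The statistic ``T = 2 * (ll_alt - ll_null)`` is referred to the
upper tail of chi-square with 1 degree of freedom; the asymptotics assume a
large number of SNPs (hundreds of thousands in typical GWAS panels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .mixture import EMConfig, PairData, PairMixtureFit, fit_marginal_em, fit_pair_em

__all__ = ["LrtResult", "PleiotropyMatrix", "lrt_pleiotropy", "pairwise_matrix"]

logger = logging.getLogger(__name__)

PVALUE_FLOOR = 1e-300  # representable floor for stored p-values

# below this many SNPs the chi-square approximation is flagged as shaky
_ASYMPTOTIC_M_WARN = 1000


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    pvalue: float
    log_pvalue: float  # natural log, exact even when pvalue underflows
    alt_fit: PairMixtureFit
    null_loglik: float
    converged: bool


@dataclass(frozen=True)
class PleiotropyMatrix:
    """Symmetric K x K pleiotropy test results for all phenotype pairs.

    ``pvalues`` has unit diagonal; ``log_pvalues`` carries the natural-log
    p-values without underflow (0 on the diagonal) and is what the distance
    transform consumes; ``pair_fits`` maps (i, j) with i < j to the
    alternative-model fit, reused by joint association mapping.
    """

    pvalues: np.ndarray
    statistics: np.ndarray
    log_pvalues: np.ndarray
    phenotype_names: tuple[str, ...]
    pair_fits: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.pvalues, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("pvalues must be square")
        if not np.allclose(p, p.T):
            raise ValueError("pvalues must be symmetric")

    @property
    def n_pheno(self) -> int:
        return self.pvalues.shape[0]

    def to_frame(self) -> pd.DataFrame:
        names = list(self.phenotype_names)
        return pd.DataFrame(self.pvalues, index=names, columns=names)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="phenotype")

    def to_records(self) -> list[dict]:
        """Per-pair records (statistic, p-value, convergence) for JSON export."""
        recs = []
        k = self.n_pheno
        for i in range(k):
            for j in range(i + 1, k):
                fit = self.pair_fits.get((i, j))
                recs.append(
                    {
                        "pair": [self.phenotype_names[i], self.phenotype_names[j]],
                        "statistic": float(self.statistics[i, j]),
                        "pvalue": float(self.pvalues[i, j]),
                        "log_pvalue": float(self.log_pvalues[i, j]),
                        "converged": bool(fit.converged) if fit is not None else None,
                        "n_iter": int(fit.n_iter) if fit is not None else None,
                    }
                )
        return recs


def lrt_pleiotropy(data: PairData, config: EMConfig | None = None) -> LrtResult:
    """Likelihood-ratio test of independent versus shared association signals."""
    config = config or EMConfig()
    if data.n_snps < _ASYMPTOTIC_M_WARN:
        logger.warning(
            "only %d SNPs: the chi-square(1) null may be inaccurate", data.n_snps
        )
    null1 = fit_marginal_em(data.p1, config)
    null2 = fit_marginal_em(data.p2, config)
    null_ll = null1.loglik + null2.loglik
    # two EM starts for the alternative: the default null-dominant start and
    # the factorized-null solution itself; starting at the null fit makes
    # ll_alt >= ll_null up to stopping error because EM never decreases the
    # likelihood, so a materially negative statistic cannot occur
    alt = fit_pair_em(data, config)
    null_pi = np.array(
        [
            (1 - null1.pi1) * (1 - null2.pi1),
            null1.pi1 * (1 - null2.pi1),
            (1 - null1.pi1) * null2.pi1,
            null1.pi1 * null2.pi1,
        ]
    )
    alt2 = fit_pair_em(data, config, init=(null_pi, null1.alpha, null2.alpha))
    if alt2.loglik > alt.loglik:
        alt = alt2
    stat = 2.0 * (alt.loglik - null_ll)
    if stat < 0.0:
        # nested models guarantee T >= 0 at global optima; a negative value
        # means one EM stopped at a worse local optimum
        logger.warning("negative LRT statistic %.3g clamped to 0", stat)
        stat = 0.0
    converged = alt.converged and null1.converged and null2.converged
    if not converged:
        logger.warning("EM non-convergence in pleiotropy LRT; result flagged")
    return LrtResult(
        statistic=float(stat),
        pvalue=float(stats.chi2.sf(stat, df=1)),
        log_pvalue=float(stats.chi2.logsf(stat, df=1)),
        alt_fit=alt,
        null_loglik=float(null_ll),
        converged=converged,
    )


def pairwise_matrix(
    pmat: pd.DataFrame, config: EMConfig | None = None
) -> PleiotropyMatrix:
    """Run the pleiotropy LRT on every phenotype pair of a p-value matrix.

    Parameters
    ----------
    pmat : DataFrame
        M x K p-value matrix; index = SNP ids, columns = phenotype names.
    """
    config = config or EMConfig()
    k = pmat.shape[1]
    if k < 3:
        raise ValueError(f"need at least 3 phenotypes for a phenotype map, got {k}")
    values = pmat.to_numpy(dtype=float)
    names = tuple(str(c) for c in pmat.columns)
    snp_ids = tuple(str(s) for s in pmat.index)

    pvals = np.ones((k, k))
    stats_mat = np.zeros((k, k))
    logp = np.zeros((k, k))
    fits: dict[tuple[int, int], PairMixtureFit] = {}
    for i in range(k):
        for j in range(i + 1, k):
            res = lrt_pleiotropy(
                PairData(p1=values[:, i], p2=values[:, j], snp_ids=snp_ids), config
            )
            pvals[i, j] = pvals[j, i] = max(res.pvalue, PVALUE_FLOOR)
            stats_mat[i, j] = stats_mat[j, i] = res.statistic
            logp[i, j] = logp[j, i] = res.log_pvalue
            fits[(i, j)] = res.alt_fit
            logger.info(
                "pair %s-%s: T=%.3f, log10 p=%.2f, iters=%d",
                names[i], names[j], res.statistic,
                res.log_pvalue / np.log(10), res.alt_fit.n_iter,
            )
    return PleiotropyMatrix(
        pvalues=pvals,
        statistics=stats_mat,
        log_pvalues=logp,
        phenotype_names=names,
        pair_fits=fits,
    )
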