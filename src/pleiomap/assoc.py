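"""Joint association mapping: the shared-SNP table at a global FDR level.

Each SNP's local FDR for an association pattern (default ``"11"``, shared by
both traits) is one minus its posterior probability of that pattern. SNPs are
sorted by ascending local FDR and the largest prefix whose running mean local
FDR stays at or below the requested global FDR level is reported — the direct
posterior probability rule for converting local to global FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mixture import STATE_LABELS, PairData, PairMixtureFit, posterior_z

__all__ = ["AssocTable", "joint_assoc"]


@dataclass(frozen=True)
class AssocTable:
    """Selected SNPs for one phenotype pair, sorted by ascending local FDR."""

    table: pd.DataFrame  # columns: snp_id, local_fdr
    pair: tuple[str, str]
    pattern: str
    global_fdr_level: float

    @property
    def n_selected(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def joint_assoc(
    fit: PairMixtureFit,
    data: PairData,
    global_fdr: float = 0.05,
    pattern: str = "11",
    pair: tuple[str, str] = ("trait_1", "trait_2"),
) -> AssocTable:
    """SNPs associated under ``pattern`` at the given global FDR level."""
    if not 0.0 < global_fdr < 1.0:
        raise ValueError(f"global_fdr must lie in (0, 1), got {global_fdr}")
    if pattern not in STATE_LABELS:
        raise ValueError(f"pattern must be one of {STATE_LABELS}, got {pattern!r}")
    post = posterior_z(fit, data)
    local_fdr = 1.0 - post[:, STATE_LABELS.index(pattern)]

    snp_ids = (
        list(data.snp_ids)
        if data.snp_ids is not None
        else [f"snp_{i + 1}" for i in range(data.n_snps)]
    )
    order = np.argsort(local_fdr, kind="stable")
    sorted_fdr = local_fdr[order]
    running_mean = np.cumsum(sorted_fdr) / np.arange(1, sorted_fdr.size + 1)
    passing = np.nonzero(running_mean <= global_fdr)[0]
    n_keep = int(passing[-1]) + 1 if passing.size else 0

    kept = order[:n_keep]
    table = pd.DataFrame(
        {"snp_id": [snp_ids[i] for i in kept], "local_fdr": local_fdr[kept]}
    )
    return AssocTable(
        table=table, pair=pair, pattern=pattern, global_fdr_level=float(global_fdr)
    )
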