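"""Reading and validating p-value matrices, pipeline orchestration, outputs.

The pipeline mirrors the batch fit-then-visualize workflow: fit all pairwise
pleiotropy tests, Box-Cox-transform the p-value matrix into distances, embed
with isomap, cluster the coordinates, and (optionally) produce joint
association tables for chosen pairs. All outputs land in one directory with
a JSON run-manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import AssocTable, joint_assoc
from .clustering import ClusterResult, cluster_phenotypes
from .exceptions import PleiomapError
from .mixture import EMConfig, PairData, P_FLOOR
from .phenomap import EmbeddingConfig, PhenotypeMap, isomap_embed, transform_distance_matrix
from .pleiotropy import PleiotropyMatrix, pairwise_matrix
from .plotting import plot_map

__all__ = [
    "PValueMatrix",
    "PipelineConfig",
    "PipelineResult",
    "PipelineStageError",
    "read_pvalue_matrix",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class PipelineStageError(PleiomapError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class PValueMatrix:
    """Validated M x K p-value matrix with SNP ids and phenotype names."""

    values: np.ndarray
    snp_ids: tuple[str, ...]
    phenotype_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D")
        if v.shape != (len(self.snp_ids), len(self.phenotype_names)):
            raise ValueError("values shape must match snp_ids x phenotype_names")
        if len(set(self.phenotype_names)) != len(self.phenotype_names):
            raise ValueError("phenotype names must be unique")
        if not np.isfinite(v).all():
            raise ValueError("values must be finite")
        if v.min(initial=1) <= 0 or v.max(initial=0) > 1:
            raise ValueError("values must lie in (0, 1]")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PValueMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            snp_ids=tuple(str(i) for i in frame.index),
            phenotype_names=tuple(str(c) for c in frame.columns),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.snp_ids, name="snp_id"),
            columns=list(self.phenotype_names),
        )

    def pair_data(self, i: int, j: int) -> PairData:
        return PairData(
            p1=self.values[:, i], p2=self.values[:, j], snp_ids=self.snp_ids
        )

    @property
    def n_snps(self) -> int:
        return self.values.shape[0]

    @property
    def n_pheno(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for the full fit -> embed -> cluster -> assoc pipeline."""

    lam: float = 0.0
    epsilon: float | None = None  # None = auto (smallest connecting grid value)
    ndim: int = 2
    n_clusters: int = 3
    cluster_method: str = "kmeans"
    global_fdr: float = 0.05
    assoc_pairs: tuple[tuple[str, str], ...] = ()
    em: EMConfig = field(default_factory=EMConfig)
    seed: int = 0
    make_plot: bool = True
    plot_title: str = "phenotype-map"


@dataclass(frozen=True)
class PipelineResult:
    pleiotropy: PleiotropyMatrix
    phenomap: PhenotypeMap
    clusters: ClusterResult
    assoc_tables: tuple[AssocTable, ...]
    manifest: dict


def read_pvalue_matrix(
    path: str | Path,
    delimiter: str | None = None,
    clip: bool = False,
    clip_floor: float = P_FLOOR,
) -> PValueMatrix:
    """Read a delimited p-value matrix (first column SNP ids, header names).

    Values must lie in (0, 1]; with ``clip=True`` values in [0, clip_floor)
    are raised to ``clip_floor`` (logged), otherwise any out-of-range cell is
    an error naming its location. Rows containing missing values are dropped
    with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no phenotype columns found")
    if frame.columns.str.startswith("Unnamed").all():
        logger.warning("%s: no phenotype header; generating names", path)
        frame.columns = [f"pheno_{k + 1}" for k in range(frame.shape[1])]
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            raise ValueError(
                f"{path}: non-numeric value at row {bad.idxmax()!r}, column {col!r}"
            )
        frame[col] = coerced
    n_before = len(frame)
    frame = frame.dropna()
    dropped = n_before - len(frame)
    if dropped:
        logger.warning("%s: dropped %d rows with missing values", path, dropped)
    if len(frame) == 0:
        raise ValueError(f"{path}: no rows remain after filtering")

    values = frame.to_numpy(dtype=float)
    too_high = values > 1.0
    if too_high.any():
        r, c = map(int, np.argwhere(too_high)[0])
        raise ValueError(
            f"{path}: p-value {values[r, c]} > 1 at row {frame.index[r]!r}, "
            f"column {frame.columns[c]!r}"
        )
    too_low = values < clip_floor
    if too_low.any():
        if not clip:
            r, c = map(int, np.argwhere(too_low)[0])
            raise ValueError(
                f"{path}: p-value {values[r, c]} <= 0 (or below floor) at row "
                f"{frame.index[r]!r}, column {frame.columns[c]!r}; pass clip=True"
            )
        logger.info("%s: clipped %d values up to %g", path, too_low.sum(), clip_floor)
        values = np.maximum(values, clip_floor)
        frame = pd.DataFrame(values, index=frame.index, columns=frame.columns)
    return PValueMatrix.from_frame(frame)


def _coordinates_frame(pmap: PhenotypeMap, clusters: ClusterResult) -> pd.DataFrame:
    names = list(pmap.phenotype_names) or [
        f"pheno_{k + 1}" for k in range(pmap.coords.shape[0])
    ]
    frame = pd.DataFrame(
        pmap.coords,
        index=pd.Index(names, name="phenotype"),
        columns=[f"dim{a + 1}" for a in range(pmap.coords.shape[1])],
    )
    frame["cluster"] = clusters.labels
    return frame


def run_pipeline(
    pmat: PValueMatrix,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline; write outputs when ``outdir`` is given.

    Outputs: pleiotropy p-value matrix (TSV), per-pair fit summaries (JSON),
    coordinates + cluster labels (TSV), assoc tables (CSV), run manifest
    (JSON), and a static map plot (PDF + PNG). All compute happens before
    any file is written, so a failed run leaves no partial outputs.
    """
    config = config or PipelineConfig()

    def _stage(name, fn):
        try:
            return fn()
        except PleiomapError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineStageError(name, exc) from exc

    frame = pmat.to_frame()
    pleio = _stage("pairwise_matrix", lambda: pairwise_matrix(frame, config.em))
    td = _stage(
        "transform_distance_matrix",
        lambda: transform_distance_matrix(pleio, config.lam),
    )
    emb_cfg = EmbeddingConfig(epsilon=config.epsilon, ndim=config.ndim, lam=config.lam)
    pmap = _stage("isomap_embed", lambda: isomap_embed(td, emb_cfg))
    clusters = _stage(
        "cluster_phenotypes",
        lambda: cluster_phenotypes(
            pmap, config.n_clusters, method=config.cluster_method, seed=config.seed
        ),
    )
    pmap = pmap.with_clusters(clusters.labels)

    name_to_idx = {n: i for i, n in enumerate(pmat.phenotype_names)}
    tables = []
    for a, b in config.assoc_pairs:
        if a not in name_to_idx or b not in name_to_idx:
            raise ValueError(f"unknown phenotype in assoc pair ({a}, {b})")
        i, j = sorted((name_to_idx[a], name_to_idx[b]))
        fit = pleio.pair_fits[(i, j)]
        tables.append(
            _stage(
                "joint_assoc",
                lambda i=i, j=j, fit=fit: joint_assoc(
                    fit,
                    pmat.pair_data(i, j),
                    global_fdr=config.global_fdr,
                    pair=(pmat.phenotype_names[i], pmat.phenotype_names[j]),
                ),
            )
        )

    manifest = {
        "package": "pleiomap",
        "version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "n_snps": pmat.n_snps,
        "n_pheno": pmat.n_pheno,
        "n_pair_fits": len(pleio.pair_fits),
        "config": {
            "lam": config.lam,
            "epsilon": pmap.config.epsilon,
            "ndim": config.ndim,
            "n_clusters": config.n_clusters,
            "cluster_method": config.cluster_method,
            "global_fdr": config.global_fdr,
            "em": asdict(config.em),
        },
        "pair_convergence": {
            f"{pleio.phenotype_names[i]}|{pleio.phenotype_names[j]}": {
                "converged": bool(fit.converged),
                "n_iter": int(fit.n_iter),
            }
            for (i, j), fit in pleio.pair_fits.items()
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }

    result = PipelineResult(
        pleiotropy=pleio,
        phenomap=pmap,
        clusters=clusters,
        assoc_tables=tuple(tables),
        manifest=manifest,
    )
    if outdir is not None:
        write_outputs(result, outdir, config)
    return result


def write_outputs(
    result: PipelineResult, outdir: str | Path, config: PipelineConfig
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["pleiotropy"] = outdir / "pleiotropy_pvalues.tsv"
    result.pleiotropy.write_tsv(paths["pleiotropy"])

    paths["pairs"] = outdir / "pleiotropy_pairs.json"
    paths["pairs"].write_text(json.dumps(result.pleiotropy.to_records(), indent=2))

    paths["coordinates"] = outdir / "coordinates.tsv"
    _coordinates_frame(result.phenomap, result.clusters).to_csv(
        paths["coordinates"], sep="\t"
    )

    for table in result.assoc_tables:
        key = f"assoc_{table.pair[0]}_{table.pair[1]}"
        paths[key] = outdir / f"{key}.csv"
        table.write_csv(paths[key])

    if config.make_plot:
        for ext in ("pdf", "png"):
            paths[f"plot_{ext}"] = outdir / f"{config.plot_title}-map.{ext}"
            plot_map(result.phenomap, paths[f"plot_{ext}"])

    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(result.manifest, indent=2))
    return paths
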