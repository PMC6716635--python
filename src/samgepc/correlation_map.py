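"""Candidate-vs-global per-patient fold-change correlation maps.

For a patient stratum (typically an LVEF-change tertile), every gene's
per-patient log2 fold change (baseline → LOCF) is correlated, across
patients, between each candidate gene (columns) and each genome-wide gene
(rows) using Spearman's rho with midranks for ties.  Row/column display
orders come from average-linkage hierarchical clustering with a
1 − Pearson-correlation distance on the rho vectors; orders derived from the
largest-remodeling stratum are then reapplied to the other strata so maps are
comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .io_model import ExpressionMatrix, PairedView
from .platform_quant import paired_delta


def per_patient_log2fc(
    expr: ExpressionMatrix,
    paired_view: PairedView,
    patients: Sequence[str] | None = None,
    **delta_kwargs,
) -> pd.DataFrame:
    """Genes × patients log2 fold-change matrix for a patient stratum."""
    deltas = paired_delta(expr, paired_view, **delta_kwargs)
    fc = deltas.delta
    if patients is not None:
        patients = [p for p in patients if p in fc.columns]
        fc = fc[patients]
    if fc.shape[1] < 4:
        raise ValueError(
            f"need >= 4 patients for a correlation map, got {fc.shape[1]}"
        )
    return fc


@dataclass
class CorrelationMap:
    """Spearman rho between candidate (columns) and global (rows) fold changes."""

    rho: pd.DataFrame
    stratum: str = ""
    row_order: list[str] = field(default_factory=list)
    col_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.row_order:
            self.row_order = list(self.rho.index)
        if not self.col_order:
            self.col_order = list(self.rho.columns)

    def ordered(self) -> pd.DataFrame:
        return self.rho.loc[self.row_order, self.col_order]


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, axis=1)


def spearman_map(
    candidate_fc: pd.DataFrame, global_fc: pd.DataFrame, stratum: str = ""
) -> CorrelationMap:
    """rho(row, col) = Spearman correlation across patients of the two genes'
    log2 fold changes.  Genes with zero variance get missing rho."""
    patients = [p for p in global_fc.columns if p in candidate_fc.columns]
    if len(patients) < 4:
        raise ValueError("matrices must share >= 4 patient columns")
    g = _rank_rows(global_fc[patients].to_numpy(float))
    c = _rank_rows(candidate_fc[patients].to_numpy(float))
    g_c = g - g.mean(axis=1, keepdims=True)
    c_c = c - c.mean(axis=1, keepdims=True)
    g_sd = np.sqrt((g_c**2).sum(axis=1))
    c_sd = np.sqrt((c_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (g_c @ c_c.T) / np.outer(g_sd, c_sd)
    rho[~np.isfinite(rho)] = np.nan
    return CorrelationMap(
        pd.DataFrame(rho, index=global_fc.index, columns=candidate_fc.index),
        stratum=stratum,
    )


def _leaf_order(vectors: pd.DataFrame) -> list[str]:
    """Average-linkage leaf order on 1 − Pearson distance between the rows of
    ``vectors``; items are pre-sorted lexicographically so the result does not
    depend on input order."""
    ids = sorted(vectors.index)
    if len(ids) < 2:
        return list(vectors.index)
    x = vectors.loc[ids].to_numpy(float)
    x = np.nan_to_num(x, nan=0.0)  # missing rho treated as 0 for ordering only
    sd = x.std(axis=1)
    corr = np.corrcoef(x)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist[sd == 0, :] = 1.0  # flat vectors: maximally distant from everything
    dist[:, sd == 0] = 1.0
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(len(ids), k=1)]
    z = linkage(np.clip(condensed, 0, None), method="average")
    return [ids[i] for i in leaves_list(z)]


def order_by_clustering(map_reference: CorrelationMap) -> tuple[list[str], list[str]]:
    """(row order, column order) from hierarchical clustering of the reference
    stratum's map; apply the same orders to the other strata."""
    row_order = _leaf_order(map_reference.rho)
    col_order = _leaf_order(map_reference.rho.T)
    return row_order, col_order


def apply_order(
    cmap: CorrelationMap, row_order: Sequence[str], col_order: Sequence[str]
) -> CorrelationMap:
    if sorted(row_order) != sorted(cmap.rho.index) or sorted(col_order) != sorted(
        cmap.rho.columns
    ):
        raise ValueError("orders must be permutations of the map's axes")
    return CorrelationMap(cmap.rho, cmap.stratum, list(row_order), list(col_order))


def export_map(
    cmap: CorrelationMap, directory: str | Path, prefix: str = "rho", heatmap: bool = False
) -> dict[str, Path]:
    """Write the rho matrix (display order) as TSV plus a JSON sidecar with the
    orders and stratum; optionally render a raster heatmap (needs matplotlib)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    tsv = directory / f"{prefix}_matrix.tsv"
    try:
        cmap.ordered().round(6).to_csv(tsv, sep="\t", index_label="gene_id")
    except OSError as exc:
        raise OSError(f"failed writing {tsv}: {exc}") from exc
    paths["matrix"] = tsv
    sidecar = directory / f"{prefix}_orders.json"
    sidecar.write_text(
        json.dumps(
            {
                "stratum": cmap.stratum,
                "row_order": cmap.row_order,
                "col_order": cmap.col_order,
            },
            indent=2,
        )
    )
    paths["orders"] = sidecar
    if heatmap:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 10))
        ax.imshow(cmap.ordered().to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_title(f"Candidate vs global fold-change rho ({cmap.stratum or 'all'})")
        ax.set_xlabel("candidate genes")
        ax.set_ylabel("global genes")
        png = directory / f"{prefix}_heatmap.png"
        fig.savefig(png, dpi=120)
        plt.close(fig)
        paths["heatmap"] = png
    return paths
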