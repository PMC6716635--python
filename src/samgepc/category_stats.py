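"""Up/down asymmetry of biologic categories with Benjamini-Hochberg adjustment.

Each category's up- vs. down-regulated counts are tested against a 50:50
split by a continuity-corrected chi-square goodness of fit:

    n = n_up + n_down,  E = n/2,
    chi2 = 2 · max(|n_up − E| − 0.5, 0)² / E   on 1 df.

The BH family is the categories themselves; the overall totals row is tested
with the same statistic but excluded from the family.  An exact binomial
(sign test) alternative is available via ``method="binomial"``.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import DEFAULT_CATEGORIES, GeneAnnotation

UNCLASSIFIED = "Unclassified/Unknown Function"


def updown_asymmetry_p(n_up: int, n_down: int, method: str = "chi2") -> float:
    """Two-sided p for asymmetry between up- and down-regulated counts."""
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be non-negative")
    n = n_up + n_down
    if n == 0:
        raise ValueError("both counts are zero")
    if method == "binomial":
        return float(stats.binomtest(n_up, n, 0.5).pvalue)
    if method != "chi2":
        raise ValueError(f"unknown method {method!r}")
    e = n / 2.0
    dev = max(abs(n_up - e) - 0.5, 0.0)
    chi2 = 2.0 * dev**2 / e
    return float(stats.chi2.sf(chi2, df=1))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def category_table(
    gene_directions: Mapping[str, str],
    annotation: GeneAnnotation,
    vocabulary: Iterable[str] | None = None,
    method: str = "chi2",
) -> pd.DataFrame:
    """Per-category up/down counts with raw and BH-adjusted asymmetry p-values.

    ``gene_directions`` maps concordantly changed genes to 'up'/'down'.
    Unannotated genes fall into the unclassified category.  The returned frame
    has one row per non-empty category (deterministic vocabulary order) plus a
    ``Totals`` row tested separately from the BH family.
    """
    if not gene_directions:
        raise ValueError("empty gene list")
    vocab = list(vocabulary) if vocabulary is not None else list(annotation.vocabulary)
    if UNCLASSIFIED not in vocab:
        vocab.append(UNCLASSIFIED)
    counts = {c: [0, 0] for c in vocab}
    for gene, direction in gene_directions.items():
        cat = annotation.category_of(gene) or UNCLASSIFIED
        if cat not in counts:
            cat = UNCLASSIFIED
        if direction == "up":
            counts[cat][0] += 1
        elif direction == "down":
            counts[cat][1] += 1
    rows = [(c, u, d) for c, (u, d) in counts.items() if u + d > 0]
    df = pd.DataFrame(rows, columns=["category", "n_up", "n_down"]).set_index("category")
    df["p_raw"] = [
        updown_asymmetry_p(u, d, method=method) for u, d in zip(df["n_up"], df["n_down"])
    ]
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    total_up = int(df["n_up"].sum())
    total_down = int(df["n_down"].sum())
    totals = pd.DataFrame(
        {
            "n_up": [total_up],
            "n_down": [total_down],
            "p_raw": [updown_asymmetry_p(total_up, total_down, method=method)],
            "p_adj": [np.nan],  # totals row sits outside the BH family
        },
        index=pd.Index(["Totals"], name="category"),
    )
    return pd.concat([df, totals])
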