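"""Platform-specific normalization, paired deltas and fold changes.

All three platforms are reduced to a common per-gene × per-patient *delta* on
a log2 scale, with the sign convention that positive delta = upregulation:

* RT-qPCR: ``−ddCt`` where ``ddCt = dCt_LOCF − dCt_baseline`` and
  ``dCt = Ct(gene) − Ct(reference)`` (Ct falls as abundance rises, hence the
  sign flip);
* microarray: ``log2 intensity_LOCF − log2 intensity_baseline`` (inputs are
  already log2-scale, RMA-style);
* RNA-Seq: ``log2 FPKM_LOCF − log2 FPKM_baseline`` with FPKM floored at a
  small epsilon before the log (the formula is undefined at zero).

The group fold change is the *mean of the per-patient ratios*,
``mean(2**delta)`` — not ``2**mean(delta)`` — and the R/NR fold change is the
ratio of the two group fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io_model import ExpressionMatrix, PairedView, Platform

DEFAULT_REFERENCE_GENE = "GAPDH"
DEFAULT_FPKM_FLOOR = 0.01


def normalize_qpcr_dct(
    ct_matrix: ExpressionMatrix, reference_gene: str = DEFAULT_REFERENCE_GENE
) -> pd.DataFrame:
    """Reference-gene normalization: dCt(g, s) = Ct(g, s) − Ct(ref, s).

    The reference gene's own row becomes all zeros; callers must treat it as
    non-analyzable (DEG calling drops it).  Raises if the reference gene has a
    missing Ct in any sample, listing the samples.
    """
    if ct_matrix.platform is not Platform.QPCR:
        raise ValueError(f"expected a qPCR matrix, got {ct_matrix.platform.value}")
    if reference_gene not in ct_matrix.values.index:
        raise ValueError(f"reference gene {reference_gene!r} not in matrix")
    ref = ct_matrix.values.loc[reference_gene]
    missing = list(ref.index[ref.isna()])
    if missing:
        raise ValueError(
            f"reference gene {reference_gene!r} has missing Ct in samples: {missing}"
        )
    return ct_matrix.values.sub(ref, axis=1)


@dataclass
class PairedDelta:
    """Per-gene × per-patient paired log2 delta plus the raw paired readouts.

    ``baseline`` and ``locf`` hold the platform's analysis readout (dCt for
    qPCR, log2 intensity for microarray, raw FPKM for RNA-Seq), columns are
    patient IDs.  ``delta`` follows the sign convention above.
    """

    platform: Platform
    delta: pd.DataFrame
    baseline: pd.DataFrame
    locf: pd.DataFrame
    non_analyzable: tuple[str, ...] = ()  # e.g. the qPCR reference gene

    @property
    def patients(self) -> list[str]:
        return list(self.delta.columns)


def paired_delta(
    expr: ExpressionMatrix,
    paired_view: PairedView,
    *,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    fpkm_floor: float = DEFAULT_FPKM_FLOOR,
) -> PairedDelta:
    """Compute per-patient paired deltas under the platform's convention."""
    patients = paired_view.patients
    b_cols = [paired_view.baseline_col[p] for p in patients]
    l_cols = [paired_view.locf_col[p] for p in patients]

    non_analyzable: tuple[str, ...] = ()
    if expr.platform is Platform.QPCR:
        dct = normalize_qpcr_dct(expr, reference_gene)
        base = dct[b_cols].set_axis(patients, axis=1)
        locf = dct[l_cols].set_axis(patients, axis=1)
        delta = base - locf  # −ddCt: lower Ct at LOCF ⇒ upregulated ⇒ positive
        non_analyzable = (reference_gene,)
    elif expr.platform is Platform.MICROARRAY:
        base = expr.values[b_cols].set_axis(patients, axis=1)
        locf = expr.values[l_cols].set_axis(patients, axis=1)
        delta = locf - base
    else:  # RNA-Seq FPKM
        base = expr.values[b_cols].set_axis(patients, axis=1)
        locf = expr.values[l_cols].set_axis(patients, axis=1)
        delta = np.log2(locf.clip(lower=fpkm_floor)) - np.log2(
            base.clip(lower=fpkm_floor)
        )
    return PairedDelta(expr.platform, delta, base, locf, non_analyzable)


def fold_change_within(deltas: PairedDelta | pd.DataFrame, members: Iterable[str]) -> pd.Series:
    """Per-gene group fold change: mean over members of 2**delta.

    Missing per-patient deltas are excluded; a gene with no member having a
    defined delta gets a missing fold.
    """
    df = deltas.delta if isinstance(deltas, PairedDelta) else deltas
    members = [m for m in members if m in df.columns]
    if not members:
        raise ValueError("no group members present in the delta table")
    return np.exp2(df[members]).mean(axis=1, skipna=True)


def fold_change_between(fold_r: pd.Series, fold_nr: pd.Series) -> pd.Series:
    """R/NR fold-change ratio: fold_R / fold_NR (missing where NR is 0/missing)."""
    ratio = fold_r / fold_nr.replace(0.0, np.nan)
    return ratio


def direction_of(fold: pd.Series) -> pd.Series:
    """'up' iff fold > 1, 'down' iff fold < 1, missing ('undefined') at exactly 1."""
    out = pd.Series(pd.NA, index=fold.index, dtype="object")
    out[fold > 1] = "up"
    out[fold < 1] = "down"
    return out
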