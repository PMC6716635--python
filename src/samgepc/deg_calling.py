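"""Per-gene differential-expression testing and DEG set construction.

Within-group change from baseline is assessed by the Wilcoxon signed-rank
test on the platform's untransformed readouts (dCt, intensity, FPKM); the
R-vs-NR analysis compares the subtracted (LOCF − baseline) values between
groups by the Wilcoxon rank-sum test.  A gene is a DEG when its two-sided
p < alpha (default 0.05, unadjusted — cross-platform concordance, not
multiplicity correction, is the error-control device) *and* its fold-change
direction is defined.

Direction is always taken from the fold-change table, never the test
statistic, so the inverted Ct scale of qPCR cannot flip calls.

Exact null distributions are used for small samples (signed-rank: n ≤ 25 with
no tied |differences|; rank-sum: min group ≤ 10 with no ties); larger samples
use the normal approximation with tie and continuity corrections.  The
vectorized matrix routines used for genome-wide calling implement the same
approximation and are cross-checked against scipy and enumeration oracles in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ExpressionMatrix, PairedView, Platform
from .platform_quant import (
    DEFAULT_FPKM_FLOOR,
    DEFAULT_REFERENCE_GENE,
    PairedDelta,
    direction_of,
    fold_change_between,
    fold_change_within,
    paired_delta,
)

ANALYSES = ("R_change", "NR_change", "RvsNR")

MIN_PAIRS = 4  # signed-rank needs >= 4 informative pairs
MIN_COMBINED = 8  # rank-sum needs combined n >= 8


# ---------------------------------------------------------------------------
# scalar tests


def wilcoxon_signed_rank_p(baseline, locf) -> float:
    """Two-sided paired Wilcoxon signed-rank p for baseline vs. LOCF.

    Pairs with a missing value are dropped, then zero differences are dropped
    (Wilcoxon's rule).  Returns NaN when fewer than 4 informative pairs
    remain (the gene is under-powered, not an error).
    """
    b = np.asarray(baseline, dtype=float)
    l = np.asarray(locf, dtype=float)
    if b.shape != l.shape:
        raise ValueError("baseline and locf must have equal length")
    keep = np.isfinite(b) & np.isfinite(l)
    d = l[keep] - b[keep]
    d = d[d != 0]
    n = len(d)
    if n < MIN_PAIRS:
        return float("nan")
    ranks_tied = len(np.unique(np.abs(d))) < n
    if n <= 25 and not ranks_tied:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", alternative="two-sided", correction=True, method=method
    )
    return float(res.pvalue)


def wilcoxon_rank_sum_p(deltas_r, deltas_nr) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p for R vs. NR deltas."""
    x = np.asarray(deltas_r, dtype=float)
    y = np.asarray(deltas_nr, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# vectorized (genes × patients) tests — normal approximation with tie and
# continuity corrections, matching the scalar large-sample path


def _tie_term(ranked_abs: np.ndarray) -> np.ndarray:
    """Per-row sum of (t^3 − t) over tie groups of |differences| (NaN-aware)."""
    out = np.zeros(ranked_abs.shape[0])
    for i, row in enumerate(ranked_abs):
        vals = row[np.isfinite(row)]
        if len(vals) == 0:
            continue
        _, counts = np.unique(vals, return_counts=True)
        counts = counts[counts > 1]
        if len(counts):
            out[i] = float(np.sum(counts**3 - counts))
    return out


def signed_rank_p_matrix(baseline: np.ndarray, locf: np.ndarray) -> np.ndarray:
    """Row-wise two-sided signed-rank p (normal approx, tie + continuity corrected).

    Rows with fewer than 4 informative pairs get NaN.
    """
    d = np.asarray(locf, dtype=float) - np.asarray(baseline, dtype=float)
    valid = np.isfinite(d) & (d != 0)
    absd = np.where(valid, np.abs(d), np.nan)
    n = valid.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        ranks = stats.rankdata(absd, axis=1, nan_policy="omit")
    t_plus = np.where(valid & (d > 0), np.where(np.isfinite(ranks), ranks, 0.0), 0.0).sum(axis=1)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(absd) / 48.0
    diff = t_plus - mu
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
        z = np.where(np.abs(diff) <= 0.5, 0.0, z)
        p = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
    p[n < MIN_PAIRS] = np.nan
    p[var <= 0] = np.nan  # all |d| tied at one value after drops
    return p


@lru_cache(maxsize=64)
def _signed_rank_cdf(n: int) -> np.ndarray:
    """Exact CDF of the positive-rank sum T+ under the null for n untied pairs.

    Counts, by dynamic programming, the subsets of ranks {1..n} attaining each
    possible sum; all 2^n sign assignments are equally likely under H0.
    """
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.concatenate([np.zeros(r), counts[: m + 1 - r]])
        counts = counts + shifted
    return np.cumsum(counts) / 2.0**n


def _exact_signed_rank_p(t_plus: int, n: int) -> float:
    cdf = _signed_rank_cdf(n)
    p_le = cdf[t_plus]
    p_ge = 1.0 - (cdf[t_plus - 1] if t_plus > 0 else 0.0)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def signed_rank_p_rows(baseline: np.ndarray, locf: np.ndarray) -> np.ndarray:
    """Row-wise signed-rank p with the scalar routine's exact/approx switch.

    Approximation (tie + continuity corrected) everywhere, then rows with
    n ≤ 25 informative pairs and no tied |differences| are replaced by the
    exact table value; small tied rows fall back to the scalar path.
    """
    baseline = np.asarray(baseline, dtype=float)
    locf = np.asarray(locf, dtype=float)
    p = signed_rank_p_matrix(baseline, locf)
    d = locf - baseline
    valid = np.isfinite(d) & (d != 0)
    n_eff = valid.sum(axis=1)
    for i in np.flatnonzero((n_eff >= MIN_PAIRS) & (n_eff <= 25)):
        di = d[i][valid[i]]
        absd = np.abs(di)
        if len(np.unique(absd)) == len(absd):
            ranks = stats.rankdata(absd)
            t_plus = int(round(ranks[di > 0].sum()))
            p[i] = _exact_signed_rank_p(t_plus, len(di))
        else:
            p[i] = wilcoxon_signed_rank_p(np.zeros_like(di), di)
    return p


def rank_sum_p_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p (normal approx with corrections)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y], axis=1)
    ok = np.isfinite(combined)
    nx = np.isfinite(x).sum(axis=1).astype(float)
    ny = np.isfinite(y).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        ranks = stats.rankdata(np.where(ok, combined, np.nan), axis=1, nan_policy="omit")
    rx = np.where(np.isfinite(ranks[:, : x.shape[1]]), ranks[:, : x.shape[1]], 0.0).sum(axis=1)
    u = rx - nx * (nx + 1) / 2.0  # Mann-Whitney U for x
    mu = nx * ny / 2.0
    n_tot = nx + ny
    tie = _tie_term(np.where(ok, combined, np.nan))
    with np.errstate(invalid="ignore", divide="ignore"):
        var = nx * ny / 12.0 * ((n_tot + 1) - tie / (n_tot * (n_tot - 1)))
        diff = u - mu
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
        z = np.where(np.abs(diff) <= 0.5, 0.0, z)
        p = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
    p[(nx == 0) | (ny == 0) | (n_tot < MIN_COMBINED)] = np.nan
    p[var <= 0] = np.nan
    return p


# ---------------------------------------------------------------------------
# DEG sets


@dataclass
class DEGSet:
    """Per-gene differential-call table for one (cohort, platform, analysis).

    ``records`` is indexed by gene id with columns ``p_value``,
    ``fold_change``, ``direction``, ``n_used`` and ``significant``.
    """

    cohort: str
    platform: str
    analysis: str
    alpha: float
    records: pd.DataFrame
    universe_size: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.universe_size:
            self.universe_size = len(self.records)

    @property
    def significant(self) -> pd.DataFrame:
        return self.records[self.records["significant"]]

    def directional(self) -> dict[str, str]:
        """gene → 'up'/'down' over the significant subset."""
        sig = self.significant
        return dict(zip(sig.index, sig["direction"]))

    def __len__(self) -> int:
        return int(self.records["significant"].sum())


def call_degs(
    expr: ExpressionMatrix,
    paired_view: PairedView,
    phenotype: pd.DataFrame,
    analysis: str,
    alpha: float = 0.05,
    *,
    cohort: str = "cohort",
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    fpkm_floor: float = DEFAULT_FPKM_FLOOR,
    deltas: PairedDelta | None = None,
    restrict_patients: list[str] | None = None,
) -> DEGSet:
    """Run one analysis (R_change, NR_change or RvsNR) over every gene.

    ``restrict_patients`` optionally narrows the patient pool (used for
    tertile-stratified change-from-baseline calling, where the stratum stands
    in for the R group).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if analysis not in ANALYSES:
        raise ValueError(f"analysis must be one of {ANALYSES}")
    if deltas is None:
        deltas = paired_delta(
            expr, paired_view, reference_gene=reference_gene, fpkm_floor=fpkm_floor
        )
    paired = set(deltas.patients)
    members = {
        g: [p for p in phenotype.index[phenotype["group"] == g] if p in paired]
        for g in ("R", "NR")
    }
    if restrict_patients is not None:
        pool = [p for p in restrict_patients if p in paired]
    genes = deltas.delta.index

    if analysis in ("R_change", "NR_change"):
        group = "R" if analysis == "R_change" else "NR"
        pats = pool if restrict_patients is not None else members[group]
        if not pats:
            raise ValueError(f"no paired patients in group {group}")
        base = deltas.baseline[pats].to_numpy(float)
        locf = deltas.locf[pats].to_numpy(float)
        n_used = (np.isfinite(base) & np.isfinite(locf)).sum(axis=1)
        p = signed_rank_p_rows(base, locf)
        fold = fold_change_within(deltas, pats)
    else:
        if not members["R"] or not members["NR"]:
            raise ValueError("RvsNR requires paired patients in both R and NR")
        xr = deltas.delta[members["R"]].to_numpy(float)
        xnr = deltas.delta[members["NR"]].to_numpy(float)
        n_used = np.isfinite(xr).sum(axis=1) + np.isfinite(xnr).sum(axis=1)
        small = np.minimum(np.isfinite(xr).sum(axis=1), np.isfinite(xnr).sum(axis=1)) <= 10
        p = rank_sum_p_matrix(xr, xnr)
        if small.any():
            for i in np.flatnonzero(small):
                xi = xr[i][np.isfinite(xr[i])]
                yi = xnr[i][np.isfinite(xnr[i])]
                p[i] = wilcoxon_rank_sum_p(xi, yi) if len(xi) and len(yi) else np.nan
        fold = fold_change_between(
            fold_change_within(deltas, members["R"]),
            fold_change_within(deltas, members["NR"]),
        )

    records = pd.DataFrame(
        {
            "p_value": p,
            "fold_change": fold,
            "direction": direction_of(fold),
            "n_used": n_used,
        },
        index=genes,
    )
    records.index.name = "gene_id"
    if deltas.non_analyzable:
        records = records.drop(index=list(deltas.non_analyzable), errors="ignore")
    records["significant"] = (
        (records["p_value"] < alpha) & records["direction"].notna()
    ).fillna(False)
    return DEGSet(
        cohort=cohort,
        platform=expr.platform.value,
        analysis=analysis,
        alpha=alpha,
        records=records,
        universe_size=len(records),
    )


def compare_detection_counts(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-proportion test of detection rates k1/n1 vs k2/n2.

    Chi-square on the 2×2 table, Fisher's exact test when any expected cell
    is below 5.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("universe sizes must be positive")
    if k1 > n1 or k2 > n2:
        raise ValueError("detected count exceeds universe size")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table.sum() == 0:
        raise ValueError("empty table")
    expected = stats.contingency.expected_freq(table)
    if (expected <= 5).any():
        return float(stats.fisher_exact(table)[1])
    chi2, p, _, _ = stats.chi2_contingency(table)
    if chi2 == 0:
        return 1.0
    return float(p)
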