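"""Cross-platform (C_cpT) and cross-cohort (C_ccT) concordance of DEG sets.

A gene is a *concordant change* when it is significant (two-sided p < 0.05)
with the same direction on both compared sides.  Total concordance is

    C = 100 · 2 · n_concordant / (n_side_a + n_side_b)

— identical to the "percentage of overlapping genes" (POG) statistic when the
two sides measure the same gene universe.  Genes significant on both sides
with *opposite* directions count in the denominator but never the numerator
and are reported separately as discordant.

The same formula serves cross-cohort concordance (same platform, two
cohorts).  Printed percentages follow the reporting convention: nearest
integer when ≥ 20, one decimal below 20; the raw value is always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .deg_calling import DEGSet


@dataclass
class DirectionalSet:
    """A bare directional DEG list (gene → 'up'/'down'), e.g. a published table."""

    label: str
    directions: dict[str, str]

    def directional(self) -> dict[str, str]:
        return dict(self.directions)

    def __len__(self) -> int:
        return len(self.directions)


SideLike = DEGSet | DirectionalSet | Mapping[str, str]


def _as_directional(side: SideLike) -> dict[str, str]:
    if hasattr(side, "directional"):
        return side.directional()  # type: ignore[union-attr]
    return dict(side)  # type: ignore[arg-type]


def format_percent(value: float | None) -> str:
    """Reporting convention: '60%' at ≥ 20, '2.4%' below 20, 'n/a' if undefined."""
    if value is None or not np.isfinite(value):
        return "n/a"
    if value >= 20:
        return f"{math.floor(value + 0.5):.0f}%"
    return f"{math.floor(value * 10 + 0.5) / 10:.1f}%"


@dataclass
class ConcordanceResult:
    """One platform-pair or cohort-pair comparison."""

    label: str
    n_side_a: int
    n_side_b: int
    concordant_up: list[str] | None
    concordant_down: list[str] | None
    discordant: list[str] | None
    n_concordant: int
    c_total: float | None  # raw percent; None when both sides are empty

    @property
    def c_total_printed(self) -> str:
        return format_percent(self.c_total)

    @classmethod
    def from_counts(
        cls, n_side_a: int, n_side_b: int, n_concordant: int, label: str = ""
    ) -> "ConcordanceResult":
        """Build a result from published summary counts (no gene lists)."""
        if n_concordant * 2 > n_side_a + n_side_b:
            raise ValueError("more concordant slots than DEGs")
        denom = n_side_a + n_side_b
        c = 100.0 * 2.0 * n_concordant / denom if denom else None
        return cls(label, n_side_a, n_side_b, None, None, None, n_concordant, c)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_a": self.n_side_a,
            "n_b": self.n_side_b,
            "concordant_up": self.concordant_up,
            "concordant_down": self.concordant_down,
            "discordant": self.discordant,
            "c_total_raw": self.c_total,
            "c_total_printed": self.c_total_printed,
        }


def concordant_set(
    degs_a: SideLike, degs_b: SideLike, universe: Sequence[str] | None = None
) -> tuple[list[str], list[str], list[str]]:
    """(up, down, discordant) gene lists for two directional DEG sets.

    Both sides are restricted to ``universe`` (when given) before
    intersecting.  Lists are sorted for determinism.
    """
    a = _as_directional(degs_a)
    b = _as_directional(degs_b)
    if universe is not None:
        u = set(universe)
        a = {g: d for g, d in a.items() if g in u}
        b = {g: d for g, d in b.items() if g in u}
    shared = set(a) & set(b)
    up = sorted(g for g in shared if a[g] == "up" and b[g] == "up")
    down = sorted(g for g in shared if a[g] == "down" and b[g] == "down")
    discordant = sorted(g for g in shared if a[g] != b[g])
    return up, down, discordant


def concordance_total(
    degs_a: SideLike,
    degs_b: SideLike,
    universe: Sequence[str] | None = None,
    label: str = "",
) -> ConcordanceResult:
    """Total concordance C = 100·2·n_concordant/(n_a + n_b) for two sides."""
    a = _as_directional(degs_a)
    b = _as_directional(degs_b)
    if universe is not None:
        u = set(universe)
        a = {g: d for g, d in a.items() if g in u}
        b = {g: d for g, d in b.items() if g in u}
    up, down, disc = concordant_set(a, b)
    n_a, n_b = len(a), len(b)
    n_conc = len(up) + len(down)
    denom = n_a + n_b
    c = 100.0 * 2.0 * n_conc / denom if denom > 0 else None
    return ConcordanceResult(label, n_a, n_b, up, down, disc, n_conc, c)


def _concordance_2x2(res: ConcordanceResult) -> list[float]:
    denom = res.n_side_a + res.n_side_b
    return [2.0 * res.n_concordant, float(denom - 2 * res.n_concordant)]


def compare_concordances(res_1: ConcordanceResult, res_2: ConcordanceResult) -> float:
    """p-value for a difference between two concordance values.

    2×2 test on concordant slots (2·n_concordant) vs. the remainder of each
    summed denominator; chi-square with Fisher fallback for small cells.
    """
    for r in (res_1, res_2):
        if r.c_total is None:
            raise ValueError(f"concordance undefined for {r.label!r}")
    table = np.array([_concordance_2x2(res_1), _concordance_2x2(res_2)])
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        return float(stats.fisher_exact(np.rint(table).astype(int))[1])
    chi2, p, _, _ = stats.chi2_contingency(table)
    return 1.0 if chi2 == 0 else float(p)


def homogeneity_p(
    counts: Sequence[tuple[float, float]], rng_seed: int = 0, n_mc: int = 10_000
) -> float:
    """Homogeneity p for per-stratum (concordant, non-concordant) counts.

    Chi-square over the 2×k table; when any expected cell is below 5 a seeded
    Monte-Carlo permutation chi-square (Fisher-Freeman-Halton style) is used
    instead, since no closed-form exact r×k test is available.
    """
    table = np.array(counts, dtype=float).T  # 2 × k
    if table.shape[1] < 2:
        raise ValueError("need >= 2 strata")
    if (table.sum(axis=0) == 0).any():
        raise ValueError("a stratum has no observations")
    expected = stats.contingency.expected_freq(table)
    chi2_obs = ((table - expected) ** 2 / expected).sum()
    if chi2_obs == 0:
        return 1.0
    if (expected < 5).any():
        rng = np.random.default_rng(rng_seed)
        k = table.shape[1]
        col_tot = table.sum(axis=0).astype(int)
        row1 = int(table[0].sum())
        n = int(table.sum())
        labels = np.repeat(np.arange(k), col_tot)
        hits = 0
        for _ in range(n_mc):
            chosen = rng.choice(n, size=row1, replace=False)
            c1 = np.bincount(labels[chosen], minlength=k)
            sim = np.array([c1, col_tot - c1], dtype=float)
            exp = stats.contingency.expected_freq(sim)
            chi2 = ((sim - exp) ** 2 / exp).sum()
            if chi2 >= chi2_obs - 1e-12:
                hits += 1
        return (hits + 1) / (n_mc + 1)
    return float(stats.chi2.sf(chi2_obs, df=table.shape[1] - 1))


def concordance_by_stratum(
    pairs: Sequence[tuple[SideLike, SideLike]],
    universe: Sequence[str] | None = None,
    labels: Sequence[str] | None = None,
) -> tuple[list[ConcordanceResult], float]:
    """Per-stratum concordance plus an overall homogeneity p-value."""
    results = []
    for i, (a, b) in enumerate(pairs):
        lab = labels[i] if labels else f"stratum {i + 1}"
        results.append(concordance_total(a, b, universe, label=lab))
    valid = [r for r in results if r.c_total is not None]
    if len(valid) < 2:
        raise ValueError("need >= 2 strata with defined concordance")
    counts = [
        (2.0 * r.n_concordant, float(r.n_side_a + r.n_side_b - 2 * r.n_concordant))
        for r in valid
    ]
    return results, homogeneity_p(counts)


def expected_null_concordance(alpha: float) -> float:
    """Probability two independent null tests are both significant with
    agreeing direction: alpha²/2 (0.00125 at alpha = 0.05)."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return alpha**2 / 2.0
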