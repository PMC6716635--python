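"""Seeded generator of paired three-platform cohorts with planted effects.

The generator emulates the study design the package analyses: a β-blocker
reverse-remodeling cohort of responders and nonresponders biopsied at
baseline and follow-up, measured contemporaneously by RT-qPCR (candidate
genes + GAPDH), microarray (log2 intensities) and RNA-Seq (negative-binomial
counts converted to FPKM).  A fraction of genes carries a true
responder-linked log2 effect (half up, half down, candidates enriched 2×),
optionally scaled by each responder's standardized LVEF change
(``effect_lvef_coupling``).

``platform_drift_sd`` adds a per-(gene, platform) systematic baseline→LOCF
shift shared by *all* patients.  It models platform-specific temporal /
batch artifacts: such shifts are detected as spurious within-group changes
but cancel in the R-vs-NR contrast — the mechanism by which the R/NR design
out-performs the R-only analysis on concordance.  Set it to 0 for a fully
null, independent-measurement condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import ConcordanceResult, SideLike, _as_directional
from .deg_calling import DEGSet
from .io_model import (
    DEFAULT_CATEGORIES,
    ClinicalTable,
    ExpressionMatrix,
    GeneAnnotation,
    Platform,
)

REFERENCE_GENE = "GAPDH"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Cohort-size, LVEF and noise defaults follow the reported study
    characteristics: 31 responders vs 16 nonresponders, baseline LVEF ~26±8 %
    truncated at the ≤40 % entry criterion, LVEF change 21±10 % in R vs 1±4 %
    in NR (SEM→SD converted with the group sizes), and 8/47 of patients
    missing the 12-month measurement (their 3-month value is carried
    forward).
    """

    n_responders: int = 31
    n_nonresponders: int = 16
    n_genes: int = 2000
    n_candidates: int = 50
    frac_true_deg: float = 0.1
    effect_log2fc_mean: float = 1.0
    effect_log2fc_sd: float = 0.25
    lvef_baseline_mean: float = 26.0
    lvef_baseline_sd: float = 8.0
    lvef_delta_r_mean: float = 21.0
    lvef_delta_r_sd: float = 10.0
    lvef_delta_nr_mean: float = 1.0
    lvef_delta_nr_sd: float = 4.0
    effect_lvef_coupling: float = 0.5
    qpcr_ct_sd: float = 0.35
    array_log2_sd: float = 0.4
    rnaseq_dispersion: float = 0.2
    platform_drift_sd: float = 0.25
    missing_m12_frac: float = 8 / 47
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_true_deg", "missing_m12_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.effect_lvef_coupling <= 1.0):
            raise ValueError("effect_lvef_coupling must be in [0, 1]")
        for name in (
            "effect_log2fc_sd",
            "lvef_baseline_sd",
            "lvef_delta_r_sd",
            "lvef_delta_nr_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("qpcr_ct_sd", "array_log2_sd", "rnaseq_dispersion", "platform_drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (0 = noise-free limit)")
        if self.n_genes < 1 or self.n_candidates < 0 or self.n_candidates > self.n_genes:
            raise ValueError("need 0 <= n_candidates <= n_genes, n_genes >= 1")
        if self.n_responders + self.n_nonresponders < 1:
            raise ValueError("cohort must contain at least one patient")

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "truth": np.random.default_rng(children[0]),
            "cohort": np.random.default_rng(children[1]),
            "expression": np.random.default_rng(children[2]),
        }


def _gene_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_genes))
    return [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def make_truth(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Ground-truth table: per-gene true log2 effects and flags.

    The first ``n_candidates`` gene ids form the candidate module; candidates
    are enriched 2× among true DEGs.  Up and down planted effects differ in
    count by at most 1.  NR effects are 0.
    """
    rng = rng or config.rngs()["truth"]
    genes = _gene_ids(config)
    n_true = int(round(config.frac_true_deg * config.n_genes))
    weights = np.ones(config.n_genes)
    weights[: config.n_candidates] = 2.0
    weights /= weights.sum()
    true_idx = rng.choice(config.n_genes, size=n_true, replace=False, p=weights)
    lfc = np.zeros(config.n_genes)
    magnitudes = np.abs(
        rng.normal(config.effect_log2fc_mean, config.effect_log2fc_sd, size=n_true)
    )
    signs = np.ones(n_true)
    signs[n_true // 2 :] = -1.0
    rng.shuffle(signs)
    lfc[true_idx] = magnitudes * signs
    df = pd.DataFrame(
        {
            "true_log2fc_R": lfc,
            "true_log2fc_NR": 0.0,
            "is_null": lfc == 0.0,
            "is_candidate": [i < config.n_candidates for i in range(config.n_genes)],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return df


def simulate_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ClinicalTable, pd.DataFrame]:
    """Simulate the clinical table plus the ground-truth phenotype labels."""
    rng = rng or config.rngs()["cohort"]
    n = config.n_responders + config.n_nonresponders
    width = max(3, len(str(n)))
    patients = [f"P{i:0{width}d}" for i in range(1, n + 1)]
    true_group = np.array(
        ["R"] * config.n_responders + ["NR"] * config.n_nonresponders
    )
    # truncated normal: redraw above the <=40 entry criterion
    base = rng.normal(config.lvef_baseline_mean, config.lvef_baseline_sd, size=n)
    for _ in range(100):
        bad = (base > 40) | (base < 5)
        if not bad.any():
            break
        base[bad] = rng.normal(config.lvef_baseline_mean, config.lvef_baseline_sd, size=bad.sum())
    base = np.clip(base, 5, 40)
    delta = np.where(
        true_group == "R",
        rng.normal(config.lvef_delta_r_mean, config.lvef_delta_r_sd, size=n),
        rng.normal(config.lvef_delta_nr_mean, config.lvef_delta_nr_sd, size=n),
    )
    missing_m12 = rng.random(n) < config.missing_m12_frac
    m3 = np.where(
        missing_m12, base + delta, base + 0.5 * delta + rng.normal(0, 2, size=n)
    )
    m12 = np.where(missing_m12, np.nan, base + delta)
    m3 = np.clip(m3, 1, 85)
    m12 = np.where(np.isnan(m12), np.nan, np.clip(m12, 1, 85))
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "lvef_baseline": np.round(base, 1),
                "lvef_m3": np.round(m3, 1),
                "lvef_m12": np.round(m12, 1),
                "rvef_baseline": np.nan,
                "rvef_locf": np.nan,
                "cohort_tags": [{"A-S"} for _ in patients],
            },
            index=pd.Index(patients, name="patient_id"),
        )
    )
    pheno_truth = pd.DataFrame(
        {
            "true_group": true_group,
            "true_lvef_change": delta,
            "locf_timepoint": np.where(missing_m12, "m3", "m12"),
        },
        index=pd.Index(patients, name="patient_id"),
    )
    return clinical, pheno_truth


def simulate_expression(
    config: SimulationConfig,
    clinical: ClinicalTable,
    truth: pd.DataFrame,
    pheno_truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, ExpressionMatrix], GeneAnnotation]:
    """Simulate the three platform matrices plus the gene annotation.

    Latent per-sample log2 abundance = gene baseline + patient offset
    + (at LOCF) true effect × responder LVEF multiplier + platform drift.
    qPCR (candidates + GAPDH): Ct = 38 − latent + noise; microarray: latent
    + noise; RNA-Seq: negative-binomial counts at mean 2^latent scaled by
    fixed gene lengths and log-normal library factors, reported as FPKM.
    """
    rng = rng or config.rngs()["expression"]
    genes = list(truth.index)
    n_genes = len(genes)
    patients = list(clinical.patients)
    n_pat = len(patients)
    locf_tp = pheno_truth["locf_timepoint"]

    gene_base = rng.normal(5.0, 1.5, size=n_genes)
    patient_offset = rng.normal(0.0, 0.5, size=(n_genes, n_pat))

    is_r = (pheno_truth["true_group"] == "R").to_numpy()
    mult = np.ones(n_pat)
    if is_r.sum() >= 2 and config.effect_lvef_coupling > 0:
        d = pheno_truth["true_lvef_change"].to_numpy(float)
        z = (d[is_r] - d[is_r].mean()) / d[is_r].std(ddof=1)
        mult[is_r] = np.maximum(0.0, 1.0 + config.effect_lvef_coupling * z)
    effect = np.where(
        is_r[None, :],
        truth["true_log2fc_R"].to_numpy()[:, None] * mult[None, :],
        truth["true_log2fc_NR"].to_numpy()[:, None],
    )

    latent_base = gene_base[:, None] + patient_offset
    matrices: dict[str, ExpressionMatrix] = {}
    for platform in (Platform.QPCR, Platform.MICROARRAY, Platform.RNASEQ):
        drift = (
            rng.normal(0.0, config.platform_drift_sd, size=(n_genes, 1))
            if config.platform_drift_sd > 0
            else np.zeros((n_genes, 1))
        )
        latent_locf = latent_base + effect + drift
        if platform is Platform.QPCR:
            cand = truth["is_candidate"].to_numpy()
            idx = np.flatnonzero(cand)
            if len(idx) == 0:
                continue
            rows = [genes[i] for i in idx] + [REFERENCE_GENE]
            ref_latent = np.full((1, n_pat), 7.0)
            lat_b = np.vstack([latent_base[idx], ref_latent])
            lat_l = np.vstack([latent_locf[idx], ref_latent])  # GAPDH flat
            cols, vals = _paired_columns(
                patients,
                locf_tp,
                38.0 - lat_b + rng.normal(0, config.qpcr_ct_sd, size=(len(rows), 2 * n_pat))[:, :n_pat],
                38.0 - lat_l + rng.normal(0, config.qpcr_ct_sd, size=(len(rows), 2 * n_pat))[:, n_pat:],
            )
            df = pd.DataFrame(np.clip(vals, 1e-3, None), index=rows, columns=cols)
        elif platform is Platform.MICROARRAY:
            noise = rng.normal(0, config.array_log2_sd, size=(n_genes, 2 * n_pat))
            cols, vals = _paired_columns(
                patients, locf_tp, latent_base + noise[:, :n_pat], latent_locf + noise[:, n_pat:]
            )
            df = pd.DataFrame(vals, index=genes, columns=cols)
        else:
            lengths_kb = rng.uniform(0.5, 10.0, size=n_genes)
            lib = 2e7 * np.exp(rng.normal(0, 0.2, size=2 * n_pat))
            fpkm_b = _nb_fpkm(np.exp2(latent_base), lengths_kb, lib[:n_pat], config, rng)
            fpkm_l = _nb_fpkm(np.exp2(latent_locf), lengths_kb, lib[n_pat:], config, rng)
            cols, vals = _paired_columns(patients, locf_tp, fpkm_b, fpkm_l)
            df = pd.DataFrame(vals, index=genes, columns=cols)
        df.index.name = "gene_id"
        matrices[platform.value] = ExpressionMatrix(platform, df)

    categories = rng.choice(list(DEFAULT_CATEGORIES), size=n_genes)
    annotation = GeneAnnotation(
        pd.DataFrame(
            {"category": categories, "is_candidate": truth["is_candidate"].to_numpy()},
            index=pd.Index(genes, name="gene_id"),
        )
    )
    return matrices, annotation


def _paired_columns(patients, locf_tp, baseline_vals, locf_vals):
    """Interleave baseline and follow-up columns with proper sample keys."""
    cols: list[str] = []
    blocks: list[np.ndarray] = []
    for j, p in enumerate(patients):
        cols.append(f"{p}_baseline")
        blocks.append(baseline_vals[:, j])
        cols.append(f"{p}_{locf_tp[p]}")
        blocks.append(locf_vals[:, j])
    return cols, np.column_stack(blocks)


def _nb_fpkm(fpkm_true, lengths_kb, lib_sizes, config, rng):
    """Negative-binomial counts at the target FPKM, converted back to FPKM."""
    per_million = lib_sizes / 1e6
    mu = fpkm_true * lengths_kb[:, None] * per_million[None, :]
    if config.rnaseq_dispersion <= 0:
        counts = mu  # deterministic limit, supports exactness checks
    else:
        shape = 1.0 / config.rnaseq_dispersion
        lam = rng.gamma(shape, mu * config.rnaseq_dispersion)
        counts = rng.poisson(lam).astype(float)
    return counts / (lengths_kb[:, None] * per_million[None, :])


@dataclass
class SimulatedStudy:
    """Everything one simulated study produces."""

    config: SimulationConfig
    clinical: ClinicalTable
    pheno_truth: pd.DataFrame
    truth: pd.DataFrame
    expression: dict[str, ExpressionMatrix]
    annotation: GeneAnnotation


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the full generator under the config's seed (bit-reproducible)."""
    rngs = config.rngs()
    truth = make_truth(config, rngs["truth"])
    clinical, pheno_truth = simulate_cohort(config, rngs["cohort"])
    expression, annotation = simulate_expression(
        config, clinical, truth, pheno_truth, rngs["expression"]
    )
    return SimulatedStudy(config, clinical, pheno_truth, truth, expression, annotation)


# ---------------------------------------------------------------------------
# recovery metrics


def evaluate_recovery(
    degset: DEGSet, truth: pd.DataFrame, require_direction: bool = True
) -> dict[str, float]:
    """Sensitivity and FDR of one DEG set against the planted truth."""
    genes = degset.records.index
    missing = set(genes) - set(truth.index)
    if missing:
        raise ValueError(f"DEG universe not covered by truth table: {sorted(missing)[:5]}...")
    t = truth.loc[genes]
    planted = ~t["is_null"]
    sig = degset.records["significant"]
    if require_direction:
        true_dir = np.where(t["true_log2fc_R"] > 0, "up", "down")
        correct = sig & planted & (degset.records["direction"] == true_dir)
    else:
        correct = sig & planted
    sensitivity = float(correct.sum() / planted.sum()) if planted.any() else np.nan
    fdr = float((sig & t["is_null"]).sum() / sig.sum()) if sig.any() else 0.0
    return {
        "sensitivity": sensitivity,
        "fdr": fdr,
        "n_planted": int(planted.sum()),
        "n_called": int(sig.sum()),
    }


def null_concordant_fraction(
    degs_a: SideLike, degs_b: SideLike, truth: pd.DataFrame
) -> dict[str, float]:
    """Concordant fraction among planted-null genes, with its Monte-Carlo SE."""
    a = _as_directional(degs_a)
    b = _as_directional(degs_b)
    nulls = set(truth.index[truth["is_null"]])
    if not nulls:
        raise ValueError("truth table contains no null genes")
    conc = {
        g
        for g in (set(a) & set(b) & nulls)
        if a[g] == b[g]
    }
    frac = len(conc) / len(nulls)
    se = float(np.sqrt(max(frac * (1 - frac), 1e-12) / len(nulls)))
    return {"fraction": frac, "se": se, "n_null": len(nulls), "n_concordant": len(conc)}
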