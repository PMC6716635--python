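"""End-to-end orchestration: simulate or load, phenotype, call DEGs,
measure concordance, categorize, and map correlations — from one config.

The run config is a plain mapping (usually parsed from YAML):

.. code-block:: yaml

    seed: 1
    alpha: 0.05
    output_dir: results/run1
    simulate:              # either this block ...
      n_genes: 500
    inputs:                # ... or explicit file paths
      qpcr: qpcr.tsv
      microarray: array.tsv
      rnaseq: rnaseq.tsv
      clinical: clinical.csv
      annotation: annotation.tsv
    analyses: [R_change, NR_change, RvsNR]
    platform_pairs: [[qpcr, microarray], [microarray, rnaseq]]
    tertile_concordance: true
    correlation_maps: false

Every stage's outputs are written under ``output_dir`` and a manifest records
the config hash, seed and package version so a run can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .category_stats import category_table
from .concordance import concordance_by_stratum, concordance_total, format_percent
from .correlation_map import apply_order, order_by_clustering, spearman_map, export_map, per_patient_log2fc
from .deg_calling import DEGSet, call_degs
from .io_model import (
    Platform,
    read_annotation,
    read_clinical_table,
    read_expression_matrix,
    pair_samples,
    shared_gene_universe,
    write_clinical_table,
    write_expression_matrix,
    write_annotation,
)
from .phenotyping import ResponseRules, assign_tertiles, classify_response, select_locf
from .platform_quant import paired_delta
from .synthetic_data import SimulationConfig, simulate_study

DEFAULT_ANALYSES = ("R_change", "NR_change", "RvsNR")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise StageError("config", "run config must be a mapping")
    return dict(config)


def _validate(cfg: dict) -> None:
    if ("simulate" in cfg) == ("inputs" in cfg):
        raise StageError("config", "exactly one of 'simulate' or 'inputs' is required")
    alpha = cfg.get("alpha", 0.05)
    if not (0 < alpha < 1):
        raise StageError("config", f"alpha must be in (0, 1), got {alpha}")
    platforms = set()
    if "inputs" in cfg:
        platforms = {p.value for p in Platform if p.value in cfg["inputs"]}
        if not platforms:
            raise StageError("config", "inputs block names no platform matrices")
    else:
        platforms = {p.value for p in Platform}
    pairs = cfg.get("platform_pairs") or _default_pairs(platforms)
    if not pairs:
        raise StageError("config", "no platform pair to compare")
    for a, b in pairs:
        for p in (a, b):
            if p not in platforms:
                raise StageError(
                    "config", f"platform {p!r} requested but absent from inputs"
                )


def _default_pairs(platforms: set[str]) -> list[tuple[str, str]]:
    order = [p.value for p in Platform]
    present = [p for p in order if p in platforms]
    return [(a, b) for i, a in enumerate(present) for b in present[i + 1 :]]


def run_full_analysis(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Run the whole analysis; returns a dict of in-memory results and writes
    all report artifacts under the output directory."""
    cfg = _load_config(config)
    _validate(cfg)
    outdir = Path(output_dir or cfg.get("output_dir", "samge_output"))
    outdir.mkdir(parents=True, exist_ok=True)
    alpha = float(cfg.get("alpha", 0.05))
    rules = ResponseRules(**cfg.get("response_rules", {}))
    cohort = cfg.get("cohort_label", "A-S")

    # ---- stage: data ------------------------------------------------------
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        sim_kwargs.setdefault("seed", int(cfg.get("seed", 0)))
        sim = simulate_study(SimulationConfig(**sim_kwargs))
        clinical, expression, annotation = sim.clinical, sim.expression, sim.annotation
        truth = sim.truth
        _write_simulated(sim, outdir / "simulated")
    else:
        inputs = cfg["inputs"]
        expression = {
            p.value: read_expression_matrix(inputs[p.value], p)
            for p in Platform
            if p.value in inputs
        }
        clinical = read_clinical_table(inputs["clinical"])
        annotation = (
            read_annotation(inputs["annotation"]) if "annotation" in inputs else None
        )
        truth = None

    # ---- stage: phenotyping ----------------------------------------------
    locf = select_locf(clinical)
    pheno = classify_response(clinical, locf, rules)
    try:
        pheno = assign_tertiles(pheno)
    except ValueError:
        pass  # fewer than 3 classified patients: tertiles stay missing
    pheno.to_csv(outdir / "phenotype.tsv", sep="\t")

    # ---- stage: DEG calling ----------------------------------------------
    analyses = tuple(cfg.get("analyses", DEFAULT_ANALYSES))
    degsets: dict[tuple[str, str], DEGSet] = {}
    views = {}
    deltas = {}
    for name, expr in expression.items():
        view = pair_samples(expr, locf)
        views[name] = view
        deltas[name] = paired_delta(expr, view)
        for analysis in analyses:
            try:
                ds = call_degs(
                    expr, view, pheno, analysis, alpha,
                    cohort=cohort, deltas=deltas[name],
                )
            except ValueError as exc:
                raise StageError("deg_calling", f"{name}/{analysis}: {exc}") from exc
            degsets[(name, analysis)] = ds
            ds.records.to_csv(outdir / f"degs_{name}_{analysis}.tsv", sep="\t")

    # ---- stage: concordance ----------------------------------------------
    pairs = [tuple(p) for p in (cfg.get("platform_pairs") or _default_pairs(set(expression)))]
    report = []
    for a, b in pairs:
        universe = shared_gene_universe(expression[a], expression[b])
        for analysis in analyses:
            res = concordance_total(
                degsets[(a, analysis)], degsets[(b, analysis)], universe,
                label=f"{cohort} {a}/{b} {analysis}",
            )
            report.append(res.to_dict())
    (outdir / "concordance.json").write_text(json.dumps(report, indent=2))

    # ---- stage: tertile concordance --------------------------------------
    tertiles = None
    if cfg.get("tertile_concordance", True) and pairs and pheno["tertile"].notna().any():
        a, b = pairs[0]
        universe = shared_gene_universe(expression[a], expression[b])
        stratum_pairs, labels = [], []
        for t in (1, 2, 3):
            members = list(pheno.index[pheno["tertile"] == t])
            try:
                da = call_degs(expression[a], views[a], pheno, "R_change", alpha,
                               cohort=cohort, deltas=deltas[a], restrict_patients=members)
                db = call_degs(expression[b], views[b], pheno, "R_change", alpha,
                               cohort=cohort, deltas=deltas[b], restrict_patients=members)
            except ValueError:
                continue
            stratum_pairs.append((da, db))
            labels.append(f"tertile {t}")
        if len(stratum_pairs) >= 2:
            results, p_hom = concordance_by_stratum(stratum_pairs, universe, labels)
            tertiles = {
                "strata": [r.to_dict() for r in results],
                "homogeneity_p": p_hom,
            }
            (outdir / "tertile_concordance.json").write_text(json.dumps(tertiles, indent=2))

    # ---- stage: categories ------------------------------------------------
    categories = None
    if annotation is not None and pairs:
        a, b = pairs[-1]
        universe = shared_gene_universe(expression[a], expression[b])
        res = concordance_total(
            degsets[(a, "RvsNR")], degsets[(b, "RvsNR")], universe
        ) if ("RvsNR" in analyses) else None
        if res and res.n_concordant:
            directions = {g: "up" for g in res.concordant_up}
            directions.update({g: "down" for g in res.concordant_down})
            categories = category_table(directions, annotation)
            categories.to_csv(outdir / "category_report.tsv", sep="\t")

    # ---- stage: correlation maps ------------------------------------------
    if cfg.get("correlation_maps", False) and annotation is not None:
        _correlation_maps(expression, views, pheno, annotation, outdir)

    manifest = {
        "version": __version__,
        "seed": cfg.get("seed"),
        "alpha": alpha,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "platforms": sorted(expression),
        "analyses": list(analyses),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "phenotype": pheno,
        "degsets": degsets,
        "concordance": report,
        "tertile_concordance": tertiles,
        "categories": categories,
        "truth": truth,
        "output_dir": outdir,
    }


def _correlation_maps(expression, views, pheno, annotation, outdir):
    """Per-tertile candidate-vs-global rho maps on the microarray platform,
    ordered by the tertile-3 cluster solution."""
    name = "microarray" if "microarray" in expression else sorted(expression)[0]
    expr, view = expression[name], views[name]
    candidates = [g for g in annotation.candidates if g in expr.values.index]
    if len(candidates) < 2:
        return
    maps = {}
    for t in (1, 2, 3):
        members = [p for p in pheno.index[pheno["tertile"] == t] if p in view.patients]
        if len(members) < 4:
            continue
        fc = per_patient_log2fc(expr, view, members)
        maps[t] = spearman_map(fc.loc[candidates], fc, stratum=f"tertile {t}")
    if not maps:
        return
    ref = maps.get(3) or maps[max(maps)]
    row_order, col_order = order_by_clustering(ref)
    for t, cmap in maps.items():
        export_map(apply_order(cmap, row_order, col_order), outdir / "correlation_maps",
                   prefix=f"tertile{t}")


def _write_simulated(sim, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_clinical_table(sim.clinical, outdir / "clinical.csv")
    for name, em in sim.expression.items():
        write_expression_matrix(em, outdir / f"{name}.tsv")
    write_annotation(sim.annotation, outdir / "annotation.tsv")
    sim.truth.to_csv(outdir / "truth.tsv", sep="\t")
    (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(sim.config)))


# ---------------------------------------------------------------------------
# table-shaped report


def report_table1_style(
    degs_r: tuple, degs_rvsnr: tuple, platform_names: tuple[str, str] = ("platform 1", "platform 2"),
    universe=None,
) -> str:
    """Two-platform comparison table: up/down gene lists per platform and
    analysis, concordant columns, and the ``n/total (c%)`` footer."""
    lines = []
    footers = []
    for label, (a, b) in (("R", degs_r), ("R/NR", degs_rvsnr)):
        res = concordance_total(a, b, universe, label=label)
        lines.append(f"== {label} analysis ==")
        for side_name, side in zip(platform_names, (a, b)):
            d = side.directional() if hasattr(side, "directional") else dict(side)
            up = sorted(g for g, v in d.items() if v == "up")
            down = sorted(g for g, v in d.items() if v == "down")
            lines.append(f"{side_name}: up ({len(up)}): {', '.join(up) or '-'}")
            lines.append(f"{side_name}: down ({len(down)}): {', '.join(down) or '-'}")
        lines.append(f"Concordant up: {', '.join(res.concordant_up) or '-'}")
        lines.append(f"Concordant down: {', '.join(res.concordant_down) or '-'}")
        denom = res.n_side_a + res.n_side_b
        if denom:
            footers.append(f"{2 * res.n_concordant}/{denom} ({res.c_total_printed})")
        else:
            footers.append("0/0 (n/a)")
        lines.append("")
    lines.append(
        "Overall total number and % concordance, both platforms, up and "
        f"downregulated genes: R {footers[0]}; R/NR {footers[1]}"
    )
    return "\n".join(lines)
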