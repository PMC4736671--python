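"""End-to-end study orchestration.

``run_study`` chains the whole analysis — simulate (or load) data, edit
and pre-adjust phenotypes, build G and D, fit models A and A+D, compare
them with the mixture-chi-square likelihood-ratio test, correlate
dominance deviations with genomic inbreeding, and cross-validate
predictive ability — and collects everything in a ``StudyReport`` whose
tables mirror the usual reporting layout of a dominance-GBLUP study:
variance components with derived ratios, model-comparison LogL/p table,
CV accuracy/slope/MSE tables, selection-percentage rank correlations and
inbreeding correlations.  ``verify_report`` re-derives every ratio and
p-value from the raw components in the report and flags mismatches.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import (
    GenotypeTable,
    PhenotypeRecords,
    read_genotypes_tsv,
    read_phenotypes_tsv,
)
from .crossval import (
    DEFAULT_SELECTION_PERCENTAGES,
    assign_folds,
    rank_table_over_folds,
    run_cv,
    summarize_cv,
)
from .grm import (
    build_additive_grm,
    build_dominance_grm,
    compute_inbreeding,
    correlate_dominance_with_inbreeding,
    estimate_allele_frequencies,
)
from .mixedmodel import (
    ModelSpec,
    VarianceComponents,
    build_incidence,
    mixture_lrt,
    reml_fit,
    solve_blup,
    variance_ratios,
)
from .simdata import SimConfig, adjust_phenotypes, apply_edit_filters, simulate_dataset

__all__ = ["RunConfig", "StudyReport", "run_study", "verify_report", "write_report"]

logger = logging.getLogger("domgblup")


@dataclass(frozen=True)
class RunConfig:
    """One study run: exactly one input mode (simulate | files)."""

    sim: SimConfig | None = None
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    trait: str = "sim"
    apply_edits: bool = False
    k_folds: int = 5
    selection_percentages: tuple[int, ...] = DEFAULT_SELECTION_PERCENTAGES
    higher_is_better: bool = True
    seed: int = 1

    def __post_init__(self) -> None:
        simulate = self.sim is not None
        files = self.genotypes_path is not None or self.phenotypes_path is not None
        if simulate == files:
            raise ValueError("exactly one input mode: simulate or files")
        if files and (self.genotypes_path is None or self.phenotypes_path is None):
            raise ValueError("file mode needs both genotype and phenotype paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        if sim is not None:
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            sim = SimConfig(**sim)
        if "selection_percentages" in raw:
            raw["selection_percentages"] = tuple(raw["selection_percentages"])
        return cls(sim=sim, **raw)


@dataclass
class StudyReport:
    """All result tables of one run plus a provenance block."""

    variance_components: pd.DataFrame  # model, parameter, estimate, se
    lrt: pd.DataFrame  # logl_A, logl_AD, statistic, p_value
    inbreeding_correlations: pd.DataFrame
    cv_metrics: pd.DataFrame
    cv_tests: pd.DataFrame
    rank_correlations: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _components_rows(model: str, fit: VarianceComponents) -> list[dict]:
    ratios = variance_ratios(fit)
    rows = [
        {"model": model, "parameter": "sigma_a2", "estimate": fit.sigma_a2,
         "se": fit.se.get("a", float("nan"))},
    ]
    if fit.sigma_d2 is not None:
        rows.append({"model": model, "parameter": "sigma_d2", "estimate": fit.sigma_d2,
                     "se": fit.se.get("d", float("nan"))})
    rows += [
        {"model": model, "parameter": "sigma_pe2", "estimate": fit.sigma_pe2,
         "se": fit.se.get("pe", float("nan"))},
        {"model": model, "parameter": "sigma_e2", "estimate": fit.sigma_e2,
         "se": fit.se.get("e", float("nan"))},
        {"model": model, "parameter": "sigma_p2", "estimate": ratios.sigma_p2,
         "se": float("nan")},
        {"model": model, "parameter": "h_a2", "estimate": ratios.h_a2, "se": float("nan")},
        {"model": model, "parameter": "repeatability", "estimate": ratios.repeatability,
         "se": float("nan")},
    ]
    if fit.sigma_d2 is not None:
        rows += [
            {"model": model, "parameter": "h_d2", "estimate": ratios.h_d2,
             "se": float("nan")},
            {"model": model, "parameter": "dominance_share",
             "estimate": ratios.dominance_share, "se": float("nan")},
        ]
    return rows


def run_study(config: RunConfig) -> StudyReport:
    """Execute the full analysis chain for one configuration."""
    stage_times: dict[str, float] = {}

    def stage(name: str):
        logger.info("stage: %s", name)
        stage_times[name] = time.perf_counter()
        return name

    def done(name: str):
        stage_times[name] = time.perf_counter() - stage_times[name]

    s = stage("data")
    if config.sim is not None:
        genotypes, truth, records = simulate_dataset(config.sim, trait=config.trait)
    else:
        genotypes = read_genotypes_tsv(config.genotypes_path)
        records = read_phenotypes_tsv(config.phenotypes_path)
        truth = None
    done(s)

    s = stage("edit-and-adjust")
    n_dropped = n_capped = 0
    if config.apply_edits:
        records, counts = apply_edit_filters(records, config.trait)
        n_dropped, n_capped = counts.dropped, counts.capped
    records = adjust_phenotypes(records)  # intercept-only pre-correction
    done(s)

    s = stage("relationship-matrices")
    freqs = estimate_allele_frequencies(genotypes)
    G = build_additive_grm(genotypes, freqs)
    D = build_dominance_grm(genotypes, freqs)
    done(s)

    s = stage("reml")
    incidence = build_incidence(records, list(G.animal_ids))
    y = records.values
    fit_a = reml_fit(y, incidence, G, None, ModelSpec(include_dominance=False))
    fit_ad = reml_fit(y, incidence, G, D, ModelSpec(include_dominance=True))
    comp_rows = _components_rows("A", fit_a) + _components_rows("AD", fit_ad)
    done(s)

    s = stage("lrt")
    lrt = mixture_lrt(fit_a.loglik, fit_ad.loglik)
    lrt_table = pd.DataFrame(
        [{"logl_A": fit_a.loglik, "logl_AD": fit_ad.loglik,
          "statistic": lrt.statistic, "p_value": lrt.p_value}]
    )
    done(s)

    s = stage("inbreeding")
    sol_ad = solve_blup(fit_ad, y, incidence, G, D)
    inb = compute_inbreeding(genotypes, freqs)
    dv = sol_ad.dv.loc[genotypes.animal_ids].to_numpy()
    rows = []
    for name, measure in (("hom_fraction", inb.hom_fraction), ("g_f", inb.g_f)):
        r = correlate_dominance_with_inbreeding(dv, measure.to_numpy())
        degenerate = bool(np.isnan(r))
        rows.append(
            {"measure": name, "correlation": 0.0 if degenerate else r,
             "degenerate_zero_dv": degenerate}
        )
    inb_table = pd.DataFrame(rows)
    done(s)

    s = stage("cross-validation")
    sires = genotypes.sires or ["0"] * genotypes.n_animals
    folds = assign_folds(list(genotypes.animal_ids), list(sires),
                         k=config.k_folds, seed=config.seed)
    cv = run_cv(records, genotypes, folds, G=G, D=D)
    cv_summary = summarize_cv(cv.metrics)
    rank_tbl = rank_table_over_folds(
        cv, config.selection_percentages, config.higher_is_better
    )
    done(s)

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "trait": config.trait,
        "input_mode": "simulate" if config.sim is not None else "files",
        "sim": asdict(config.sim) if config.sim is not None else None,
        "n_animals": genotypes.n_animals,
        "n_snps": genotypes.n_snps,
        "n_records": len(records),
        "records_dropped": n_dropped,
        "records_capped": n_capped,
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: (asdict(v) if isinstance(v, SimConfig) else v)
                 for k, v in asdict(config).items()},
                sort_keys=True, default=str,
            ).encode()
        ).hexdigest()[:16],
    }
    logger.info("stage wall-times (s): %s",
                {k: round(v, 2) for k, v in stage_times.items()})
    return StudyReport(
        variance_components=pd.DataFrame(comp_rows),
        lrt=lrt_table,
        inbreeding_correlations=inb_table,
        cv_metrics=cv_summary.table,
        cv_tests=cv_summary.tests,
        rank_correlations=rank_tbl,
        provenance=provenance,
    )


def write_report(report: StudyReport, outdir: str | Path) -> None:
    """Emit the report as TSV tables plus a YAML metadata block.

    Machine files carry full precision; the human-readable summary rounds
    ratios to 3 decimals and variance components to whole units.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.variance_components.to_csv(out / "variance_components.tsv", sep="\t", index=False)
    report.lrt.to_csv(out / "lrt.tsv", sep="\t", index=False)
    report.inbreeding_correlations.to_csv(out / "inbreeding_correlations.tsv", sep="\t", index=False)
    report.cv_metrics.to_csv(out / "cv_metrics.tsv", sep="\t", index=False)
    report.cv_tests.to_csv(out / "cv_tests.tsv", sep="\t", index=False)
    report.rank_correlations.to_csv(out / "rank_correlations.tsv", sep="\t", index=False)
    with open(out / "metadata.yaml", "w") as fh:
        yaml.safe_dump(report.provenance, fh, sort_keys=True)

    ratios = report.variance_components[
        report.variance_components["parameter"].isin(
            ["h_a2", "h_d2", "dominance_share", "repeatability"]
        )
    ].copy()
    ratios["estimate"] = ratios["estimate"].round(3)
    comps = report.variance_components[
        report.variance_components["parameter"].str.startswith("sigma")
    ].copy()
    comps["estimate"] = comps["estimate"].round(0)
    with open(out / "summary.txt", "w") as fh:
        fh.write("Variance components (rounded)\n")
        fh.write(comps.to_string(index=False))
        fh.write("\n\nRatios (3 dp)\n")
        fh.write(ratios.to_string(index=False))
        fh.write("\n")


def verify_report(report: StudyReport, rtol: float = 1e-6) -> list[dict]:
    """Re-derive every ratio and the LRT p-value from the raw components in
    the report and confirm internal consistency.

    Returns a list of checks, each ``{"check": name, "passed": bool,
    "detail": str}``.  Tolerance is relative; feeding externally rounded
    components (e.g. published tables) still passes at rounding precision
    when ``rtol`` is set accordingly.
    """
    checks: list[dict] = []

    def add(name: str, passed: bool, detail: str = "") -> None:
        checks.append({"check": name, "passed": bool(passed), "detail": detail})

    vc = report.variance_components
    for model in vc["model"].unique():
        sub = vc[vc["model"] == model].set_index("parameter")["estimate"]
        comps = [sub.get("sigma_a2", 0.0), sub.get("sigma_d2", 0.0),
                 sub.get("sigma_pe2", 0.0), sub.get("sigma_e2", 0.0)]
        total = float(np.sum(comps))
        if "sigma_p2" in sub.index:
            ok = np.isclose(sub["sigma_p2"], total, rtol=rtol)
            add(f"{model}: sigma_p2 equals component sum", ok,
                f"{sub['sigma_p2']:.6g} vs {total:.6g}")
        for name, num in (
            ("h_a2", sub.get("sigma_a2", 0.0)),
            ("h_d2", sub.get("sigma_d2", np.nan)),
        ):
            if name in sub.index:
                ok = np.isclose(sub[name], num / total, rtol=rtol, atol=5e-4)
                add(f"{model}: {name} consistent", ok,
                    f"{sub[name]:.6g} vs {num / total:.6g}")
        if "dominance_share" in sub.index:
            genetic = sub.get("sigma_a2", 0.0) + sub.get("sigma_d2", 0.0)
            expect = sub.get("sigma_d2", 0.0) / genetic if genetic > 0 else 0.0
            ok = np.isclose(sub["dominance_share"], expect, rtol=rtol, atol=5e-4)
            add(f"{model}: dominance share consistent", ok,
                f"{sub['dominance_share']:.6g} vs {expect:.6g}")
        if "repeatability" in sub.index:
            expect = (sub.get("sigma_a2", 0.0) + sub.get("sigma_d2", 0.0)
                      + sub.get("sigma_pe2", 0.0)) / total
            ok = np.isclose(sub["repeatability"], expect, rtol=rtol, atol=5e-4)
            add(f"{model}: repeatability consistent", ok,
                f"{sub['repeatability']:.6g} vs {expect:.6g}")

    for _, row in report.lrt.iterrows():
        lrt = mixture_lrt(row["logl_A"], row["logl_AD"])
        ok = np.isclose(row["statistic"], lrt.statistic, rtol=rtol, atol=1e-9) and (
            np.isclose(row["p_value"], lrt.p_value, rtol=max(rtol, 1e-3), atol=1e-9)
        )
        add("LRT statistic and p recomputed from LogLs", ok,
            f"stat {row['statistic']:.6g} vs {lrt.statistic:.6g}, "
            f"p {row['p_value']:.3g} vs {lrt.p_value:.3g}")
    return checks
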