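"""Half-sib-aware cross-validation of genomic predictive ability.

Folds are built from whole paternal half-sib families so that no
validation animal shares a sire with any training animal; when dam links
are supplied, dam and daughter are co-assigned so that no predicted cow
has daughters in the training data.  Within each fold both models are
re-fitted on the remaining folds' records (validation genotypes stay in
G and D, their phenotypes do not), validation animals' genetic values are
predicted through their genomic covariances, and predictive ability is
scored against the per-animal mean of adjusted records: Pearson
correlation, regression slope of phenotype on genetic value (closer to 1
is better) and mean squared error.  Fold averages are compared across
models with paired t tests, slopes against 1 with one-sample t tests,
and re-ranking between breeding values and total genetic values is
summarised with Spearman correlations at selection percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeTable, PhenotypeRecords
from .grm import (
    RelationshipMatrix,
    build_additive_grm,
    build_dominance_grm,
    estimate_allele_frequencies,
)
from .mixedmodel import (
    ModelSpec,
    VarianceComponents,
    build_incidence,
    reml_fit,
    solve_blup,
)

__all__ = [
    "FoldAssignment",
    "CVResult",
    "CVSummary",
    "assign_folds",
    "run_cv",
    "summarize_cv",
    "rank_correlation_by_selection",
    "rank_table_over_folds",
]

DEFAULT_SELECTION_PERCENTAGES = (10, 25, 50, 75, 100)


@dataclass
class FoldAssignment:
    """Animal -> fold index (1..k); all daughters of a sire share a fold."""

    folds: pd.Series  # index animal_id, values 1..k
    k: int
    seed: int

    def animals_in(self, fold: int) -> list[str]:
        return [str(a) for a in self.folds.index[self.folds == fold]]

    def sizes(self) -> pd.Series:
        return self.folds.value_counts().sort_index()


def assign_folds(
    animals: list[str],
    sires: list[str],
    k: int = 5,
    seed: int = 0,
    dams: list[str] | None = None,
) -> FoldAssignment:
    """Allocate whole sire families to folds, largest family first into the
    currently smallest fold with a seeded random tie-break.

    With ``dams`` supplied (dam id per animal, ids referring to animals in
    the list), a dam's family is merged with her daughters' families so
    that no predicted cow has daughters in the training set.
    """
    if k < 2:
        raise ValueError("need at least k=2 folds")
    if len(sires) != len(animals):
        raise ValueError("sires must align with animals")
    # union-find over family groups keyed by sire
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for s in sires:
        parent.setdefault(s, s)
    if dams is not None:
        if len(dams) != len(animals):
            raise ValueError("dams must align with animals")
        sire_of = dict(zip(animals, sires))
        for a, dam in zip(animals, dams):
            if dam in sire_of:  # dam is herself an animal here
                union(sire_of[a], sire_of[dam])

    groups: dict[str, list[str]] = {}
    for a, s in zip(animals, sires):
        groups.setdefault(find(s), []).append(a)
    if len(groups) < k:
        raise ValueError(
            f"only {len(groups)} independent families for k={k} folds"
        )

    rng = np.random.default_rng(seed)
    keys = sorted(groups)
    order = sorted(keys, key=lambda g: (-len(groups[g]), rng.random()))
    sizes = np.zeros(k)
    assignment: dict[str, int] = {}
    for g in order:
        # smallest fold; random tie-break among equally small folds
        smallest = np.flatnonzero(sizes == sizes.min())
        f = int(rng.choice(smallest))
        for a in groups[g]:
            assignment[a] = f + 1
        sizes[f] += len(groups[g])
    folds = pd.Series({a: assignment[a] for a in animals}, name="fold")
    folds.index.name = "animal_id"
    return FoldAssignment(folds=folds.loc[animals], k=k, seed=seed)


@dataclass
class CVResult:
    """Tidy per-fold metrics plus per-fold predictions and fitted components.

    ``metrics`` columns: fold, model ('A' or 'AD'), metric, value.  Metrics
    are corr_bv, corr_dv (A+D only), corr_tgv, slope, mse; the slope and
    MSE use the model's headline predictor (BV for A, TGV for A+D).
    """

    metrics: pd.DataFrame
    predictions: dict[int, pd.DataFrame] = field(default_factory=dict)
    components: dict[tuple[int, str], VarianceComponents] = field(default_factory=dict)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _slope(pheno: np.ndarray, gv: np.ndarray) -> float:
    """Regression coefficient of phenotype on genetic value."""
    v = np.var(gv)
    if v == 0.0:
        return float("nan")
    return float(np.cov(pheno, gv, ddof=1)[0, 1] / np.var(gv, ddof=1))


def run_cv(
    records: PhenotypeRecords,
    genotypes: GenotypeTable,
    folds: FoldAssignment,
    spec_a: ModelSpec | None = None,
    spec_ad: ModelSpec | None = None,
    G: RelationshipMatrix | None = None,
    D: RelationshipMatrix | None = None,
) -> CVResult:
    """Fivefold (k-fold) cross-validation of models A and A+D.

    G and D are built once over all animals (validation genotypes included,
    their phenotypes excluded per fold); variance components are
    re-estimated within every training set.
    """
    spec_a = spec_a or ModelSpec(include_dominance=False)
    spec_ad = spec_ad or ModelSpec(include_dominance=True)
    if G is None or D is None:
        freqs = estimate_allele_frequencies(genotypes)
        G = G or build_additive_grm(genotypes, freqs)
        D = D or build_dominance_grm(genotypes, freqs)
    animal_order = list(G.animal_ids)
    pheno_animals = set(records.animal_ids)
    unassigned = pheno_animals - set(map(str, folds.folds.index))
    if unassigned:
        raise ValueError(f"folds do not cover phenotyped animals: {sorted(unassigned)[:5]}")

    means = records.animal_means()
    rows = []
    predictions: dict[int, pd.DataFrame] = {}
    components: dict[tuple[int, str], VarianceComponents] = {}
    for fold in range(1, folds.k + 1):
        val_animals = [a for a in folds.animals_in(fold) if a in pheno_animals]
        val_set = set(val_animals)
        train_mask = ~records.data["animal_id"].astype(str).isin(val_set)
        train = PhenotypeRecords(records.data.loc[train_mask])
        if len(train) == 0 or len(val_animals) == 0:
            raise RuntimeError(f"fold {fold} leaves an empty training or validation set")
        incidence = build_incidence(train, animal_order)
        y = train.values
        fit_a = reml_fit(y, incidence, G, None, spec_a)
        fit_ad = reml_fit(y, incidence, G, D, spec_ad)
        sol_a = solve_blup(fit_a, y, incidence, G, None)
        sol_ad = solve_blup(fit_ad, y, incidence, G, D)
        components[(fold, "A")] = fit_a
        components[(fold, "AD")] = fit_ad

        pheno = means.loc[val_animals].to_numpy(dtype=float)
        bv_a = sol_a.bv.loc[val_animals].to_numpy()
        bv_ad = sol_ad.bv.loc[val_animals].to_numpy()
        dv_ad = sol_ad.dv.loc[val_animals].to_numpy()
        tgv_ad = sol_ad.tgv.loc[val_animals].to_numpy()
        predictions[fold] = pd.DataFrame(
            {
                "pheno": pheno,
                "bv_a": bv_a,
                "bv_ad": bv_ad,
                "dv_ad": dv_ad,
                "tgv_ad": tgv_ad,
            },
            index=pd.Index(val_animals, name="animal_id"),
        )
        for model, vals in (
            ("A", {"corr_bv": _pearson(pheno, bv_a),
                   "corr_tgv": _pearson(pheno, bv_a),
                   "slope": _slope(pheno, bv_a),
                   "mse": float(np.mean((pheno - bv_a) ** 2))}),
            ("AD", {"corr_bv": _pearson(pheno, bv_ad),
                    "corr_dv": _pearson(pheno, dv_ad),
                    "corr_tgv": _pearson(pheno, tgv_ad),
                    "slope": _slope(pheno, tgv_ad),
                    "mse": float(np.mean((pheno - tgv_ad) ** 2))}),
        ):
            for metric, value in vals.items():
                rows.append({"fold": fold, "model": model, "metric": metric, "value": value})
    return CVResult(
        metrics=pd.DataFrame(rows), predictions=predictions, components=components
    )


@dataclass
class CVSummary:
    """Fold means/SEs per metric and model, with significance tests.

    ``tests`` rows: comparison, statistic, p_value, degenerate.  The paired
    tests compare models A and A+D (correlations and MSE); the one-sample
    tests compare each model's slope with 1.
    """

    table: pd.DataFrame
    tests: pd.DataFrame


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    d = x - y
    if np.allclose(d, 0.0) or np.std(d, ddof=1) == 0.0:
        return 0.0, 1.0, True
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue), False


def _one_sample_t(x: np.ndarray, popmean: float) -> tuple[float, float, bool]:
    if np.std(x, ddof=1) == 0.0:
        if np.allclose(x, popmean):
            return 0.0, 1.0, True
        return float("inf"), 0.0, True
    res = stats.ttest_1samp(x, popmean)
    return float(res.statistic), float(res.pvalue), False


def summarize_cv(metrics: pd.DataFrame) -> CVSummary:
    """Average fold metrics and run the model-comparison tests."""
    k = metrics["fold"].nunique()
    if k < 2:
        raise ValueError("need at least 2 folds to summarise")
    grp = metrics.groupby(["model", "metric"])["value"]
    table = grp.agg(
        mean="mean", se=lambda v: np.std(v, ddof=1) / np.sqrt(len(v))
    ).reset_index()

    def fold_values(model: str, metric: str) -> np.ndarray:
        sel = metrics[(metrics["model"] == model) & (metrics["metric"] == metric)]
        return sel.sort_values("fold")["value"].to_numpy(dtype=float)

    tests = []
    for name, a_metric, ad_metric in (
        ("corr: BV_A vs BV_AD", "corr_bv", "corr_bv"),
        ("corr: BV_A vs TGV_AD", "corr_bv", "corr_tgv"),
        ("mse: A vs AD", "mse", "mse"),
    ):
        t, p, degen = _paired_t(fold_values("A", a_metric), fold_values("AD", ad_metric))
        tests.append({"comparison": name, "statistic": t, "p_value": p, "degenerate": degen})
    for model in ("A", "AD"):
        t, p, degen = _one_sample_t(fold_values(model, "slope"), 1.0)
        tests.append(
            {"comparison": f"slope_{model} vs 1", "statistic": t, "p_value": p,
             "degenerate": degen}
        )
    return CVSummary(table=table, tests=pd.DataFrame(tests))


def rank_correlation_by_selection(
    values_A: pd.Series,
    values_AD: pd.Series,
    percentages=DEFAULT_SELECTION_PERCENTAGES,
    higher_is_better: bool = True,
) -> pd.DataFrame:
    """Spearman rank correlation between two evaluations within the top X%.

    Animals are ranked by ``values_A`` (the selection criterion of the
    additive evaluation; ties broken by id), the top X% selected, and the
    Spearman correlation between the two value vectors computed on that
    subset with midranks for ties.  Subsets smaller than 3 animals give NaN.
    For a smaller-is-better trait pass ``higher_is_better=False``.
    """
    if not values_A.index.equals(values_AD.index):
        values_AD = values_AD.loc[values_A.index]
    n = len(values_A)
    order = values_A.sort_index()
    asc = not higher_is_better
    ranked = order.sort_values(ascending=asc, kind="mergesort")  # stable: id tie-break
    rows = []
    for pct in percentages:
        if not 0 < pct <= 100:
            raise ValueError("selection percentages must lie in (0, 100]")
        m = int(np.ceil(pct / 100.0 * n))
        top = ranked.index[:m]
        if m < 3:
            rho = float("nan")
        else:
            va = values_A.loc[top].to_numpy(dtype=float)
            vb = values_AD.loc[top].to_numpy(dtype=float)
            if np.ptp(va) == 0.0 or np.ptp(vb) == 0.0:
                rho = float("nan")  # constant ranking: undefined
            else:
                rho = float(stats.spearmanr(va, vb).statistic)
        rows.append({"percentage": pct, "n_selected": m, "spearman": rho})
    return pd.DataFrame(rows)


def rank_table_over_folds(
    result: CVResult,
    percentages=DEFAULT_SELECTION_PERCENTAGES,
    higher_is_better: bool = True,
) -> pd.DataFrame:
    """Average over folds of the selection-percentage rank correlations
    between BV (model A) and TGV (model A+D) of validation animals."""
    per_fold = []
    for fold, pred in result.predictions.items():
        tbl = rank_correlation_by_selection(
            pred["bv_a"], pred["tgv_ad"], percentages, higher_is_better
        )
        tbl["fold"] = fold
        per_fold.append(tbl)
    allf = pd.concat(per_fold, ignore_index=True)
    out = (
        allf.groupby("percentage")["spearman"]
        .agg(mean="mean", se=lambda v: np.std(v, ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    return out
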