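"""Synthetic dairy-cattle data with known additive and dominance truth.

The generator emulates the statistical structure the evaluation model
assumes: Hardy-Weinberg biallelic genotypes over a chosen minor-allele
frequency spectrum, paternal half-sib families (sires at HWE, one sire
gamete plus one population gamete per daughter), per-SNP additive and
dominance effects rescaled to hit target variance components exactly on
the HWE scale, an iid permanent-environmental effect per animal and
repeated records per animal.  A directional mean dominance effect can be
switched on to induce inbreeding depression (more homozygous animals then
carry systematically lower total dominance deviations).

Also houses the data-edit filters (trait plausibility bounds with the
calving-interval capping rule) and the least-squares pre-adjustment that
replaces contemporary-group correction on real data.

All randomness flows from ``SimConfig.seed`` through named substreams; the
same config reproduces bit-identical genotypes, truth and records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .containers import GenotypeTable, PhenotypeRecords, PHENOTYPE_COLUMNS
from .grm import AlleleFrequencies, additive_codes, dominance_codes

__all__ = [
    "SimConfig",
    "TruthSet",
    "EditRule",
    "FilterCounts",
    "DEFAULT_EDIT_RULES",
    "draw_allele_frequencies",
    "simulate_half_sib_genotypes",
    "draw_snp_effects",
    "build_truth_set",
    "simulate_records",
    "simulate_dataset",
    "apply_edit_filters",
    "adjust_phenotypes",
]

# substream labels: keep generator stages independent of each other
_STREAM_FREQS = 0
_STREAM_GENOTYPES = 1
_STREAM_EFFECTS = 2
_STREAM_PE = 3
_STREAM_RECORDS = 4


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one simulated dataset.

    Defaults describe the design used throughout the package's own
    validation: 20 paternal half-sib families of 50 daughters (1000 cows),
    2000 SNPs with minor-allele frequencies uniform on [0.05, 0.5], two
    records per cow, and variance components
    (sigma_a2, sigma_d2, sigma_pe2, sigma_e2) = (0.25, 0.05, 0.10, 0.60)
    on a unit phenotypic-variance scale — additive heritability 0.25 and a
    dominance share of phenotypic variance of 5%, in the range reported for
    dairy yield traits.
    """

    n_sires: int = 20
    daughters_per_sire: int = 50
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    records_per_animal: int = 2
    mean: float = 0.0
    true_sigma_a2: float = 0.25
    true_sigma_d2: float = 0.05
    true_sigma_pe2: float = 0.10
    true_sigma_e2: float = 0.60
    mean_dominance_effect: float = 0.0
    seed: int = 2016

    def __post_init__(self) -> None:
        for name in ("n_sires", "daughters_per_sire", "n_snps", "records_per_animal"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        for name in ("true_sigma_a2", "true_sigma_d2", "true_sigma_pe2", "true_sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_animals(self) -> int:
        return self.n_sires * self.daughters_per_sire

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class TruthSet:
    """True per-SNP effects and per-animal genetic values of a simulation.

    ``bv`` is the additive-code row times the a-vector, ``dv`` the
    dominance-code row times the d-vector, both at the drawing allele
    frequencies; ``pe`` is the animal's permanent-environmental effect.
    """

    snp_effects: pd.DataFrame  # index marker_id, columns a, d
    animals: pd.DataFrame  # index animal_id, columns sire_id, bv, dv, pe

    @property
    def bv(self) -> pd.Series:
        return self.animals["bv"]

    @property
    def dv(self) -> pd.Series:
        return self.animals["dv"]

    @property
    def pe(self) -> pd.Series:
        return self.animals["pe"]

    def to_tsv(self, path: str | Path) -> None:
        self.animals.to_csv(path, sep="\t")

    def snp_effects_to_tsv(self, path: str | Path) -> None:
        self.snp_effects.to_csv(path, sep="\t")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def draw_allele_frequencies(
    n_snps: int, maf_range: tuple[float, float], seed: int
) -> np.ndarray:
    """Frequencies of the counted allele with MAF uniform on ``maf_range``.

    The counted allele is the minor or the major one with equal probability,
    so p spans both sides of 0.5 while min(p, 1-p) stays inside the range.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = _rng(seed, _STREAM_FREQS)
    maf = rng.uniform(lo, hi, size=n_snps)
    flip = rng.random(n_snps) < 0.5
    return np.where(flip, 1.0 - maf, maf)


def simulate_half_sib_genotypes(
    cfg: SimConfig, freqs: np.ndarray | None = None
) -> GenotypeTable:
    """Paternal half-sib genotypes: HWE sires, daughters get one sire gamete
    and one gamete drawn at the population frequency (dam genotypes are not
    materialised).  The returned table carries the sire map; only daughters
    are genotyped animals.
    """
    if freqs is None:
        freqs = draw_allele_frequencies(cfg.n_snps, cfg.maf_range, cfg.seed)
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs <= 0.0) | (freqs >= 1.0)).any():
        raise ValueError("founder allele frequencies must lie strictly in (0, 1)")
    rng = _rng(cfg.seed, _STREAM_GENOTYPES)
    n_snps = freqs.size
    sire_counts = rng.binomial(2, freqs, size=(cfg.n_sires, n_snps))
    animal_ids: list[str] = []
    sires: list[str] = []
    rows = np.empty((cfg.n_sires * cfg.daughters_per_sire, n_snps), dtype=np.int8)
    k = 0
    for s in range(cfg.n_sires):
        sire_id = f"S{s + 1:03d}"
        # transmission probability per SNP is half the sire's allele count
        p_sire = sire_counts[s] / 2.0
        for d in range(cfg.daughters_per_sire):
            paternal = rng.random(n_snps) < p_sire
            maternal = rng.random(n_snps) < freqs
            rows[k] = paternal.astype(np.int8) + maternal.astype(np.int8)
            animal_ids.append(f"{sire_id}_D{d + 1:03d}")
            sires.append(sire_id)
            k += 1
    marker_ids = [f"snp{i + 1:05d}" for i in range(n_snps)]
    return GenotypeTable(rows, animal_ids, marker_ids, sires=sires)


def draw_snp_effects(
    freqs: np.ndarray,
    target_sigma_a2: float,
    target_sigma_d2: float,
    mean_dominance_effect: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian per-SNP additive and dominance effects rescaled to targets.

    Over HWE genotypes the variance contributed by SNP i is 2*p*q*a_i^2
    additively and (2*p*q)^2*d_i^2 through dominance, so the drawn vectors
    are rescaled to make those sums hit the targets exactly.  The dominance
    vector is d_i = mean_dominance_effect + s*eps_i with centred Gaussian
    eps: the mean term is directional (it generates inbreeding depression)
    and only the spread s is calibrated against ``target_sigma_d2``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if target_sigma_a2 < 0 or target_sigma_d2 < 0:
        raise ValueError("variance targets must be >= 0")
    rng = _rng(seed, _STREAM_EFFECTS)
    two_pq = 2.0 * freqs * (1.0 - freqs)
    poly = two_pq > 0
    a_raw = rng.standard_normal(freqs.size)
    eps = rng.standard_normal(freqs.size)
    eps -= eps.mean()

    if target_sigma_a2 > 0:
        denom_a = float((two_pq * a_raw**2)[poly].sum())
        if denom_a == 0.0:
            raise RuntimeError("additive target > 0 but no polymorphic SNPs")
        a = a_raw * np.sqrt(target_sigma_a2 / denom_a)
    else:
        a = np.zeros(freqs.size)

    if target_sigma_d2 > 0:
        denom_d = float((two_pq**2 * eps**2)[poly].sum())
        if denom_d == 0.0:
            raise RuntimeError("dominance target > 0 but no polymorphic SNPs")
        d = mean_dominance_effect + eps * np.sqrt(target_sigma_d2 / denom_d)
    else:
        d = np.full(freqs.size, float(mean_dominance_effect))
        if mean_dominance_effect == 0.0:
            d = np.zeros(freqs.size)
    return a, d


def build_truth_set(
    genotypes: GenotypeTable,
    freqs: np.ndarray,
    a: np.ndarray,
    d: np.ndarray,
    cfg: SimConfig,
) -> TruthSet:
    """True BV/DV per animal via the additive/dominance codings at the
    drawing frequencies, plus a permanent-environmental effect drawn once
    per animal with variance ``true_sigma_pe2``.
    """
    af = AlleleFrequencies(np.asarray(freqs, dtype=float), list(genotypes.marker_ids))
    z = additive_codes(genotypes, af).values
    m = dominance_codes(genotypes, af).values
    bv = z @ np.asarray(a, dtype=float)
    dv = m @ np.asarray(d, dtype=float)
    rng = _rng(cfg.seed, _STREAM_PE)
    pe = rng.normal(0.0, np.sqrt(cfg.true_sigma_pe2), size=genotypes.n_animals)
    sires = genotypes.sires if genotypes.sires is not None else ["0"] * genotypes.n_animals
    animals = pd.DataFrame(
        {"sire_id": sires, "bv": bv, "dv": dv, "pe": pe},
        index=pd.Index(genotypes.animal_ids, name="animal_id"),
    )
    snp_effects = pd.DataFrame(
        {"a": a, "d": d}, index=pd.Index(genotypes.marker_ids, name="marker_id")
    )
    return TruthSet(snp_effects, animals)


def simulate_records(
    genotypes: GenotypeTable, truth: TruthSet, cfg: SimConfig, trait: str = "sim"
) -> PhenotypeRecords:
    """Repeated records y = mean + BV + DV + pe + e.

    The permanent-environmental effect is constant across an animal's
    records (it comes from the truth set); the residual e is drawn fresh
    per record with variance ``true_sigma_e2``.
    """
    missing = [a for a in genotypes.animal_ids if a not in truth.animals.index]
    if missing:
        raise ValueError(f"truth set does not cover animals: {missing[:5]}")
    rng = _rng(cfg.seed, _STREAM_RECORDS)
    r = cfg.records_per_animal
    n = genotypes.n_animals
    anim = truth.animals.loc[genotypes.animal_ids]
    base = cfg.mean + (anim["bv"] + anim["dv"] + anim["pe"]).to_numpy()
    resid = rng.normal(0.0, np.sqrt(cfg.true_sigma_e2), size=(n, r))
    values = (base[:, None] + resid).ravel()
    data = pd.DataFrame(
        {
            "animal_id": np.repeat(genotypes.animal_ids, r),
            "sire_id": np.repeat(anim["sire_id"].to_numpy(), r),
            "trait": trait,
            "value": values,
        }
    )
    return PhenotypeRecords(data)


def simulate_dataset(
    cfg: SimConfig, trait: str = "sim"
) -> tuple[GenotypeTable, TruthSet, PhenotypeRecords]:
    """Full generator chain: frequencies -> genotypes -> effects -> truth
    -> records, all driven by ``cfg.seed``."""
    freqs = draw_allele_frequencies(cfg.n_snps, cfg.maf_range, cfg.seed)
    genotypes = simulate_half_sib_genotypes(cfg, freqs)
    a, d = draw_snp_effects(
        freqs, cfg.true_sigma_a2, cfg.true_sigma_d2, cfg.mean_dominance_effect, cfg.seed
    )
    truth = build_truth_set(genotypes, freqs, a, d, cfg)
    records = simulate_records(genotypes, truth, cfg, trait=trait)
    return genotypes, truth, records


# --------------------------------------------------------------- data edits
@dataclass(frozen=True)
class EditRule:
    """Keep-range filter with an optional cap-range.

    Records with values inside ``keep`` are retained; values inside ``cap``
    (when given) are set to ``cap_value`` and retained; everything else is
    dropped.
    """

    keep: tuple[float, float]
    cap: tuple[float, float] | None = None
    cap_value: float | None = None


# shipped defaults: dairy-trait plausibility bounds (calving interval in
# days, milk in litres, fat/protein in kg); CI between 551 and 762 days is
# truncated to 551 rather than discarded
DEFAULT_EDIT_RULES: dict[str, EditRule] = {
    "ci": EditRule(keep=(290.0, 550.0), cap=(551.0, 762.0), cap_value=551.0),
    "milk": EditRule(keep=(2000.0, 15000.0)),
    "fat": EditRule(keep=(50.0, 800.0)),
    "protein": EditRule(keep=(45.0, 600.0)),
}


@dataclass
class FilterCounts:
    kept: int
    dropped: int
    capped: int


def apply_edit_filters(
    records: PhenotypeRecords,
    trait: str,
    rules: dict[str, EditRule] | None = None,
) -> tuple[PhenotypeRecords, FilterCounts]:
    """Apply the trait's edit rule; returns the filtered copy and counts."""
    rules = DEFAULT_EDIT_RULES if rules is None else rules
    if trait not in rules:
        raise ValueError(f"no edit rule for trait {trait!r}; known: {sorted(rules)}")
    rule = rules[trait]
    df = records.data.copy()
    if df.empty:
        return PhenotypeRecords(df), FilterCounts(0, 0, 0)
    v = df["value"].to_numpy(dtype=float)
    keep = (v >= rule.keep[0]) & (v <= rule.keep[1])
    capped = np.zeros_like(keep)
    if rule.cap is not None:
        capped = (v >= rule.cap[0]) & (v <= rule.cap[1]) & ~keep
        v = np.where(capped, rule.cap_value, v)
    retain = keep | capped
    df["value"] = v
    out = df.loc[retain].reset_index(drop=True)
    return (
        PhenotypeRecords(out),
        FilterCounts(kept=int(retain.sum()), dropped=int((~retain).sum()), capped=int(capped.sum())),
    )


def adjust_phenotypes(
    records: PhenotypeRecords, covariates: pd.DataFrame | None = None
) -> PhenotypeRecords:
    """Pre-adjust records by ordinary least squares on supplied covariates.

    Stands in for the national contemporary-group correction on real data:
    the records are regressed on an intercept plus the covariate design
    (categorical columns dummy-coded) and the residuals become the new
    record values.  Exactly collinear columns are pruned; if the design is
    still rank-deficient the offending columns are named in the error.
    """
    y = records.values
    if covariates is None or covariates.shape[1] == 0:
        return records.with_values(y - y.mean())
    if len(covariates) != len(records):
        raise ValueError("covariate table must have one row per record")
    X = pd.get_dummies(covariates, drop_first=True, dtype=float)
    X.insert(0, "intercept", 1.0)
    Xv = X.to_numpy(dtype=float)
    # prune exactly collinear columns via pivoted QR
    _, rdiag, piv = scipy.linalg.qr(Xv, mode="economic", pivoting=True)
    diag = np.abs(np.diag(rdiag))
    tol = max(Xv.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    redundant = [X.columns[j] for j in piv[rank:]]
    keep_cols = [c for c in X.columns if c not in redundant]
    Xk = X[keep_cols].to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        raise RuntimeError(
            f"design rank-deficient after pruning; offending columns: {keep_cols}"
        )
    fit = sm.OLS(y, Xk).fit()
    return records.with_values(fit.resid)
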