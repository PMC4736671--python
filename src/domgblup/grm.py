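"""Genomic relationship matrices and genomic inbreeding measures.

The additive matrix **G** is built from allele counts centred at twice the
allele frequency, G = ZZ'/sum(2*p*q); the dominance matrix **D** from the
heterozygosity-based coding, D = MM'/sum((2*p*q)^2).  Under Hardy-Weinberg
proportions the two codings are orthogonal per SNP (E[z] = E[m] = E[z*m] = 0),
so additive and dominance variance components estimated against G and D are
not confounded.

Two per-animal inbreeding measures are provided: the excess-homozygosity
coefficient G_F extracted from the diagonal of the additive matrix (the
self-relationship minus one, computed SNP-wise with the most common allele
counted), and the raw fraction of homozygous SNP genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeTable

__all__ = [
    "AlleleFrequencies",
    "CodesMatrix",
    "RelationshipMatrix",
    "InbreedingMeasures",
    "estimate_allele_frequencies",
    "additive_codes",
    "dominance_codes",
    "build_additive_grm",
    "build_dominance_grm",
    "genomic_inbreeding",
    "homozygosity_fraction",
    "compute_inbreeding",
    "correlate_dominance_with_inbreeding",
]


@dataclass
class AlleleFrequencies:
    """Per-SNP frequency of the counted allele A, with q = 1 - p.

    ``monomorphic`` flags SNPs with p in {0, 1}; those contribute nothing to
    relationship-matrix numerators or denominators and are excluded from the
    inbreeding average (their per-SNP term is 0/0).
    """

    p: np.ndarray
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1:
            raise ValueError("allele frequencies must be a vector")
        if len(self.marker_ids) != self.p.size:
            raise ValueError("marker ids must align with frequencies")
        if ((self.p < 0) | (self.p > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    @property
    def monomorphic(self) -> np.ndarray:
        return (self.p <= 0.0) | (self.p >= 1.0)

    @property
    def n_polymorphic(self) -> int:
        return int((~self.monomorphic).sum())


@dataclass
class CodesMatrix:
    """Real-valued genotype codes: kind 'additive' (Z) or 'dominance' (M)."""

    values: np.ndarray
    kind: str
    marker_ids: list[str]


@dataclass
class RelationshipMatrix:
    """Symmetric animal x animal genomic relationship matrix."""

    values: np.ndarray
    animal_ids: list[str]
    kind: str  # 'additive' or 'dominance'
    denominator: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape must match animal ids")
        scale = max(1.0, float(np.abs(self.values).max()))
        if np.abs(self.values - self.values.T).max() > 1e-12 * scale:
            raise ValueError("relationship matrix is not symmetric")
        if not self.denominator > 0:
            raise ValueError("denominator must be positive")

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.animal_ids, name="animal_id")
        return pd.DataFrame(self.values, index=idx, columns=idx)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def to_npz(self, path) -> None:
        """Binary container with an id sidecar inside the archive."""
        np.savez(
            path,
            values=self.values,
            animal_ids=np.asarray(self.animal_ids),
            kind=self.kind,
            denominator=self.denominator,
        )


@dataclass
class InbreedingMeasures:
    """Per-animal G_F and homozygous-SNP fraction, id-aligned Series."""

    g_f: pd.Series
    hom_fraction: pd.Series
    n_snps_used: int


def estimate_allele_frequencies(genotypes: GenotypeTable) -> AlleleFrequencies:
    """Observed frequency of the counted allele: p = mean allele count / 2.

    Computed over all supplied animals (training and validation together
    when both are present, matching how validation genotypes enter G/D).
    """
    if genotypes.n_animals == 0 or genotypes.n_snps == 0:
        raise ValueError("cannot estimate frequencies from an empty table")
    p = genotypes.counts.mean(axis=0) / 2.0
    return AlleleFrequencies(p, list(genotypes.marker_ids))


def _check_aligned(genotypes: GenotypeTable, freqs: AlleleFrequencies) -> None:
    if list(genotypes.marker_ids) != list(freqs.marker_ids):
        raise ValueError("marker ids of genotypes and frequencies are misaligned")


def additive_codes(
    genotypes: GenotypeTable, freqs: AlleleFrequencies
) -> CodesMatrix:
    """Centred allele counts z = x - 2p.

    Per SNP the three genotypes aa/Aa/AA (x = 0, 1, 2) code to
    -2p, q - p and 2q.  Monomorphic SNPs are zero-filled, so they drop out
    of any cross-product.
    """
    _check_aligned(genotypes, freqs)
    z = genotypes.counts.astype(float) - 2.0 * freqs.p[np.newaxis, :]
    z[:, freqs.monomorphic] = 0.0
    return CodesMatrix(z, "additive", list(freqs.marker_ids))


def dominance_codes(
    genotypes: GenotypeTable, freqs: AlleleFrequencies
) -> CodesMatrix:
    """Dominance codes: aa -> -2p^2, Aa -> 2pq, AA -> -2q^2 per SNP."""
    _check_aligned(genotypes, freqs)
    p, q = freqs.p, freqs.q
    x = genotypes.counts
    m = np.where(
        x == 1,
        (2.0 * p * q)[np.newaxis, :],
        np.where(x == 0, (-2.0 * p * p)[np.newaxis, :], (-2.0 * q * q)[np.newaxis, :]),
    ).astype(float)
    m[:, freqs.monomorphic] = 0.0
    return CodesMatrix(m, "dominance", list(freqs.marker_ids))


def build_additive_grm(
    genotypes: GenotypeTable, freqs: AlleleFrequencies | None = None
) -> RelationshipMatrix:
    """G = ZZ' / sum over polymorphic SNPs of 2*p*q."""
    if freqs is None:
        freqs = estimate_allele_frequencies(genotypes)
    _check_aligned(genotypes, freqs)
    if freqs.n_polymorphic == 0:
        raise ValueError("no polymorphic SNPs: additive GRM undefined")
    z = additive_codes(genotypes, freqs).values
    poly = ~freqs.monomorphic
    denom = float((2.0 * freqs.p * freqs.q)[poly].sum())
    g = (z @ z.T) / denom
    g = 0.5 * (g + g.T)  # enforce exact symmetry against fp round-off
    return RelationshipMatrix(g, list(genotypes.animal_ids), "additive", denom)


def build_dominance_grm(
    genotypes: GenotypeTable, freqs: AlleleFrequencies | None = None
) -> RelationshipMatrix:
    """D = MM' / sum over polymorphic SNPs of (2*p*q)^2."""
    if freqs is None:
        freqs = estimate_allele_frequencies(genotypes)
    _check_aligned(genotypes, freqs)
    if freqs.n_polymorphic == 0:
        raise ValueError("no polymorphic SNPs: dominance GRM undefined")
    m = dominance_codes(genotypes, freqs).values
    poly = ~freqs.monomorphic
    denom = float(((2.0 * freqs.p * freqs.q) ** 2)[poly].sum())
    d = (m @ m.T) / denom
    d = 0.5 * (d + d.T)
    return RelationshipMatrix(d, list(genotypes.animal_ids), "dominance", denom)


def genomic_inbreeding(
    genotypes: GenotypeTable, freqs: AlleleFrequencies | None = None
) -> pd.Series:
    """Genomic inbreeding coefficient G_F per animal.

    G_F = (1/N) * sum_i (x_i^2 - (1 + 2p_i) x_i + 2 p_i^2) / (2 p_i (1 - p_i))

    where x_i counts copies of the *most common* allele at SNP i and p_i is
    that allele's frequency; N counts polymorphic SNPs only.  This is the
    diagonal of the frequency-standardised self-relationship minus one:
    fully heterozygous animals score -1 at p = 0.5, fully homozygous +1.
    """
    if freqs is None:
        freqs = estimate_allele_frequencies(genotypes)
    _check_aligned(genotypes, freqs)
    poly = ~freqs.monomorphic
    if not poly.any():
        raise ValueError("all SNPs monomorphic: G_F undefined")
    # flip so x counts the most common allele (frequency >= 0.5)
    p = freqs.p[poly]
    x = genotypes.counts[:, poly].astype(float)
    flip = p < 0.5
    p = np.where(flip, 1.0 - p, p)
    x[:, flip] = 2.0 - x[:, flip]
    terms = (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / (2.0 * p * (1.0 - p))
    return pd.Series(
        terms.mean(axis=1), index=pd.Index(genotypes.animal_ids, name="animal_id"),
        name="g_f",
    )


def homozygosity_fraction(genotypes: GenotypeTable) -> pd.Series:
    """Fraction of an animal's SNP genotypes that are homozygous (aa or AA)."""
    if genotypes.n_snps == 0:
        raise ValueError("zero SNPs: homozygosity fraction undefined")
    frac = (genotypes.counts != 1).mean(axis=1)
    return pd.Series(
        frac, index=pd.Index(genotypes.animal_ids, name="animal_id"),
        name="hom_fraction",
    )


def compute_inbreeding(
    genotypes: GenotypeTable, freqs: AlleleFrequencies | None = None
) -> InbreedingMeasures:
    if freqs is None:
        freqs = estimate_allele_frequencies(genotypes)
    return InbreedingMeasures(
        g_f=genomic_inbreeding(genotypes, freqs),
        hom_fraction=homozygosity_fraction(genotypes),
        n_snps_used=freqs.n_polymorphic,
    )


def correlate_dominance_with_inbreeding(dv, measure) -> float:
    """Pearson correlation between dominance deviations and an inbreeding
    measure over the same animals.

    Returns NaN when either vector has zero variance (undefined; callers
    report such cases as 0 when the deviations themselves are numerically
    zero, the convention used for a breed/trait with no dominance signal).
    """
    dv = np.asarray(dv, dtype=float)
    measure = np.asarray(measure, dtype=float)
    if dv.shape != measure.shape or dv.ndim != 1:
        raise ValueError("inputs must be aligned 1-D vectors")
    if dv.size < 3:
        raise ValueError("need at least 3 animals for a correlation")
    if np.std(dv) == 0.0 or np.std(measure) == 0.0:
        return float("nan")
    return float(np.corrcoef(dv, measure)[0, 1])
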