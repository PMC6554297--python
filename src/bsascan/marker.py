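"""Single-marker validation statistics and the grain-elongation phenotype.

Genotypes are donor-allele dosages in {0, 1, 2} (missing allowed). The
single-marker model is ordinary least squares of phenotype on dosage coded
(-1, 0, +1), the standard additive coding for an F2: the slope is the
additive effect (half the homozygote difference under pure additivity),
PVE = 100 R², and LOD = -(n/2) log10(1 - R²), the regression form of the
log10 likelihood ratio. A 2-df genotype-class model is available for
markers with dominance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm


@dataclass(frozen=True)
class MarkerTraitResult:
    marker: str
    n: int
    lod: float
    pve: float
    additive_effect: float
    donor: str | None
    significant: bool


@dataclass(frozen=True)
class JointPveResult:
    pve: float
    n: int
    n_markers: int
    dropped: tuple[str, ...]


def _clean_pairs(codes, phenotypes):
    codes = np.asarray(codes, dtype=float)
    phen = np.asarray(phenotypes, dtype=float)
    if codes.shape != phen.shape:
        raise ValueError("codes and phenotypes must align")
    ok = ~np.isnan(codes) & ~np.isnan(phen)
    return codes[ok], phen[ok]


def bulk_allele_frequency(codes) -> tuple[float, float]:
    """(donor fraction, other fraction) of alleles among non-missing plants."""
    codes = np.asarray(codes, dtype=float)
    codes = codes[~np.isnan(codes)]
    if len(codes) == 0:
        raise ValueError("all genotypes missing")
    if np.any((codes < 0) | (codes > 2) | (codes != np.rint(codes))):
        raise ValueError("codes must be dosages in {0, 1, 2}")
    donor = float(codes.sum() / (2 * len(codes)))
    return donor, 1.0 - donor


def single_marker(
    codes,
    phenotypes,
    marker: str = "",
    donor_name: str = "donor",
    other_name: str = "other",
    model: str = "additive",
    lod_threshold: float = 3.0,
) -> MarkerTraitResult:
    """Regress phenotype on one marker's dosages.

    ``model='additive'`` fits the (-1, 0, +1)-coded slope; ``'genotypic'``
    fits genotype-class means (2 df) for R²/LOD while the additive effect
    stays half the homozygote-mean difference. Missing pairs are dropped
    listwise. The donor is the parent whose allele raises the trait (sign
    of the additive effect); ``significant`` applies the conventional
    LOD >= ``lod_threshold`` rule.
    """
    x, y = _clean_pairs(codes, phenotypes)
    if len(x) < 3:
        raise ValueError("need at least 3 non-missing genotype/phenotype pairs")
    if np.var(x) == 0:
        raise ValueError(f"marker {marker!r} is monomorphic in the scored individuals")
    n = len(x)
    coded = x - 1.0
    if model == "additive":
        fit = sm.OLS(y, sm.add_constant(coded)).fit()
        r2 = float(fit.rsquared)
        effect = float(fit.params[1])
    elif model == "genotypic":
        design = np.column_stack([(x == 1).astype(float), (x == 2).astype(float)])
        fit = sm.OLS(y, sm.add_constant(design)).fit()
        r2 = float(fit.rsquared)
        hom0, hom2 = y[x == 0], y[x == 2]
        if len(hom0) == 0 or len(hom2) == 0:
            raise ValueError("genotypic model needs both homozygote classes")
        effect = float((hom2.mean() - hom0.mean()) / 2)
    else:
        raise ValueError(f"unknown model {model!r}")
    r2 = min(max(r2, 0.0), 1.0 - 1e-15)
    lod = -(n / 2) * np.log10(1.0 - r2)
    donor = None if effect == 0 else (donor_name if effect > 0 else other_name)
    return MarkerTraitResult(
        marker=marker,
        n=n,
        lod=float(lod),
        pve=100.0 * r2,
        additive_effect=abs(effect),
        donor=donor,
        significant=lod >= lod_threshold,
    )


def joint_pve(codes_matrix, phenotypes, marker_names=None) -> JointPveResult:
    """Percent of phenotypic variance jointly explained by several markers.

    Multiple regression of phenotype on all marker dosages with listwise
    deletion of individuals missing any marker. Linearly dependent columns
    are dropped (greedily, left to right) and reported, so a rank-deficient
    design degrades gracefully instead of failing.
    """
    X = np.asarray(codes_matrix, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 markers")
    if marker_names is None:
        marker_names = [f"m{i}" for i in range(X.shape[1])]
    ok = ~np.isnan(X).any(axis=1) & ~np.isnan(y)
    X, y = X[ok], y[ok]
    n, m = X.shape
    if n <= m + 1:
        raise ValueError("need more individuals than markers + 1")
    centered = X - X.mean(axis=0)
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(m):
        trial = centered[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            dropped.append(marker_names[j])
    fit = sm.OLS(y, sm.add_constant(X[:, keep])).fit()
    return JointPveResult(
        pve=100.0 * float(fit.rsquared),
        n=n,
        n_markers=len(keep),
        dropped=tuple(dropped),
    )


def ge_ratio(milled_replicates, cooked_replicates) -> tuple[float, float]:
    """Grain-elongation ratio: mean cooked length / mean milled length.

    Both arguments are sequences of replicates, each a sequence of
    per-grain lengths (mm); the conventional design is 3 replicates of 10
    grains. The ratio is computed within each replicate and the mean and
    sample s.d. across replicates are returned (s.d. is NaN with a single
    replicate).
    """
    if len(milled_replicates) != len(cooked_replicates) or len(milled_replicates) == 0:
        raise ValueError("need the same, non-zero number of replicates in each state")
    ratios = []
    for milled, cooked in zip(milled_replicates, cooked_replicates):
        milled = np.asarray(milled, dtype=float)
        cooked = np.asarray(cooked, dtype=float)
        if len(milled) == 0 or len(cooked) == 0:
            raise ValueError("each replicate needs at least one grain in each state")
        if np.any(milled <= 0) or np.any(cooked <= 0):
            raise ValueError("grain lengths must be positive")
        ratios.append(cooked.mean() / milled.mean())
    ratios = np.asarray(ratios)
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else float("nan")
    return float(ratios.mean()), sd
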