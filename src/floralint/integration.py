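"""Phenotypic integration index and among-species divergence statistics.

The integration index summarises how strongly a set of morphological traits
covary within a species.  For ``T`` traits measured on ``N`` individuals it
is the variance of the eigenvalues of the trait correlation matrix: if all
traits are perfectly correlated one eigenvalue equals ``T`` and the rest are
zero (maximal variance, equal to ``T`` when the sample variance with divisor
``T - 1`` is used), whereas independent traits give all eigenvalues equal to
one (variance zero).  The raw index carries a positive small-sample bias of
``(T - 1) / N``, which is subtracted, and the corrected index is expressed
as a percentage of its maximum ``T``.

Divergence statistics (PCA of the pooled individuals, per-trait one-way
ANOVA with Tukey HSD letters and a Bonferroni correction across traits)
quantify whether species differ in the raw traits at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DegenerateTraitError, ValidationError

__all__ = [
    "IntegrationResult",
    "DivergenceResult",
    "correlation_matrix",
    "integration_index",
    "bootstrap_integration",
    "species_integration",
    "divergence_pca",
    "trait_anova_tukey",
]


@dataclass
class IntegrationResult:
    """Integration index of one species."""

    species_id: str
    n_traits: int
    n_individuals: int
    eigenvalues: np.ndarray
    raw_variance: float
    corrected_int: float
    percent_int: float
    negative_corrected: bool
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None
    n_redrawn: int = 0

    def as_dict(self) -> dict:
        d = {
            "species_id": self.species_id,
            "n_traits": self.n_traits,
            "n_individuals": self.n_individuals,
            "eigenvalues": [float(x) for x in self.eigenvalues],
            "raw_variance": float(self.raw_variance),
            "corrected_int": float(self.corrected_int),
            "percent_int": float(self.percent_int),
            "negative_corrected": bool(self.negative_corrected),
        }
        if self.n_boot is not None:
            d.update(
                ci_low=float(self.ci_low),
                ci_high=float(self.ci_high),
                n_boot=int(self.n_boot),
            )
        return d


@dataclass
class DivergenceResult:
    """Among-species divergence: PCA of pooled individuals and per-trait ANOVA."""

    pca_proportions: np.ndarray | None = None
    pca_loadings: pd.DataFrame | None = None
    pca_scores: pd.DataFrame | None = None
    anova: pd.DataFrame | None = None
    tukey_letters: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def _check_matrix(values: np.ndarray, trait_names=None) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError("expected an N x T matrix of trait values")
    n, t = values.shape
    if t < 2:
        raise ValidationError(f"need at least 2 traits, got {t}")
    if n < 3:
        raise ValidationError(f"need at least 3 individuals, got {n}")
    if not np.all(np.isfinite(values)):
        raise ValidationError("trait matrix contains non-finite values")
    sd = values.std(axis=0)
    if np.any(sd == 0):
        names = trait_names if trait_names is not None else range(t)
        bad = [str(nm) for nm, s in zip(names, sd) if s == 0]
        raise DegenerateTraitError(f"constant trait column(s): {bad}")
    return values


def correlation_matrix(values: np.ndarray, trait_names=None) -> np.ndarray:
    """Pearson correlation matrix of an N x T trait matrix (columns = traits)."""
    values = _check_matrix(values, trait_names)
    corr = np.corrcoef(values, rowvar=False)
    # guard against roundoff drifting the diagonal
    np.fill_diagonal(corr, 1.0)
    return corr


def integration_index(
    values: np.ndarray,
    *,
    apply_correction: bool = True,
    percent_scale: bool = True,
    species_id: str = "",
    trait_names=None,
) -> IntegrationResult:
    """Eigenvalue-variance integration index of one species' trait matrix.

    ``raw_variance`` is the sample variance (divisor ``T - 1``) of the ``T``
    eigenvalues of the Pearson correlation matrix; the corrected index
    subtracts ``(T - 1) / N`` and the percent scale divides by the maximum
    ``T``.  With ``apply_correction=False`` the correction term is skipped
    (the percent scale then applies to the raw variance).
    """
    values = _check_matrix(values, trait_names)
    n, t = values.shape
    corr = correlation_matrix(values, trait_names)
    eig = np.linalg.eigvalsh(corr)[::-1]
    raw = float(np.var(eig, ddof=1))
    corrected = raw - (t - 1) / n if apply_correction else raw
    percent = 100.0 * corrected / t if percent_scale else corrected
    return IntegrationResult(
        species_id=species_id,
        n_traits=t,
        n_individuals=n,
        eigenvalues=eig,
        raw_variance=raw,
        corrected_int=corrected,
        percent_int=percent,
        negative_corrected=corrected < 0,
    )


def bootstrap_integration(
    values: np.ndarray,
    n_boot: int = 5000,
    seed: int | np.random.Generator = 0,
    *,
    species_id: str = "",
    trait_names=None,
    ci: tuple[float, float] = (2.5, 97.5),
) -> IntegrationResult:
    """Integration index with a percentile bootstrap CI on the percent scale.

    Individuals (rows) are resampled with replacement ``n_boot`` times.
    Resamples in which a trait becomes constant (correlations undefined)
    are redrawn; the number of redraws is recorded on the result.
    """
    if n_boot < 1:
        raise ValidationError(f"n_boot must be >= 1, got {n_boot}")
    values = _check_matrix(values, trait_names)
    n, _ = values.shape
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    point = integration_index(values, species_id=species_id, trait_names=trait_names)
    boots = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            sample = values[idx]
            if np.all(sample.std(axis=0) > 0):
                break
            n_redrawn += 1
        boots[b] = integration_index(sample).percent_int
    lo, hi = np.percentile(boots, ci)
    point.ci_low = float(lo)
    point.ci_high = float(hi)
    point.n_boot = n_boot
    point.n_redrawn = n_redrawn
    return point


def species_integration(
    table,
    n_boot: int = 5000,
    seed: int = 0,
) -> list[IntegrationResult]:
    """Bootstrap integration index for every species in a trait table.

    Species are processed in sorted label order with independent child
    seeds so that results do not depend on row order.
    """
    results = []
    ss = np.random.SeedSequence(seed)
    species = sorted(table.species())
    children = ss.spawn(len(species))
    for sp, child in zip(species, children):
        values = table.species_matrix(sp)
        results.append(
            bootstrap_integration(
                values,
                n_boot=n_boot,
                seed=np.random.default_rng(child),
                species_id=sp,
                trait_names=table.trait_names,
            )
        )
    return results


# ----------------------------------------------------------------------
# Divergence statistics


def divergence_pca(table) -> DivergenceResult:
    """PCA of the pooled individual-by-trait matrix on the correlation scale.

    Columns are centred and scaled by their sample standard deviation
    (divisor ``N - 1``); components are ordered by decreasing variance and
    each component's sign is fixed so its largest-magnitude loading is
    positive.
    """
    if len(table.species()) < 2:
        raise ValidationError("divergence PCA needs at least 2 species")
    values = _check_matrix(table.values(), table.trait_names)
    n, t = values.shape
    z = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    var = s**2 / (n - 1)
    proportions = var / var.sum()
    loadings = vt.T  # columns = components
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1.0
            u[:, j] *= -1.0
    comp_names = [f"PC{i + 1}" for i in range(t)]
    scores = pd.DataFrame(u * s, columns=comp_names)
    scores.insert(0, "species_id", list(table.frame["species_id"]))
    return DivergenceResult(
        pca_proportions=proportions,
        pca_loadings=pd.DataFrame(loadings, index=table.trait_names, columns=comp_names),
        pca_scores=scores,
    )


def _compact_letters(groups: list[str], not_different: set[frozenset]) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    ``not_different`` holds unordered pairs whose means were NOT separated.
    Groups sharing a letter are statistically indistinguishable; ties are
    broken by the (sorted) group-label order in which groups are processed.
    """
    letters_sets: list[set[str]] = [set(groups)]
    for a_i, a in enumerate(groups):
        for b in groups[a_i + 1 :]:
            if frozenset((a, b)) in not_different:
                continue
            # a and b are different: split every letter-set containing both
            new_sets = []
            for s in letters_sets:
                if a in s and b in s:
                    new_sets.append(s - {a})
                    new_sets.append(s - {b})
                else:
                    new_sets.append(s)
            # absorb: drop sets contained in another
            letters_sets = [
                s
                for i, s in enumerate(new_sets)
                if s and not any(i != j and s <= t for j, t in enumerate(new_sets))
            ]
    # deduplicate while preserving discovery order, then order letters by
    # the first (label-sorted) group each set contains
    uniq: list[set[str]] = []
    for s in letters_sets:
        if s not in uniq:
            uniq.append(s)
    uniq.sort(key=lambda s: [groups.index(g) for g in sorted(s, key=groups.index)])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, uniq):
        for g in sorted(s, key=groups.index):
            out[g] += letter
    return out


def trait_anova_tukey(table, alpha: float = 0.05) -> DivergenceResult:
    """One-way ANOVA per trait with Tukey HSD letters, Bonferroni across traits.

    Per trait: F on ``(k - 1, N - k)`` degrees of freedom across the ``k``
    species; Tukey HSD pairwise comparisons at family level ``alpha``
    rendered as a compact letter display; the ANOVA p-value is
    Bonferroni-adjusted across the ``T`` traits (``min(1, p * T)``).
    """
    species = sorted(table.species())
    if len(species) < 2:
        raise ValidationError("ANOVA needs at least 2 species")
    counts = table.frame.groupby("species_id").size()
    singletons = sorted(counts[counts < 2].index)
    if singletons:
        raise ValidationError(f"species with a single individual: {singletons}")
    t_traits = len(table.trait_names)
    rows = []
    letters = {}
    labels = np.asarray(table.frame["species_id"])
    for trait in table.trait_names:
        y = np.asarray(table.frame[trait], dtype=float)
        groups = [y[labels == sp] for sp in species]
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            f_stat, p_raw = 0.0, 1.0
        else:
            f_stat, p_raw = stats.f_oneway(*groups)
            if np.isnan(f_stat):  # identical values everywhere
                f_stat, p_raw = 0.0, 1.0
        k = len(species)
        n_tot = len(y)
        rows.append(
            {
                "trait": trait,
                "F": float(f_stat),
                "df1": k - 1,
                "df2": n_tot - k,
                "p_raw": float(p_raw),
                "p_bonferroni": float(min(1.0, p_raw * t_traits)),
            }
        )
        not_diff = set()
        if np.ptp(y) == 0:
            not_diff = {frozenset((a, b)) for a in species for b in species if a != b}
        else:
            hsd = pairwise_tukeyhsd(y, labels, alpha=alpha)
            res = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
            for _, r in res.iterrows():
                if not r["reject"]:
                    not_diff.add(frozenset((str(r["group1"]), str(r["group2"]))))
        letters[trait] = _compact_letters(species, not_diff)
    anova = pd.DataFrame(rows)
    letter_frame = pd.DataFrame(letters, index=species)
    letter_frame.index.name = "species_id"
    return DivergenceResult(anova=anova, tukey_letters=letter_frame)
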