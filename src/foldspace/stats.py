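"""Hypothesis testing and enrichment statistics.

Implements the testing machinery used for age-group contrasts:
tie-corrected Mann-Whitney U (with an exact permutation path for small
samples), Pearson chi-square tests on amino-acid proportions,
hypergeometric enrichment of functional terms with Bonferroni
correction, percentile curves of age distributions, and the
structure-versus-function contrast that asks whether the age split by
strand direction is sharper than the split by directionally enriched
functional annotations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    n1: int
    n2: int
    z: float
    p_two_sided: float
    p_one_sided: float
    method: str  # "normal" or "exact"
    degenerate: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    group: str
    k: int   # annotated in group
    n: int   # group size
    K: int   # annotated overall
    N: int   # universe size
    p: float
    m: int   # number of tests for Bonferroni
    significant: bool


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    p: float
    low_expected: bool


@dataclass(frozen=True)
class PercentileCurve:
    label: str
    percentiles: np.ndarray
    quantiles: np.ndarray


# ---------------------------------------------------------------------------
# Mann-Whitney


def _mw_exact_tail(x: np.ndarray, y: np.ndarray, u_obs: float) -> tuple[float, float]:
    """Exact permutation tail probabilities of U with ties.

    Enumerates every assignment of the pooled values to the two groups.
    Returns (one-sided upper-tail on U1, two-sided doubling rule... ) --
    the two-sided p is computed as the probability of |U - mu| >= |u_obs
    - mu| under the permutation distribution.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mu = n1 * (n - n1) / 2.0
    upper = 0
    two = 0
    total = 0
    dev_obs = abs(u_obs - mu)
    for combo in itertools.combinations(range(n), n1):
        r1 = ranks[list(combo)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2.0
        if u1 >= u_obs - 1e-12:
            upper += 1
        if abs(u1 - mu) >= dev_obs - 1e-12:
            two += 1
        total += 1
    return upper / total, two / total


def mann_whitney_ties(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    exact_limit: int = 12,
    continuity: bool = True,
) -> MannWhitneyResult:
    """Mann-Whitney U test with a tie-corrected normal approximation.

    U is computed from midranks; the variance is adjusted for ties,
    var = (n1*n2/12) * [(N+1) - sum(t^3 - t)/(N*(N-1))] over tie groups
    of size t, and a 0.5 continuity correction is applied to z.  With
    ``method='exact'`` (or 'auto' and pooled N <= ``exact_limit``) exact
    permutation p-values are computed instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    _vals, t = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(t**3 - t))
    if n > 1:
        var = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    else:
        var = 0.0
    degenerate = var <= 0.0
    if degenerate:
        return MannWhitneyResult(
            U=u1, n1=n1, n2=n2, z=0.0, p_two_sided=1.0, p_one_sided=1.0,
            method="normal", degenerate=True,
        )
    use_exact = method == "exact" or (method == "auto" and n <= exact_limit)
    sd = math.sqrt(var)
    dev = u1 - mu
    cc = 0.5 if continuity else 0.0
    if dev > 0:
        z = (dev - cc) / sd
    elif dev < 0:
        z = (dev + cc) / sd
    else:
        z = 0.0
    if use_exact:
        p_one, p_two = _mw_exact_tail(x, y, u1)
        return MannWhitneyResult(
            U=u1, n1=n1, n2=n2, z=z,
            p_two_sided=min(p_two, 1.0), p_one_sided=min(p_one, 1.0),
            method="exact",
        )
    p_two = 2.0 * sps.norm.sf(abs(z))
    p_one = sps.norm.sf((dev - cc) / sd)  # upper tail: x tends larger
    return MannWhitneyResult(
        U=u1, n1=n1, n2=n2, z=z,
        p_two_sided=min(p_two, 1.0), p_one_sided=min(p_one, 1.0),
        method="normal",
    )


# ---------------------------------------------------------------------------
# chi-square on proportions


def chi_square_propensity(
    n_aa_group: int, N_group: int, n_aa: int, N: int
) -> ChiSquareResult:
    """Pearson chi-square (1 df) on an amino acid's group vs rest proportions.

    The 2x2 table crosses (this amino acid vs all others) with (this
    group vs the rest of the set).  No Yates correction; a warning flag
    is set when any expected cell falls below 1.
    """
    if not (0 <= n_aa_group <= N_group and n_aa_group <= n_aa <= N and N_group <= N):
        raise ValueError("inconsistent counts")
    table = np.array(
        [
            [n_aa_group, N_group - n_aa_group],
            [n_aa - n_aa_group, (N - N_group) - (n_aa - n_aa_group)],
        ],
        dtype=float,
    )
    if table.min() < 0:
        raise ValueError("inconsistent counts")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / N
    if (row == 0).any() or (col == 0).any():
        return ChiSquareResult(chi2=0.0, p=1.0, low_expected=True)
    chi2 = float(np.sum((table - expected) ** 2 / expected))
    p = float(sps.chi2.sf(chi2, df=1))
    return ChiSquareResult(chi2=chi2, p=p, low_expected=bool(expected.min() < 1.0))


def bonferroni(
    p_values: Sequence[float] | float, m: int, alpha: float = 0.05
) -> np.ndarray | bool:
    """Bonferroni significance: p < alpha / m."""
    scalar = np.isscalar(p_values)
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m < len(p):
        raise ValueError("m must be at least the number of p-values")
    flags = p < alpha / m
    return bool(flags[0]) if scalar else flags


# ---------------------------------------------------------------------------
# hypergeometric enrichment


def hypergeometric_p(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_enrichment(
    annotations: Mapping[str, Iterable[str]],
    groups: Mapping[str, str],
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    annotated_only: bool = True,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment of terms in each group.

    ``annotations`` maps superfamily -> terms, ``groups`` superfamily ->
    group label.  The universe defaults to all superfamilies with at
    least one annotation (``annotated_only=False`` uses every
    superfamily in ``groups``).  Bonferroni correction is over all
    (term, group) tests performed.  Terms annotating nothing in the
    universe are skipped.
    """
    if universe is None:
        universe = set(groups)
    universe = set(universe)
    if annotated_only:
        universe = {s for s in universe if annotations.get(s)}
    N = len(universe)
    if N == 0:
        raise ValueError("empty enrichment universe")
    term_members: dict[str, set[str]] = {}
    for sf in universe:
        for term in annotations.get(sf, ()):
            term_members.setdefault(term, set()).add(sf)
    group_members: dict[str, set[str]] = {}
    for sf in universe:
        g = groups.get(sf)
        if g is not None:
            group_members.setdefault(g, set()).add(sf)
    tests = []
    for term, members in sorted(term_members.items()):
        K = len(members)
        if K == 0:
            continue
        for g, gm in sorted(group_members.items()):
            n = len(gm)
            k = len(members & gm)
            tests.append((term, g, k, n, K, hypergeometric_p(k, N, K, n)))
    m = len(tests)
    return [
        EnrichmentResult(
            term_id=term, group=g, k=k, n=n, K=K, N=N, p=p, m=m,
            significant=bool(p < alpha / m),
        )
        for term, g, k, n, K, p in tests
    ]


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# percentile curves and the structure-vs-function contrast


def percentile_curves(
    ages_by_label: Mapping[str, Sequence[float]],
) -> list[PercentileCurve]:
    """Age quantiles at integer percentiles 0-100 with linear interpolation."""
    curves = []
    grid = np.arange(101)
    for label, ages in ages_by_label.items():
        ages = np.asarray(list(ages), dtype=float)
        if len(ages) < 1:
            raise ValueError(f"no ages for group {label!r}")
        q = np.percentile(ages, grid, method="linear")
        curves.append(PercentileCurve(label=label, percentiles=grid, quantiles=q))
    return curves


def curves_to_frame(curves: Sequence[PercentileCurve]) -> pd.DataFrame:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {"label": c.label, "percentile": c.percentiles, "age": c.quantiles}
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class ContrastReport:
    """Result of the structure-vs-function age contrast."""

    structural: MannWhitneyResult
    functional: MannWhitneyResult | None
    functional_unique: MannWhitneyResult | None
    n_parallel_terms: int
    n_antiparallel_terms: int
    n_overlap_superfamilies: int
    curves: dict[str, list[PercentileCurve]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def structure_vs_function_contrast(
    ages: Mapping[str, float],
    strand_labels: Mapping[str, str],
    annotations: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> ContrastReport:
    """Compare the age split by strand direction against functional splits.

    Three Mann-Whitney contrasts of parallel vs antiparallel populations:
    (i) by structural label; (ii) by annotation with terms enriched in
    the parallel or antiparallel subset (overlapping superfamilies
    counted on both sides); (iii) restricted to superfamilies annotated
    with terms of only one direction.
    """
    notes: list[str] = []
    par = [s for s, l in strand_labels.items() if l == "parallel" and s in ages]
    anti = [s for s, l in strand_labels.items() if l == "antiparallel" and s in ages]
    if not par or not anti:
        raise ValueError("need both parallel and antiparallel superfamilies")
    structural = mann_whitney_ties(
        [ages[s] for s in par], [ages[s] for s in anti]
    )
    curves = {
        "structural": percentile_curves(
            {
                "parallel": [ages[s] for s in par],
                "antiparallel": [ages[s] for s in anti],
            }
        )
    }

    directional = {s: l for s, l in strand_labels.items()
                   if l in ("parallel", "antiparallel")}
    enrich = hypergeometric_enrichment(annotations, directional, alpha=alpha)
    par_terms = {r.term_id for r in enrich if r.group == "parallel" and r.significant}
    anti_terms = {
        r.term_id for r in enrich if r.group == "antiparallel" and r.significant
    }

    def annotated_with(terms: set[str]) -> set[str]:
        return {
            s for s, anns in annotations.items()
            if s in ages and terms & set(anns)
        }

    functional = None
    functional_unique = None
    n_overlap = 0
    if not par_terms:
        notes.append("no terms enriched in the parallel subset")
    if not anti_terms:
        notes.append("no terms enriched in the antiparallel subset")
    if par_terms and anti_terms:
        fpar = annotated_with(par_terms)
        fanti = annotated_with(anti_terms)
        n_overlap = len(fpar & fanti)
        functional = mann_whitney_ties(
            [ages[s] for s in fpar], [ages[s] for s in fanti]
        )
        curves["functional"] = percentile_curves(
            {
                "parallel_terms": [ages[s] for s in fpar],
                "antiparallel_terms": [ages[s] for s in fanti],
            }
        )
        upar = fpar - fanti
        uanti = fanti - fpar
        if upar and uanti:
            functional_unique = mann_whitney_ties(
                [ages[s] for s in upar], [ages[s] for s in uanti]
            )
            curves["functional_unique"] = percentile_curves(
                {
                    "parallel_only": [ages[s] for s in upar],
                    "antiparallel_only": [ages[s] for s in uanti],
                }
            )
        else:
            notes.append(
                "unique-annotation comparison degenerate: one side empty "
                "after removing overlaps"
            )
    return ContrastReport(
        structural=structural,
        functional=functional,
        functional_unique=functional_unique,
        n_parallel_terms=len(par_terms),
        n_antiparallel_terms=len(anti_terms),
        n_overlap_superfamilies=n_overlap,
        curves=curves,
        notes=notes,
    )
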