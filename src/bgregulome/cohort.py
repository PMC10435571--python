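"""Cohort genetics: two-locus haplotype frequencies, linkage disequilibrium,
and genotype-dose association with erythrocyte expression readouts.

Genotypes are coded as minor-allele doses 0/1/2 per locus.  Haplotype
frequencies are estimated either by the double-heterozygote counting rule
(phase-ambiguous samples are assigned the most common haplotype
configuration) or by the standard two-locus EM algorithm.  LD is summarized
as D = p_AB - p_A p_B, D' = |D| / D_max and r^2 = D^2 / (p_A p_a p_B p_b).
Expression association uses geometric mean fluorescence intensity and
delta-delta-Ct outcomes with one-way ANOVA (Bonferroni post hoc) and OLS
regression on the two dose covariates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("bgregulome.cohort")

#: haplotype order used throughout: major/major, major/minor, minor/major,
#: minor/minor at (locus 1, locus 2)
HAPLOTYPES = ("AB", "Ab", "aB", "ab")


class LDUndefinedError(ValueError):
    """LD statistics are undefined (monomorphic locus)."""


class CollinearityError(ValueError):
    """The dose design matrix is rank-deficient."""


def _as_dose_array(table) -> np.ndarray:
    """Normalize a genotype table to an (n, 2) integer dose array."""
    if hasattr(table, "columns"):
        arr = np.asarray(table[["dose_locus1", "dose_locus2"]], dtype=int)
    else:
        arr = np.asarray(table, dtype=int)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("genotype table must be a non-empty n x 2 dose array")
    if not np.isin(arr, (0, 1, 2)).all():
        raise ValueError("doses must be 0, 1 or 2")
    return arr


def _unambiguous_counts(doses: np.ndarray) -> tuple[np.ndarray, int]:
    """Haplotype counts from phase-unambiguous samples plus the number of
    double heterozygotes."""
    counts = np.zeros(4)
    n_double_het = 0
    for d1, d2 in doses:
        if d1 == 1 and d2 == 1:
            n_double_het += 1
            continue
        # a sample with at least one homozygous locus resolves uniquely
        locus1 = ["a"] * d1 + ["A"] * (2 - d1)
        locus2 = ["b"] * d2 + ["B"] * (2 - d2)
        if d1 == 1:
            haps = [locus1[0] + locus2[0], locus1[1] + locus2[0]]
        elif d2 == 1:
            haps = [locus1[0] + locus2[0], locus1[0] + locus2[1]]
        else:
            haps = [locus1[0] + locus2[0]] * 2
        for h in haps:
            counts[HAPLOTYPES.index(h)] += 1
    return counts, n_double_het


@dataclass
class HaplotypeFrequencies:
    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    counts: np.ndarray = field(default=None)  # expected haplotype counts
    n_samples: int = 0
    n_double_het: int = 0
    estimation_mode: str = "direct"

    def __post_init__(self) -> None:
        f = self.frequencies
        if np.any(f < -1e-12):
            raise ValueError("haplotype frequencies must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([self.p_AB, self.p_Ab, self.p_aB, self.p_ab])


def genotype_loglikelihood(hf: HaplotypeFrequencies, table) -> float:
    """Log-likelihood of the unphased genotypes under random union of
    gametes with the given haplotype frequencies."""
    doses = _as_dose_array(table)
    p = dict(zip(HAPLOTYPES, hf.frequencies))
    ll = 0.0
    for d1, d2 in doses:
        prob = 0.0
        for h1 in HAPLOTYPES:
            for h2 in HAPLOTYPES:
                if (h1[0] == "a") + (h2[0] == "a") == d1 and (h1[1] == "b") + (h2[1] == "b") == d2:
                    prob += p[h1] * p[h2]
        ll += math.log(prob) if prob > 0 else -math.inf
    return ll


def estimate_haplotypes(table, mode: str = "counting-rule") -> HaplotypeFrequencies:
    """Two-locus haplotype frequencies from unphased genotype doses.

    mode="counting-rule": double heterozygotes are assigned en bloc to the more
    common phase configuration (AB/ab versus Ab/aB), judged by the product of
    the frequencies estimated from the unambiguous samples; ties resolve to
    AB/ab (cis-common).  mode="em": standard two-locus EM to the
    maximum-likelihood frequencies (tolerance 1e-8, at most 1000 iterations).
    When the table contains no double heterozygotes both modes reduce to
    direct gamete counting and the estimation mode is reported as "direct".
    """
    if mode not in ("counting-rule", "em"):
        raise ValueError(f"mode must be 'counting-rule' or 'em', got {mode!r}")
    doses = _as_dose_array(table)
    n = doses.shape[0]
    counts, n_dh = _unambiguous_counts(doses)

    if n_dh == 0:
        freqs = counts / counts.sum()
        return HaplotypeFrequencies(*freqs, counts=counts, n_samples=n,
                                    n_double_het=0, estimation_mode="direct")

    if mode == "counting-rule":
        total_unamb = counts.sum()
        if total_unamb > 0:
            f = counts / total_unamb
            cis, trans = f[0] * f[3], f[1] * f[2]
        else:
            cis = trans = 0.0
        if cis >= trans:
            if cis == trans:
                logger.info("double-het likelihood tie: resolving to AB/ab (cis-common)")
            counts = counts + n_dh * np.array([1.0, 0.0, 0.0, 1.0])
        else:
            counts = counts + n_dh * np.array([0.0, 1.0, 1.0, 0.0])
        freqs = counts / counts.sum()
        return HaplotypeFrequencies(*freqs, counts=counts, n_samples=n,
                                    n_double_het=n_dh, estimation_mode="counting-rule")

    # EM: split double heterozygotes by the posterior phase probability.
    # Initializing from the counting-rule estimate makes every EM step a
    # likelihood ascent from it, so EM can never end up below that rule.
    freqs = estimate_haplotypes(doses, mode="counting-rule").frequencies
    for _ in range(1000):
        cis, trans = freqs[0] * freqs[3], freqs[1] * freqs[2]
        r = cis / (cis + trans) if cis + trans > 0 else 0.5
        expected = counts + n_dh * np.array([r, 1 - r, 1 - r, r])
        new = expected / expected.sum()
        if np.abs(new - freqs).max() < 1e-8:
            freqs = new
            break
        freqs = new
    counts_em = counts + n_dh * np.array([r, 1 - r, 1 - r, r])
    return HaplotypeFrequencies(*freqs, counts=counts_em, n_samples=n,
                                n_double_het=n_dh, estimation_mode="em")


@dataclass
class LDStatistics:
    D: float
    D_max: float
    D_prime: float   # reported as |D| / D_max, in [0, 1]
    r_squared: float


def compute_ld(hf: HaplotypeFrequencies) -> LDStatistics:
    """Linkage disequilibrium from four haplotype frequencies.

    D = p_AB - p_A p_B; D_max = min(p_A p_b, p_a p_B) for D > 0 and
    min(p_A p_B, p_a p_b) for D < 0; D' = |D| / D_max; r^2 = D^2 /
    (p_A p_a p_B p_b).  When D = 0, D' is 1 if some haplotype is absent and
    0 otherwise.  Monomorphic loci leave both statistics undefined.
    """
    p_AB, p_Ab, p_aB, p_ab = hf.frequencies
    p_A, p_a = p_AB + p_Ab, p_aB + p_ab
    p_B, p_b = p_AB + p_aB, p_Ab + p_ab
    if min(p_A, p_a, p_B, p_b) <= 0:
        raise LDUndefinedError("monomorphic locus: D' and r^2 are undefined")
    D = p_AB - p_A * p_B
    if abs(D) < 1e-12:  # snap float round-off at exact independence
        D = 0.0
    if np.any(hf.frequencies == 0) and D != 0:
        # edge of the feasible region: |D| = D_max holds identically
        D_max = min(p_A * p_b, p_a * p_B) if D > 0 else min(p_A * p_B, p_a * p_b)
        return LDStatistics(
            D=D, D_max=D_max, D_prime=1.0,
            r_squared=D * D / (p_A * p_a * p_B * p_b),
        )
    if D > 0:
        D_max = min(p_A * p_b, p_a * p_B)
    elif D < 0:
        D_max = min(p_A * p_B, p_a * p_b)
    else:
        D_prime = 1.0 if np.any(hf.frequencies == 0) else 0.0
        return LDStatistics(D=0.0, D_max=0.0, D_prime=D_prime, r_squared=0.0)
    return LDStatistics(
        D=D,
        D_max=D_max,
        D_prime=abs(D) / D_max,
        r_squared=D * D / (p_A * p_a * p_B * p_b),
    )


@dataclass
class SeparationReport:
    """Samples whose two-locus genotypes break perfect LD (dose1 != dose2)."""

    n_samples: int
    n_separable: int
    fraction: float
    separable_index: list[int]


def genotype_concordance(table) -> SeparationReport:
    doses = _as_dose_array(table)
    sep = np.flatnonzero(doses[:, 0] != doses[:, 1])
    return SeparationReport(
        n_samples=doses.shape[0],
        n_separable=sep.size,
        fraction=sep.size / doses.shape[0],
        separable_index=sep.tolist(),
    )


def geometric_mfi(values) -> float:
    """Geometric mean fluorescence intensity: exp of the mean log value."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty fluorescence list")
    if np.any(arr <= 0):
        raise ValueError("fluorescence values must be positive")
    return float(np.exp(np.mean(np.log(arr))))


@dataclass
class TermResult:
    beta: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class AssociationResult:
    """ANOVA and/or regression output.

    ``pairwise`` maps (label1, label2) to (raw p, Bonferroni-adjusted p).
    """

    f_statistic: float | None = None
    p_value: float | None = None
    pairwise: dict[tuple, tuple[float, float]] | None = None
    terms: dict[str, TermResult] | None = None
    n: int = 0


def _pairwise_t(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided pooled-variance t-test p-value, tolerating zero variance."""
    pooled_ss = np.var(x, ddof=1) * (x.size - 1) + np.var(y, ddof=1) * (y.size - 1)
    if pooled_ss == 0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    return float(stats.ttest_ind(x, y, equal_var=True).pvalue)


def anova_bonferroni(groups: Mapping) -> AssociationResult:
    """Classic equal-variance one-way ANOVA across genotype groups with all
    pairwise pooled t comparisons, Bonferroni-adjusted (m = number of pairs,
    adjusted p capped at 1)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {k!r} needs at least two values")
    values = np.concatenate(list(arrays.values()))
    grand = values.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    if ss_between <= 1e-300:
        f_stat, p = 0.0, 1.0
    elif ss_within == 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat, p = stats.f_oneway(*arrays.values())
        f_stat, p = float(f_stat), float(p)
    pairs = list(combinations(sorted(arrays, key=str), 2))
    m = len(pairs)
    pairwise = {}
    for k1, k2 in pairs:
        raw = _pairwise_t(arrays[k1], arrays[k2])
        pairwise[(k1, k2)] = (raw, min(1.0, m * raw))
    return AssociationResult(
        f_statistic=f_stat, p_value=p, pairwise=pairwise, n=values.size
    )


def ols_dose_regression(y, doses) -> AssociationResult:
    """OLS fit y = b0 + b1 dose1 + b2 dose2 with t-based 95% CIs (n - 3 df)
    and two-sided per-coefficient p-values; no multiplicity adjustment.

    Collinear doses (e.g. dose1 identical to dose2 in a complete-LD cohort)
    raise CollinearityError: fit each locus separately instead.
    """
    y = np.asarray(y, dtype=float)
    d = _as_dose_array(doses)
    if y.size != d.shape[0]:
        raise ValueError("outcome and dose table lengths differ")
    if y.size <= 3:
        raise ValueError("need more than 3 samples for a 3-parameter fit")
    X = sm.add_constant(d.astype(float), has_constant="add")
    if np.linalg.matrix_rank(X) < 3:
        raise CollinearityError(
            "dose covariates are collinear (complete LD); "
            "run a single-locus regression per marker instead"
        )
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    names = ("intercept", "dose_locus1", "dose_locus2")
    terms = {
        name: TermResult(
            beta=float(fit.params[i]),
            ci_low=float(ci[i, 0]),
            ci_high=float(ci[i, 1]),
            p_value=float(fit.pvalues[i]),
        )
        for i, name in enumerate(names)
    }
    return AssociationResult(terms=terms, n=int(y.size))


def delta_delta_ct(target_ct, reference_ct, calibrator_delta_ct: float) -> float:
    """ddCt = (mean target Ct - mean reference Ct) - calibrator dCt.

    Both triplicates must be complete (three finite cycle values each).
    """
    t = np.asarray(target_ct, dtype=float)
    r = np.asarray(reference_ct, dtype=float)
    if t.shape != (3,) or r.shape != (3,):
        raise ValueError("Ct triplicates must each contain exactly three values")
    if not (np.isfinite(t).all() and np.isfinite(r).all()):
        raise ValueError("missing replicate in Ct triplicate")
    return float(t.mean() - r.mean() - calibrator_delta_ct)


@dataclass
class LuciferaseComparison:
    relative_activity: float  # mean over experiments, scaled to baseline
    t_statistic: float | None
    p_value: float
    degenerate: bool  # all paired differences identical to zero


@dataclass
class LuciferaseResult:
    baseline: str
    comparisons: dict  # construct -> LuciferaseComparison


def luciferase_ratio_test(
    firefly: Mapping, renilla: Mapping, baseline: str
) -> LuciferaseResult:
    """Firefly/Renilla ratio normalization and paired testing.

    ``firefly``/``renilla`` map construct -> array of shape (experiments,
    technical replicates).  Per-well ratios are averaged within each
    experiment, scaled to the baseline construct's grand mean, and each
    construct is compared against the baseline with a two-sided paired t-test
    on the per-experiment means.  All-zero paired differences report p = 1
    with a degenerate flag rather than erroring.
    """
    if baseline not in firefly or baseline not in renilla:
        raise ValueError(f"baseline construct {baseline!r} missing from the data")
    exp_means = {}
    for construct in firefly:
        f = np.asarray(firefly[construct], dtype=float)
        r = np.asarray(renilla[construct], dtype=float)
        if f.shape != r.shape:
            raise ValueError(f"firefly/renilla shapes differ for {construct!r}")
        if np.any(r <= 0):
            raise ValueError(f"non-positive Renilla value for {construct!r}")
        exp_means[construct] = (f / r).mean(axis=1)
    base = exp_means[baseline]
    if base.size < 2:
        raise ValueError("need at least two paired experiments")
    scale = base.mean()
    comparisons = {}
    for construct, means in exp_means.items():
        if construct == baseline:
            continue
        if means.size != base.size:
            raise ValueError(f"unpaired experiment count for {construct!r}")
        diffs = means - base
        if np.allclose(diffs, 0.0):
            comparisons[construct] = LuciferaseComparison(
                relative_activity=float(means.mean() / scale),
                t_statistic=None, p_value=1.0, degenerate=True,
            )
            continue
        t, p = stats.ttest_rel(means, base)
        comparisons[construct] = LuciferaseComparison(
            relative_activity=float(means.mean() / scale),
            t_statistic=float(t), p_value=float(p), degenerate=False,
        )
    return LuciferaseResult(baseline=baseline, comparisons=comparisons)
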