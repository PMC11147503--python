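"""Donor-mixture zygosity model and single-hit Poisson limiting-dilution
frequency estimation.

Zygosity model: each of a diploid clone's two alleles is independently
HDR-edited with probability ``h``; an edited allele carries the mutant donor
with probability ``p`` (the mutant fraction of the delivered donor mixture),
otherwise the silent donor. Allele independence — no gene-conversion coupling
between the two alleles — is the model's core assumption; zygosity is then a
simple sampling calculation, and the bulk mutant allele frequency is linear
in ``p`` with slope ``h``.

Limiting dilution: ``P(well negative | dose d) = exp(-f d)``; ``f`` is
estimated by maximum likelihood across doses (complementary-log-log binomial
model), with a Wald CI on ``log f`` and a likelihood-ratio test for equality
across groups, matching common ELDA practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .synthetic_reads import GENOTYPE_CLASSES

__all__ = [
    "MixtureParams",
    "GenotypeDistribution",
    "MixtureFit",
    "LDGroupResult",
    "LDResult",
    "genotype_distribution",
    "expected_bulk_vaf",
    "fit_mixture",
    "plan_donor_ratio",
    "ld_frequency",
]

_CHI2_95 = float(stats.chi2.ppf(0.95, df=1))  # 3.841... ; LR CI cutoff


@dataclass(frozen=True)
class MixtureParams:
    p_mutant: float
    h: float

    def __post_init__(self):
        if not (0.0 <= self.p_mutant <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError("p_mutant and h must be in [0, 1]")


@dataclass(frozen=True)
class GenotypeDistribution:
    """Probabilities over the six diploid genotype classes."""

    probabilities: dict[str, float]

    def __post_init__(self):
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, not 1")

    def conditional_edited(self) -> dict[str, float]:
        """Renormalized over clones with at least one edited allele."""
        keys = [k for k in GENOTYPE_CLASSES if k != "unedited"]
        z = sum(self.probabilities[k] for k in keys)
        if z == 0:
            raise ZeroDivisionError("no edited clones under these parameters")
        return {k: self.probabilities[k] / z for k in keys}

    def conditional_biallelic(self) -> dict[str, float]:
        """Renormalized over clones with both alleles edited."""
        keys = ["hom_mut", "het_mut_silent", "hom_silent"]
        z = sum(self.probabilities[k] for k in keys)
        if z == 0:
            raise ZeroDivisionError("no biallelic-edited clones under these parameters")
        return {k: self.probabilities[k] / z for k in keys}


def genotype_distribution(params: MixtureParams) -> GenotypeDistribution:
    """Exact class probabilities under diploid allele independence."""
    p, h = params.p_mutant, params.h
    return GenotypeDistribution({
        "hom_mut": h * h * p * p,
        "het_mut_silent": 2 * h * h * p * (1 - p),
        "hom_silent": h * h * (1 - p) * (1 - p),
        "mut_wt": 2 * h * (1 - h) * p,
        "silent_wt": 2 * h * (1 - h) * (1 - p),
        "unedited": (1 - h) * (1 - h),
    })


def expected_bulk_vaf(params: MixtureParams) -> float:
    """Bulk mutant allele frequency: h·p (linear in p with slope h)."""
    return params.h * params.p_mutant


def _binom_loglik(k: int, n: int, q: float) -> float:
    if n == 0:
        return 0.0
    if q <= 0.0:
        return 0.0 if k == 0 else -math.inf
    if q >= 1.0:
        return 0.0 if k == n else -math.inf
    return k * math.log(q) + (n - k) * math.log1p(-q)


def _binom_lr_ci(k: int, n: int) -> tuple[float, float]:
    """Likelihood-ratio (profile) 95% CI for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    qhat = k / n
    lmax = _binom_loglik(k, n, qhat)

    def dev(q):
        return 2.0 * (lmax - _binom_loglik(k, n, q)) - _CHI2_95

    lo = 0.0
    if k > 0:
        lo = optimize.brentq(dev, 1e-12, qhat, xtol=1e-12)
    hi = 1.0
    if k < n:
        hi = optimize.brentq(dev, qhat, 1 - 1e-12, xtol=1e-12)
    return (lo, hi)


@dataclass(frozen=True)
class MixtureFit:
    p_mutant: float
    h: float
    ci_p: tuple[float, float]
    ci_h: tuple[float, float]
    loglik: float
    boundary: tuple[str, ...] = ()


def fit_mixture(genotype_counts: dict[str, int]) -> MixtureFit:
    """Multinomial maximum likelihood for (p, h) from genotype class counts.

    The likelihood factorizes into two binomials — edited alleles out of 2n
    (for h) and mutant alleles out of edited alleles (for p) — so the MLE is
    closed form and the profile CIs are independent binomial
    likelihood-ratio intervals. Boundary estimates are flagged.
    """
    counts = {k: int(genotype_counts.get(k, 0)) for k in GENOTYPE_CLASSES}
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative counts")
    n = sum(counts.values())
    if n == 0:
        raise ValueError("all-zero genotype table")
    edited_alleles = (
        2 * (counts["hom_mut"] + counts["het_mut_silent"] + counts["hom_silent"])
        + counts["mut_wt"] + counts["silent_wt"]
    )
    mutant_alleles = 2 * counts["hom_mut"] + counts["het_mut_silent"] + counts["mut_wt"]
    h_hat = edited_alleles / (2 * n)
    p_hat = mutant_alleles / edited_alleles if edited_alleles else float("nan")
    ci_h = _binom_lr_ci(edited_alleles, 2 * n)
    ci_p = _binom_lr_ci(mutant_alleles, edited_alleles)
    boundary = []
    if h_hat in (0.0, 1.0):
        boundary.append("h")
    if edited_alleles and p_hat in (0.0, 1.0):
        boundary.append("p")
    ll = _binom_loglik(edited_alleles, 2 * n, h_hat) + _binom_loglik(
        mutant_alleles, edited_alleles, p_hat if edited_alleles else 0.5
    )
    return MixtureFit(p_hat, h_hat, ci_p, ci_h, ll, tuple(boundary))


def plan_donor_ratio(
    target_het: float | None = None,
    target_bulk_vaf: float | None = None,
    h: float = 1.0,
    prefer: str = "mutant_majority",
) -> tuple[float, GenotypeDistribution]:
    """Invert the model: the mutant donor fraction p achieving a desired
    conditional het fraction (mutant/silent among biallelic-edited clones,
    max 0.5 at p = 0.5) or a desired bulk mutant allele frequency.

    When two p values achieve the het target, ``prefer`` selects
    ``"mutant_majority"`` (p >= 0.5) or ``"silent_majority"``.
    """
    if (target_het is None) == (target_bulk_vaf is None):
        raise ValueError("specify exactly one of target_het, target_bulk_vaf")
    if target_het is not None:
        if not 0.0 <= target_het <= 0.5:
            raise ValueError(
                f"conditional het fraction {target_het} unachievable: "
                "max is 0.5 (at p = 0.5)"
            )
        root = math.sqrt(1.0 - 2.0 * target_het)
        p = (1.0 + root) / 2.0 if prefer == "mutant_majority" else (1.0 - root) / 2.0
    else:
        if h <= 0:
            raise ValueError("h must be positive to achieve a nonzero bulk VAF")
        p = target_bulk_vaf / h
        if not 0.0 <= p <= 1.0:
            raise ValueError(
                f"bulk VAF {target_bulk_vaf} unachievable at h={h}: max is {h}"
            )
    return p, genotype_distribution(MixtureParams(p, h))


@dataclass(frozen=True)
class LDGroupResult:
    group: str
    frequency: float  # per cell
    ci95: tuple[float, float]
    loglik: float
    flag: str = ""  # "", "all_negative", "all_positive"

    @property
    def frequency_per_100(self) -> float:
        return 100.0 * self.frequency

    @property
    def ci95_per_100(self) -> tuple[float, float]:
        return (100.0 * self.ci95[0], 100.0 * self.ci95[1])


@dataclass(frozen=True)
class LDResult:
    groups: dict[str, LDGroupResult]
    lrt_p: float | None = None  # equality of f across groups


def _ld_loglik(f: float, wells) -> float:
    ll = 0.0
    for dose, n_wells, n_neg in wells:
        n_pos = n_wells - n_neg
        ll += n_neg * (-f * dose)
        if n_pos:
            q = -math.expm1(-f * dose)  # P(positive)
            ll += n_pos * math.log(q) if q > 0 else -math.inf
    return ll


def _ld_fit_group(wells) -> tuple[float, tuple[float, float], float, str]:
    for dose, n_wells, n_neg in wells:
        if dose <= 0:
            raise ValueError("doses must be positive")
        if not 0 <= n_neg <= n_wells:
            raise ValueError("n_negative must be within [0, n_wells]")
    total_neg = sum(w[2] for w in wells)
    total_wells = sum(w[1] for w in wells)
    weighted = sum(w[0] * w[1] for w in wells)
    if total_neg == total_wells:
        # all wells negative: f̂ = 0, one-sided LR upper bound
        upper = _CHI2_95 / 2.0 / weighted
        return 0.0, (0.0, upper), 0.0, "all_negative"
    if total_neg == 0:
        # all wells positive: estimate diverges; LR lower bound only
        lmax = 0.0  # loglik -> 0 as f -> inf

        def dev(logf):
            return 2.0 * (lmax - _ld_loglik(math.exp(logf), wells)) - _CHI2_95

        lo = math.exp(optimize.brentq(dev, -30.0, 30.0, xtol=1e-12))
        return math.inf, (lo, math.inf), 0.0, "all_positive"

    def score(logf):
        # d loglik / d f; loglik is concave in f so this is monotone decreasing
        f = math.exp(logf)
        s = 0.0
        for dose, n_wells, n_neg in wells:
            n_pos = n_wells - n_neg
            q = math.exp(-f * dose)
            s += -n_neg * dose + n_pos * dose * q / (1.0 - q)
        return s

    logf_hat = optimize.brentq(score, -30.0, 10.0, xtol=1e-14)
    f_hat = math.exp(logf_hat)

    def neg_ll(logf):
        return -_ld_loglik(math.exp(logf), wells)
    # Wald CI on log f from the observed information (numeric second derivative)
    eps = 1e-5
    d2 = (neg_ll(logf_hat + eps) - 2.0 * neg_ll(logf_hat) + neg_ll(logf_hat - eps)) / eps**2
    if d2 > 0:
        se = 1.0 / math.sqrt(d2)
        z = 1.959963984540054
        ci = (math.exp(logf_hat - z * se), math.exp(logf_hat + z * se))
    else:  # pragma: no cover - degenerate curvature
        ci = (0.0, math.inf)
    return f_hat, ci, _ld_loglik(f_hat, wells), ""


def ld_frequency(
    wells_by_group: dict[str, list[tuple[float, int, int]]],
) -> LDResult:
    """Limiting-dilution frequency per group with 95% CI and group-equality LRT.

    ``wells_by_group`` maps group name to ``(dose_cells, n_wells, n_negative)``
    rows. For a single dose the MLE equals the closed form
    ``-ln(n_negative / n_wells) / dose``.
    """
    groups = {}
    for name, wells in wells_by_group.items():
        f, ci, ll, flag = _ld_fit_group(wells)
        groups[name] = LDGroupResult(name, f, ci, ll, flag)

    lrt_p = None
    if len(wells_by_group) >= 2 and all(not g.flag for g in groups.values()):
        pooled = [w for wells in wells_by_group.values() for w in wells]
        _, _, ll_pooled, flag = _ld_fit_group(pooled)
        if not flag:
            ll_full = sum(g.loglik for g in groups.values())
            lr = max(0.0, 2.0 * (ll_full - ll_pooled))
            lrt_p = float(stats.chi2.sf(lr, df=len(wells_by_group) - 1))
    return LDResult(groups, lrt_p)
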