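"""Variance statistics for phenotyping screens.

Covers the statistical layer of a pouch-and-wick screen: coefficients of
variation, the number of replicates needed to resolve a between-genotype
difference, REML variance-component decompositions for the two standard
designs (a single genotype across runs and scanners; many genotypes crossed
with runs and scanners), the percentage contribution of each source of
variation, and broad-sense heritability.

Two conventions deserve a flag:

* Replicate number uses the non-overlapping-confidence-interval criterion:
  two group means differing by ``delta`` percent are declared separable when
  their two-sided (1 - alpha) CIs no longer overlap, giving
  R = (2 z_{alpha/2} CV / delta)^2. R grows quadratically in the CV.
* Source-of-variation percentages are shares of the *standard deviations*,
  each effect's SD over the sum of all effect SDs — not shares of the
  variances. This is statistically unconventional but is the reporting
  convention of the screen tables this package mirrors; heritability, by
  contrast, is a ratio of variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

#: effect order for the single-genotype (environmental) design
SINGLE_DESIGN = ("run", "scanner", "residual")
#: effect order for the multi-genotype (heritability) design
MULTI_DESIGN = (
    "genotype",
    "genotype:run",
    "genotype:scanner",
    "genotype:run:scanner",
    "residual",
)


@dataclass
class VarianceDecomposition:
    """REML effect SDs, their percentage shares, and context of one trait."""

    effect_sds: dict[str, float]  # effect name -> SD in trait units (incl. 'residual')
    percentages: dict[str, float]  # effect name -> % of summed SDs
    cv: float  # coefficient of variation of the trait, %
    n: int  # number of observations
    trait: str = ""
    mean: float = float("nan")
    converged: bool = True


@dataclass
class ReplicateEstimate:
    R: float
    cv: float
    delta: float = 50.0
    alpha: float = 0.05


@dataclass
class Heritability:
    H2: float
    numerator: float  # genotypic variance
    denominator: float  # total variance
    components: dict[str, float] = field(default_factory=dict)


def coefficient_of_variation(values) -> float:
    """Sample CV in percent: 100 * sd(n-1) / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 values")
    m = float(x.mean())
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * float(x.std(ddof=1)) / m


def replicate_number(cv: float, delta: float = 50.0, alpha: float = 0.05) -> ReplicateEstimate:
    """Replicates needed to separate two means differing by ``delta`` percent.

    Both populations are assumed to share the trait's CV. With R replicates
    each, the two-sided (1 - alpha) CIs of the two means stop overlapping
    once R >= (2 z_{alpha/2} CV / delta)^2; that boundary value is returned
    un-rounded (screen tables print it to one decimal).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    r = (2.0 * z * cv / delta) ** 2
    return ReplicateEstimate(R=float(r), cv=float(cv), delta=delta, alpha=alpha)


def source_percentages(effect_sds: dict[str, float]) -> dict[str, float]:
    """Percentage share of each effect's SD in the sum of all effect SDs."""
    if not effect_sds:
        raise ValueError("no effects given")
    sds = {k: float(v) for k, v in effect_sds.items()}
    if any(v < 0 for v in sds.values()):
        raise ValueError("SDs must be >= 0")
    total = sum(sds.values())
    if total <= 0:
        raise ValueError("all SDs are zero; percentages undefined")
    return {k: 100.0 * v / total for k, v in sds.items()}


def _reml_neg2loglik(variances: np.ndarray, y: np.ndarray, grams: list[np.ndarray]) -> float:
    """-2 x restricted log-likelihood of the intercept-only mixed model.

    V = sum_k theta_k Z_k Z_k' + theta_resid I;
    -2l = log|V| + log(1'V^-1 1) + r'V^-1 r with r the GLS residual.
    """
    n = len(y)
    V = variances[-1] * np.eye(n)
    for theta, G in zip(variances[:-1], grams):
        V += theta * G
    try:
        c, low = cho_factor(V, check_finite=False)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * float(np.log(np.diag(c)).sum())
    ones = np.ones(n)
    vi_y = cho_solve((c, low), y, check_finite=False)
    vi_1 = cho_solve((c, low), ones, check_finite=False)
    xvx = float(ones @ vi_1)
    beta = float(ones @ vi_y) / xvx
    r = y - beta
    vi_r = vi_y - beta * vi_1
    return logdet + np.log(xvx) + float(r @ vi_r)


def _reml_variances(
    y: np.ndarray, grams: list[np.ndarray], tol: float = 1e-10
) -> tuple[np.ndarray, bool]:
    """REML variance components by bounded quasi-Newton on the deviance.

    Components are constrained to be >= 0, so negative method-of-moments
    solutions are truncated at the boundary. Deterministic: a fixed
    multi-start (equal split; residual-dominated; first-component-dominated)
    and the best deviance wins. Variances are estimated on a standardized
    scale for conditioning and mapped back.
    """
    scale = float(np.var(y, ddof=1))
    if scale == 0:
        return np.zeros(len(grams) + 1), True
    ys = (y - y.mean()) / np.sqrt(scale)
    k = len(grams) + 1
    starts = [np.full(k, 1.0 / k)]
    resid_heavy = np.full(k, 0.1 / max(k - 1, 1))
    resid_heavy[-1] = 0.9
    starts.append(resid_heavy)
    first_heavy = np.full(k, 0.1 / max(k - 1, 1))
    first_heavy[0] = 0.9
    starts.append(first_heavy)
    best = None
    bounds = [(0.0, 50.0)] * (k - 1) + [(1e-12, 50.0)]
    for x0 in starts:
        res = minimize(
            _reml_neg2loglik,
            x0,
            args=(ys, grams),
            method="L-BFGS-B",
            bounds=bounds,
            options=dict(maxiter=500, ftol=tol, gtol=1e-10),
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    converged = bool(best is not None and np.isfinite(best.fun))
    return best.x * scale, converged


def _check_design(df: pd.DataFrame, factors: list[str]) -> None:
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")


def fit_variance_components(
    table: pd.DataFrame,
    trait: str,
    random_effects: tuple[str, ...] | list[str] | str = "single",
) -> VarianceDecomposition:
    """REML variance-component decomposition of one trait.

    ``random_effects`` is an ordered list of random factors; an interaction
    is written with a colon ("genotype:run"). The two screen designs have
    shorthand names: "single" = (run, scanner-within-run) for one genotype
    observed across the platform, and "multi" = (genotype, genotype:run,
    genotype:scanner, genotype:run:scanner) — the decomposition behind
    heritability. The residual SD is always estimated and reported last.

    All factors are fitted as independent zero-mean Gaussian variance
    components (a single-group mixed model, which accommodates nested and
    crossed layouts alike). Negative component estimates are truncated at
    zero by REML itself.
    """
    if isinstance(random_effects, str):
        try:
            random_effects = {"single": SINGLE_DESIGN[:-1], "multi": MULTI_DESIGN[:-1]}[
                random_effects
            ]
        except KeyError:
            raise ValueError(
                f"unknown design {random_effects!r}; expected 'single', 'multi', "
                "or an explicit factor list"
            ) from None
    factors = list(random_effects)
    if not factors:
        raise ValueError("need at least one random factor")
    if trait not in table.columns:
        raise ValueError(f"trait {trait!r} not in table")
    df = table.dropna(subset=[trait]).copy()
    df[trait] = df[trait].astype(float)

    base = sorted({f for term in factors for f in term.split(":")})
    _check_design(df, base)
    effects = tuple(factors) + ("residual",)

    y = df[trait].to_numpy(dtype=float)
    grams = []
    partitions: list[np.ndarray] = []
    for term in factors:
        labels = df[term.split(":")[0]].astype(str)
        for f in term.split(":")[1:]:
            labels = labels + "|" + df[f].astype(str)
        codes = pd.factorize(labels)[0]
        for other, part in zip(factors, partitions):
            same = len(np.unique(part)) == len(np.unique(codes)) and np.all(
                pd.factorize(part * (codes.max() + 1) + codes)[0] == pd.factorize(part)[0]
            )
            if same:
                raise ValueError(
                    f"factors {other!r} and {term!r} induce the same grouping "
                    "of observations and are confounded"
                )
        partitions.append(codes)
        z = np.zeros((len(y), codes.max() + 1))
        z[np.arange(len(y)), codes] = 1.0
        grams.append(z @ z.T)
    variances, converged = _reml_variances(y, grams)
    if not converged:
        raise RuntimeError(
            f"REML failed to converge for trait {trait!r}; factor levels: "
            + ", ".join(f"{f}={df[f].nunique()}" for f in base)
        )
    sds = {k: float(np.sqrt(v)) for k, v in zip(effects, variances)}

    return VarianceDecomposition(
        effect_sds=sds,
        percentages=source_percentages(sds),
        cv=coefficient_of_variation(df[trait]),
        n=len(df),
        trait=trait,
        mean=float(df[trait].mean()),
        converged=converged,
    )


def broad_sense_heritability(decomp: VarianceDecomposition) -> Heritability:
    """H^2 = genotypic variance over total phenotypic variance.

    Uses squared SDs: sigma_g^2 / (sigma_g^2 + interaction variances +
    residual variance). Requires a decomposition with a genotype effect.
    """
    if "genotype" not in decomp.effect_sds:
        raise ValueError("decomposition has no genotype effect")
    variances = {k: v**2 for k, v in decomp.effect_sds.items()}
    total = sum(variances.values())
    if total <= 0:
        raise ValueError("zero total variance; heritability undefined")
    h2 = variances["genotype"] / total
    return Heritability(
        H2=float(h2),
        numerator=variances["genotype"],
        denominator=float(total),
        components=variances,
    )


def anova_one_way_components(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Method-of-moments (ANOVA) variance components for a balanced one-way design.

    Returns (sd_between, sd_within). Independent closed form used to
    cross-check the REML path on balanced designs: sigma_b^2 =
    (MS_between - MS_within) / n_per_group, truncated at zero.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    counts = np.array([np.count_nonzero(groups == g) for g in levels])
    if counts.min() != counts.max():
        raise ValueError("closed form requires a balanced design")
    n = counts[0]
    means = np.array([values[groups == g].mean() for g in levels])
    grand = values.mean()
    ms_between = n * float(((means - grand) ** 2).sum()) / (len(levels) - 1)
    ms_within = float(
        sum(((values[groups == g] - m) ** 2).sum() for g, m in zip(levels, means))
    ) / (len(values) - len(levels))
    var_between = max((ms_between - ms_within) / n, 0.0)
    return float(np.sqrt(var_between)), float(np.sqrt(ms_within))
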