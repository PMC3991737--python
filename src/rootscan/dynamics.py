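"""Growth dynamics: daily trait trajectories and the two temporal models.

Primary and total root length follow a logistic growth curve

    L(t) = phi1 / (1 + exp(-phi3 * (t - phi2)))

with a genotype-specific asymptote phi1 and inflection point phi2 (days
after sowing) and rate phi3 (per day) shared across genotypes: genotypes
follow the same growth pattern and differ only in final size. Lateral roots
elongate at a near-constant rate that depends on when they emerged; the rate
is modelled as a quadratic in emergence day with a genotype-specific
intercept,

    rate(t_e) = (b_i1 + beta1) + beta2 * t_e + beta3 * t_e**2.

Fits are joint nonlinear (logistic) / linear (quadratic) least squares with
genotype effects as per-genotype parameters; for the logistic, the two
alternative structures (everything shared; everything per-genotype) are also
fitted and compared by AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit


@dataclass
class Trajectory:
    plant_id: str
    genotype: str
    run: str
    scanner: str
    das: np.ndarray  # strictly increasing
    values: np.ndarray
    monotonicity_violations: int = 0


@dataclass
class LogisticFit:
    """Joint logistic fit: per-genotype asymptote, shared inflection and rate."""

    asymptote_by_genotype: dict[str, float]
    inflection: float  # phi2, DAS
    scale: float  # phi3, per day
    residual_sd: float
    aic: dict[str, float] = field(default_factory=dict)  # model name -> AIC
    selected_model: str = "genotype_asymptote"

    def predict(self, t, genotype: str | None = None) -> np.ndarray:
        phi1 = (
            self.asymptote_by_genotype[genotype]
            if genotype is not None
            else float(np.mean(list(self.asymptote_by_genotype.values())))
        )
        return logistic(np.asarray(t, dtype=float), phi1, self.inflection, self.scale)


@dataclass
class LateralRateFit:
    intercept_by_genotype: dict[str, float]  # b_i1 + beta1, cm/day at t_e = 0
    linear: float  # beta2
    quadratic: float  # beta3
    residual_sd: float
    max_predicted_rate: float  # over the observed emergence-day range

    def predict(self, t_emerge, genotype: str) -> np.ndarray:
        t = np.asarray(t_emerge, dtype=float)
        return self.intercept_by_genotype[genotype] + self.linear * t + self.quadratic * t**2


def assemble_trajectories(trait_table: pd.DataFrame, trait: str) -> list[Trajectory]:
    """Group a trait table into per-plant time series sorted by DAS.

    Decreases of a cumulative trait larger than 5% of the previous value are
    counted as monotonicity violations and flagged, never altered.
    """
    required = {"plant_id", "das", trait}
    missing = required - set(trait_table.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    if trait_table.duplicated(subset=["plant_id", "das"]).any():
        dupes = trait_table[trait_table.duplicated(subset=["plant_id", "das"], keep=False)]
        raise ValueError(f"duplicate (plant_id, das) rows:\n{dupes[['plant_id', 'das']]}")
    out = []
    for pid, grp in trait_table.groupby("plant_id", sort=True):
        grp = grp.sort_values("das")
        vals = grp[trait].to_numpy(dtype=float)
        prev = vals[:-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            drops = (prev - vals[1:]) / np.where(prev > 0, prev, np.inf)
        nviol = int(np.count_nonzero(drops > 0.05))
        if nviol:
            warnings.warn(f"plant {pid}: {nviol} monotonicity violation(s) in {trait}")
        out.append(
            Trajectory(
                plant_id=str(pid),
                genotype=str(grp["genotype"].iloc[0]) if "genotype" in grp else "NA",
                run=str(grp["run"].iloc[0]) if "run" in grp else "NA",
                scanner=str(grp["scanner"].iloc[0]) if "scanner" in grp else "NA",
                das=grp["das"].to_numpy(dtype=float),
                values=vals,
                monotonicity_violations=nviol,
            )
        )
    return out


def logistic(t, phi1: float, phi2: float, phi3: float):
    """Logistic growth curve phi1 / (1 + exp(-phi3 (t - phi2)))."""
    t = np.asarray(t, dtype=float)
    return phi1 * expit(phi3 * (t - phi2))


def _start_grid(t: np.ndarray, y: np.ndarray):
    ymax = max(float(y.max()), 1e-6)
    trange = float(t.max() - t.min()) or 1.0
    for phi1 in (ymax, 2 * ymax):
        for frac in (0.25, 0.5, 0.75):
            for phi3 in (0.1, 0.3, 1.0):
                yield phi1, float(t.min() + frac * trange), phi3


def _fit_logistic_arrays(t, y, geno_idx, n_geno, structure: str):
    """Least-squares logistic fit with the given parameter structure.

    structure: 'shared' (3 params), 'genotype_asymptote' (n_g + 2),
    'genotype_all' (3 n_g). Multi-start over a fixed grid; best residual wins.
    """

    def unpack(p):
        if structure == "shared":
            phi1 = np.repeat(p[0], n_geno)
            phi2 = np.repeat(p[1], n_geno)
            phi3 = np.repeat(p[2], n_geno)
        elif structure == "genotype_asymptote":
            phi1 = p[:n_geno]
            phi2 = np.repeat(p[n_geno], n_geno)
            phi3 = np.repeat(p[n_geno + 1], n_geno)
        else:
            phi1 = p[:n_geno]
            phi2 = p[n_geno : 2 * n_geno]
            phi3 = p[2 * n_geno :]
        return phi1, phi2, phi3

    def resid(p):
        phi1, phi2, phi3 = unpack(p)
        return logistic(t, phi1[geno_idx], phi2[geno_idx], phi3[geno_idx]) - y

    best = None
    for phi1_0, phi2_0, phi3_0 in _start_grid(t, y):
        if structure == "shared":
            p0 = np.array([phi1_0, phi2_0, phi3_0])
        elif structure == "genotype_asymptote":
            p0 = np.concatenate([np.repeat(phi1_0, n_geno), [phi2_0, phi3_0]])
        else:
            p0 = np.concatenate(
                [np.repeat(phi1_0, n_geno), np.repeat(phi2_0, n_geno), np.repeat(phi3_0, n_geno)]
            )
        try:
            sol = least_squares(resid, p0, xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000)
        except Exception:
            continue
        cost = float(sol.cost)
        if best is None or cost < best[0] - 1e-12:
            best = (cost, sol)
    if best is None:
        raise RuntimeError("logistic fit failed to converge from every start")
    sol = best[1]
    phi1, phi2, phi3 = unpack(sol.x)
    rss = float(2 * sol.cost)
    n = len(y)
    k = len(sol.x) + 1  # + residual variance
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    return phi1, phi2, phi3, rss, float(aic)


def fit_logistic(
    trajectories: list[Trajectory],
    group_by_genotype: bool = True,
    compare_models: bool = True,
) -> LogisticFit:
    """Fit the logistic growth model jointly over all plants.

    The retained structure has one asymptote per genotype and a shared
    inflection and rate. When ``compare_models`` is set, the fully shared
    and fully per-genotype structures are fitted too and ranked by AIC;
    the returned parameters always come from the genotype-asymptote
    structure (or the shared one when ``group_by_genotype`` is off).
    """
    t = np.concatenate([tr.das for tr in trajectories])
    y = np.concatenate([tr.values for tr in trajectories])
    genos = sorted({tr.genotype for tr in trajectories}) if group_by_genotype else ["all"]
    gmap = {g: i for i, g in enumerate(genos)}
    if group_by_genotype:
        gidx = np.concatenate(
            [np.repeat(gmap[tr.genotype], len(tr.das)) for tr in trajectories]
        )
    else:
        gidx = np.zeros(len(t), dtype=int)
    for g in genos:
        if len(np.unique(t[gidx == gmap[g]])) < 4:
            raise ValueError(f"genotype {g}: need >= 4 distinct timepoints to fit a logistic")

    structure = "genotype_asymptote" if group_by_genotype and len(genos) > 1 else "shared"
    phi1, phi2, phi3, rss, aic_main = _fit_logistic_arrays(t, y, gidx, len(genos), structure)

    aic = {structure: aic_main}
    if compare_models and structure == "genotype_asymptote":
        for alt in ("shared", "genotype_all"):
            try:
                *_, aic_alt = _fit_logistic_arrays(t, y, gidx, len(genos), alt)
                aic[alt] = aic_alt
            except RuntimeError:
                pass
    n_params = len(genos) + 2 if structure == "genotype_asymptote" else 3
    dof = max(len(y) - n_params, 1)
    return LogisticFit(
        asymptote_by_genotype={g: float(phi1[gmap[g]]) for g in genos},
        inflection=float(phi2[0]),
        scale=float(phi3[0]),
        residual_sd=float(np.sqrt(rss / dof)),
        aic=aic,
        selected_model=min(aic, key=aic.get),
    )


def lateral_elongation_rate(length_cm: float, t_obs: float, t_emerge: float) -> float:
    """Mean elongation rate of a lateral: length over time since emergence."""
    if t_obs <= t_emerge:
        raise ValueError(f"observation day {t_obs} must be after emergence day {t_emerge}")
    return float(length_cm) / (float(t_obs) - float(t_emerge))


def fit_lateral_rate_model(
    rates: np.ndarray,
    emergence_days: np.ndarray,
    genotypes: np.ndarray,
) -> LateralRateFit:
    """Quadratic model of lateral elongation rate vs emergence day.

    rate = intercept_g + beta2 * t_e + beta3 * t_e^2 with a per-genotype
    intercept and shared beta2, beta3, by ordinary least squares. The
    emergence day is centred before solving to tame collinearity;
    coefficients are reported on the raw scale.
    """
    rates = np.asarray(rates, dtype=float)
    t_e = np.asarray(emergence_days, dtype=float)
    genos = np.asarray(genotypes)
    levels = sorted(set(genos.tolist()))
    for g in levels:
        if np.count_nonzero(genos == g) < 6:
            raise ValueError(f"genotype {g}: need >= 6 (rate, emergence) pairs")
    mu = float(t_e.mean())
    tc = t_e - mu
    X = np.zeros((len(rates), len(levels) + 2))
    for i, g in enumerate(levels):
        X[genos == g, i] = 1.0
    X[:, -2] = tc
    X[:, -1] = tc**2
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant emergence days?)")
    coef, rss_arr, *_ = np.linalg.lstsq(X, rates, rcond=None)
    resid = rates - X @ coef
    rss = float(resid @ resid)
    b3 = float(coef[-1])
    b2c = float(coef[-2])
    beta2 = b2c - 2.0 * b3 * mu
    intercepts = {g: float(coef[i] - b2c * mu + b3 * mu * mu) for i, g in enumerate(levels)}
    dof = max(len(rates) - X.shape[1], 1)
    grid = np.linspace(t_e.min(), t_e.max(), 512)
    preds = [
        intercepts[g] + beta2 * grid + b3 * grid**2 for g in levels
    ]
    return LateralRateFit(
        intercept_by_genotype=intercepts,
        linear=beta2,
        quadratic=b3,
        residual_sd=float(np.sqrt(rss / dof)),
        max_predicted_rate=float(np.max(preds)),
    )
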