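"""Association analysis: design assembly, generalized mixed linear models,
hypothesis tests and diagnostics.

The biomarker table (one row per patient × staining) is joined with the
clinical covariates; continuous covariates are z-standardized on the
analysis sample and interaction columns are built after standardization.
The response models follow the study design:

* diabetes status — binomial family, canonical logit link;
* insulin secretion (HOMA2B) — Gaussian (identity) and Gamma families,
  compared by AIC;
* diabetes duration — Gaussian, additionally controlling for status.

All models carry random intercepts for staining and cohort (no patient
random effect: the response does not vary within a patient, so a patient
intercept would fit each patient perfectly).  Fitting is maximum likelihood
with a Laplace approximation to the marginal likelihood, optimized with
L-BFGS-B; random-effect standard deviations are bounded at zero and may
legitimately sit on the boundary.  Wald z-tests (two-sided) use the
observed information of the fixed effects at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

from isletscope.synthetic import ValidationError

BIOMARKER_EFFECTS = (
    "islet_mean_area",
    "islet_count",
    "adipocyte_cluster_area",
    "adipocyte_cluster_count",
    "islet_adipocyte_distance",
    "connective_area",
)
STATUS_COVARIATES = ("sex", "age", "bmi", "malignant_tumor", "chronic_pancreatitis")
_BINARY_LIKE = {"sex", "malignant_tumor", "chronic_pancreatitis", "insulin_therapy", "diabetic_status"}


@dataclass(frozen=True)
class ModelSpec:
    """Response, family, fixed effects and random-intercept factors."""

    response: str
    family: str  # "binomial" | "gaussian" | "gamma"
    fixed_effects: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    random_effects: tuple[str, ...] = ("staining", "cohort")
    zstandardize: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("binomial", "gaussian", "gamma"):
            raise ValidationError(f"unknown family {self.family!r}")

    @classmethod
    def diabetes_status(cls, biomarkers: tuple[str, ...] = BIOMARKER_EFFECTS) -> "ModelSpec":
        return cls(
            response="diabetic_status",
            family="binomial",
            fixed_effects=biomarkers + STATUS_COVARIATES,
        )

    @classmethod
    def homa2b(cls, family: str = "gaussian") -> "ModelSpec":
        return cls(
            response="homa2b",
            family=family,
            fixed_effects=BIOMARKER_EFFECTS + STATUS_COVARIATES + ("insulin_therapy",),
            interactions=(("adipocyte_cluster_area", "bmi"),),
        )

    @classmethod
    def diabetes_duration(cls) -> "ModelSpec":
        return cls(
            response="diabetes_duration",
            family="gaussian",
            fixed_effects=BIOMARKER_EFFECTS + STATUS_COVARIATES + ("diabetic_status",),
        )


@dataclass
class DesignMatrices:
    frame: pd.DataFrame
    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    groups: dict[str, np.ndarray]       # factor -> integer codes per row
    group_levels: dict[str, list]
    spec: ModelSpec


def assemble_design(
    cohort: pd.DataFrame,
    biomarkers: pd.DataFrame,
    spec: ModelSpec,
) -> DesignMatrices:
    """Join biomarkers to covariates and build the model matrices.

    One row per (patient, staining); rows with a missing response or
    missing predictors are dropped; continuous covariates are z-scored on
    the analysis sample (binary indicators are left as 0/1, and a Gamma
    response is kept on its positive natural scale).
    """
    orphans = set(biomarkers["patient_id"]) - set(cohort["patient_id"])
    if orphans:
        raise ValidationError(f"biomarker rows without cohort entry: {sorted(orphans)[:5]}")
    frame = biomarkers.merge(cohort, on="patient_id", how="inner", validate="many_to_one")

    frame = frame.dropna(subset=[spec.response])
    needed = list(dict.fromkeys(spec.fixed_effects + tuple(c for pair in spec.interactions for c in pair)))
    missing_cols = [c for c in needed + [spec.response] if c not in frame.columns]
    if missing_cols:
        raise ValidationError(f"design is missing columns: {missing_cols}")
    frame = frame.dropna(subset=needed).reset_index(drop=True)

    work = frame.copy()
    if spec.zstandardize:
        for col in needed:
            if col in _BINARY_LIKE:
                continue
            sd = work[col].std(ddof=1)
            if sd > 0:
                work[col] = (work[col] - work[col].mean()) / sd
        if spec.family == "gaussian" and spec.response not in _BINARY_LIKE:
            sd = work[spec.response].std(ddof=1)
            if sd > 0:
                work[spec.response] = (work[spec.response] - work[spec.response].mean()) / sd

    columns = ["Intercept"] + list(spec.fixed_effects)
    X_parts = [np.ones(len(work))] + [work[c].to_numpy(dtype=float) for c in spec.fixed_effects]
    for a, b in spec.interactions:
        columns.append(f"{a}:{b}")
        X_parts.append(work[a].to_numpy(dtype=float) * work[b].to_numpy(dtype=float))
    X = np.column_stack(X_parts)

    groups, levels = {}, {}
    for factor in spec.random_effects:
        codes, lv = pd.factorize(frame[factor])
        groups[factor] = codes
        levels[factor] = list(lv)

    y = work[spec.response].to_numpy(dtype=float)
    return DesignMatrices(
        frame=frame, y=y, X=X, columns=columns, groups=groups, group_levels=levels, spec=spec
    )


# ---------------------------------------------------------------------------
# Laplace-ML generalized mixed linear model
# ---------------------------------------------------------------------------

def _family(family: str):
    """Per-observation log-likelihood and its first two eta-derivatives."""

    if family == "binomial":

        def ll(y, eta, disp):
            p = special.expit(eta)
            return y * eta - np.logaddexp(0.0, eta), y - p, -p * (1 - p)

    elif family == "gaussian":

        def ll(y, eta, disp):
            phi = np.exp(disp)
            r = y - eta
            return (
                -0.5 * (r * r / phi + np.log(2 * np.pi * phi)),
                r / phi,
                np.full_like(eta, -1.0 / phi),
            )

    elif family == "gamma":
        # log link; disp is log(shape)
        def ll(y, eta, disp):
            k = np.exp(disp)
            mu_inv_y = y * np.exp(-eta)
            return (
                k * (disp - eta) + (k - 1) * np.log(y) - k * mu_inv_y - special.gammaln(k),
                k * (mu_inv_y - 1.0),
                -k * mu_inv_y,
            )

    else:  # pragma: no cover
        raise ValidationError(f"unknown family {family!r}")
    return ll


@dataclass
class GMLMFit:
    """Maximum-likelihood mixed-model fit with Wald z-tests."""

    params: pd.DataFrame           # estimate, se, z, p, stars per fixed effect
    random_effects: pd.DataFrame   # factor, variance, sd
    loglik: float
    aic: float
    nobs: int
    group_counts: dict[str, int]
    family: str
    response: str
    converged: bool
    u_hat: dict[str, np.ndarray] = field(default_factory=dict)
    dispersion: float | None = None
    fitted_linear: np.ndarray | None = None

    def summary(self) -> str:
        lines = [f"GMLM ({self.family}) for {self.response}", "Fixed effects:"]
        lines.append(self.params.to_string(float_format=lambda v: f"{v: .3f}"))
        lines.append("Random effects (intercepts):")
        lines.append(self.random_effects.to_string(index=False, float_format=lambda v: f"{v: .3f}"))
        lines.append(
            f"Observations: {self.nobs}  Groups: {self.group_counts}  "
            f"Log-likelihood: {self.loglik:.3f}  AIC: {self.aic:.3f}"
        )
        return "\n".join(lines)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


class _LaplaceObjective:
    def __init__(self, y, X, Z_blocks, family, has_disp):
        self.y, self.X = y, X
        self.Z_blocks = Z_blocks  # list of (n, q_f) indicator matrices
        self.q = [z.shape[1] for z in Z_blocks]
        self.family = _family(family)
        self.has_disp = has_disp
        self.p = X.shape[1]
        self._warm = np.zeros(sum(self.q))

    def split(self, theta):
        p = self.p
        beta = theta[:p]
        sigmas = theta[p : p + len(self.q)]
        disp = theta[-1] if self.has_disp else 0.0
        return beta, sigmas, disp

    def _eta(self, beta, sigmas, u):
        eta = self.X @ beta
        off = 0
        for z, s, qf in zip(self.Z_blocks, sigmas, self.q):
            eta = eta + s * (z @ u[off : off + qf])
            off += qf
        return eta

    def _mode(self, beta, sigmas, disp):
        """Inner Newton iteration for the latent mode (scaled effects)."""
        u = self._warm.copy()
        qtot = sum(self.q)
        if qtot == 0:
            return u, np.zeros((0, 0))
        Zs = np.hstack([s * z for z, s in zip(self.Z_blocks, sigmas)])
        for _ in range(60):
            eta = self.X @ beta + Zs @ u
            _, d1, d2 = self.family(self.y, eta, disp)
            grad = Zs.T @ d1 - u
            H = Zs.T @ (Zs * (-d2)[:, None]) + np.eye(qtot)
            step = np.linalg.solve(H, grad)
            u = u + step
            if np.max(np.abs(step)) < 1e-10:
                break
        self._warm = u
        eta = self.X @ beta + Zs @ u
        _, _, d2 = self.family(self.y, eta, disp)
        H = Zs.T @ (Zs * (-d2)[:, None]) + np.eye(qtot)
        return u, H

    def neg_loglik(self, theta):
        beta, sigmas, disp = self.split(theta)
        u, H = self._mode(beta, sigmas, disp)
        eta = self._eta(beta, sigmas, u)
        ll_terms, _, _ = self.family(self.y, eta, disp)
        ll = ll_terms.sum() - 0.5 * float(u @ u)
        if H.size:
            sign, logdet = np.linalg.slogdet(H)
            if sign <= 0:
                return 1e10
            ll -= 0.5 * logdet
        return -ll


def fit_gmlm(design: DesignMatrices, spec: ModelSpec | None = None) -> GMLMFit:
    """Fit the generalized mixed linear model by Laplace maximum likelihood.

    Random intercepts enter as independent blocks with their own standard
    deviation, bounded below by zero (boundary estimates are reported as
    exactly that, not dropped).  The outer optimization uses L-BFGS-B;
    non-convergence raises with the residual gradient norm.  Wald standard
    errors come from the observed information of the fixed effects at the
    optimum, with variance components held at their estimates.
    """
    spec = spec or design.spec
    y, X = design.y, design.X
    n, p = X.shape
    for factor, codes in design.groups.items():
        if len(np.unique(codes)) < 1:
            raise ValidationError(f"random factor {factor!r} has no level")
    Z_blocks = []
    for factor in spec.random_effects:
        codes = design.groups[factor]
        q = codes.max() + 1
        Z = np.zeros((n, q))
        Z[np.arange(n), codes] = 1.0
        Z_blocks.append(Z)

    has_disp = spec.family in ("gaussian", "gamma")
    obj = _LaplaceObjective(y, X, Z_blocks, spec.family, has_disp)

    # starting values from the fixed-effects GLM
    import statsmodels.api as sm

    fam = {
        "binomial": sm.families.Binomial(),
        "gaussian": sm.families.Gaussian(),
        "gamma": sm.families.Gamma(link=sm.families.links.Log()),
    }[spec.family]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X, family=fam).fit()
    beta0 = np.asarray(glm.params)
    theta0 = list(beta0) + [0.3] * len(Z_blocks)
    if has_disp:
        if spec.family == "gaussian":
            theta0.append(float(np.log(max(glm.scale, 1e-6))))
        else:
            theta0.append(float(-np.log(max(glm.scale, 1e-6))))
    theta0 = np.asarray(theta0)
    bounds = (
        [(None, None)] * p
        + [(0.0, 50.0)] * len(Z_blocks)
        + ([(-12.0, 12.0)] if has_disp else [])
    )

    res = optimize.minimize(
        obj.neg_loglik, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-2:
        raise ValidationError(
            f"GMLM did not converge: {res.message} (gradient norm {np.linalg.norm(res.jac):.2e})"
        )
    theta = res.x
    beta, sigmas, disp = obj.split(theta)
    loglik = -obj.neg_loglik(theta)

    # observed information of the fixed effects (variance components fixed)
    def nll_beta(b):
        return obj.neg_loglik(np.concatenate([b, theta[p:]]))

    hess = _numerical_hessian(nll_beta, beta)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)

    z = np.divide(beta, se, out=np.full(p, np.nan), where=se > 0)
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    params = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "z": z,
            "p": pvals,
            "stars": [_stars(v) for v in pvals],
        },
        index=design.columns,
    )
    rand = pd.DataFrame(
        {
            "factor": list(spec.random_effects),
            "type": "Intercept",
            "variance": sigmas**2,
            "sd": sigmas,
        }
    )
    k = p + len(Z_blocks) + (1 if has_disp else 0)
    u, _ = obj._mode(beta, sigmas, disp)
    u_hat, off = {}, 0
    for factor, z_blk, s in zip(spec.random_effects, Z_blocks, sigmas):
        qf = z_blk.shape[1]
        u_hat[factor] = s * u[off : off + qf]
        off += qf
    return GMLMFit(
        params=params,
        random_effects=rand,
        loglik=float(loglik),
        aic=float(2 * k - 2 * loglik),
        nobs=n,
        group_counts={f: len(lv) for f, lv in design.group_levels.items()},
        family=spec.family,
        response=spec.response,
        converged=bool(res.success),
        u_hat=u_hat,
        dispersion=float(np.exp(disp)) if has_disp else None,
        fitted_linear=obj._eta(beta, sigmas, u),
    )


def _numerical_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            if i == j:
                xp = x.copy(); xp[i] += eps
                xm = x.copy(); xm[i] -= eps
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / eps**2
            else:
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps**2)
    return H


def aic_select(fits: list[GMLMFit]) -> GMLMFit:
    """Return the fit with minimal AIC (ties: first declared, with a warning)."""
    if not fits:
        raise ValidationError("no fits to select from")
    first = fits[0]
    for fit in fits[1:]:
        if fit.response != first.response or fit.nobs != first.nobs:
            raise ValidationError("AIC comparison requires the same response and data")
    aics = [f.aic for f in fits]
    best = int(np.argmin(aics))
    if aics.count(min(aics)) > 1:
        warnings.warn("AIC tie; returning the first-declared fit")
    return fits[best]


# ---------------------------------------------------------------------------
# Multicollinearity screening
# ---------------------------------------------------------------------------

def vif_screen(
    frame: pd.DataFrame,
    effects: list[str],
    threshold: float = 10.0,
) -> tuple[list[str], pd.DataFrame, list[str]]:
    """Variance-inflation screening with deterministic removal.

    Perfectly collinear effects (VIF numerically infinite) are removed one
    at a time, later-declared first, until none remain; the final table
    flags any retained effect whose VIF still exceeds ``threshold``.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    if len(effects) < 2:
        raise ValidationError("VIF screening needs at least two effects")
    retained = list(effects)
    dropped: list[str] = []
    while True:
        X = np.column_stack(
            [np.ones(len(frame))] + [frame[c].to_numpy(dtype=float) for c in retained]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vifs = np.array(
                [variance_inflation_factor(X, i + 1) for i in range(len(retained))]
            )
        infinite = ~np.isfinite(vifs) | (vifs > 1e8)
        if not infinite.any():
            break
        victim = np.flatnonzero(infinite)[-1]  # later-declared dropped first
        dropped.append(retained.pop(victim))
        if len(retained) < 2:
            break
    X = np.column_stack(
        [np.ones(len(frame))] + [frame[c].to_numpy(dtype=float) for c in retained]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design remains singular after VIF removal")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final_vifs = [variance_inflation_factor(X, i + 1) for i in range(len(retained))]
    table = pd.DataFrame({"effect": retained, "vif": final_vifs})
    table["flagged"] = table["vif"] > threshold
    return retained, table, dropped


# ---------------------------------------------------------------------------
# Basic hypothesis tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    df: float | tuple
    name: str

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05


def t_test(a, b) -> TestResult:
    """Two-sided two-sample t-test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least two observations")
    res = sps.ttest_ind(a, b)
    return TestResult(float(res.statistic), float(res.pvalue), float(len(a) + len(b) - 2), "t-test")


def anova_f(*groups) -> TestResult:
    """One-way ANOVA F-test."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("ANOVA needs >= 2 groups with >= 2 observations each")
    res = sps.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return TestResult(float(res.statistic), float(res.pvalue), (df1, df2), "anova-F")


def z_test(estimate: float, se: float, null: float = 0.0) -> TestResult:
    """Two-sided z-test of a coefficient against ``null``."""
    if se <= 0:
        raise ValidationError("standard error must be positive")
    z = (estimate - null) / se
    return TestResult(float(z), float(2 * sps.norm.sf(abs(z))), np.inf, "z-test")


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def model_diagnostics(fit: GMLMFit, design: DesignMatrices, make_plots: bool = False) -> dict:
    """Confusion matrix (binomial) or residual/parity/Q-Q data (linear fits)."""
    eta = fit.fitted_linear
    out: dict = {}
    if fit.family == "binomial":
        probs = special.expit(eta)
        pred = (probs >= 0.5).astype(int)
        y = design.y.astype(int)
        cm = np.zeros((2, 2), dtype=int)
        for t, p_ in zip(y, pred):
            cm[t, p_] += 1
        out["confusion_matrix"] = cm
        out["accuracy"] = float(np.trace(cm) / cm.sum())
    else:
        mu = np.exp(eta) if fit.family == "gamma" else eta
        resid = design.y - mu
        sd = resid.std(ddof=1)
        std_resid = resid / sd if sd > 0 else resid
        osm, osr = sps.probplot(std_resid, fit=False)
        out["residuals"] = resid
        out["parity"] = pd.DataFrame({"observed": design.y, "fitted": mu})
        out["qq"] = pd.DataFrame({"theoretical": osm, "sample": osr})
    if make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
        if fit.family == "binomial":
            axes[0].imshow(out["confusion_matrix"], cmap="Blues")
            axes[0].set_title("confusion matrix")
            axes[1].hist(special.expit(eta), bins=20)
            axes[1].set_title("fitted probabilities")
        else:
            axes[0].scatter(out["parity"]["fitted"], out["parity"]["observed"], s=6)
            axes[0].set_title("parity")
            axes[1].scatter(out["qq"]["theoretical"], out["qq"]["sample"], s=6)
            axes[1].set_title("Q-Q")
        fig.tight_layout()
        out["figure"] = fig
    return out
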