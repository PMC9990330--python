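"""Inhomogeneous-point-process weighted resource-selection functions.

The used/available comparison is fitted as a weighted logistic regression:
used locations get weight 1, available locations a large weight W (default
5000), so the weighted Bernoulli likelihood approximates the inhomogeneous
Poisson point-process likelihood and the slope coefficients estimate the
log relative-selection surface.  The intercept is an artefact of the
used:available ratio and the weight and carries no selection information.

Individual variation is handled by two-stage pooling: per-tag-deployment
fixed fits aggregated by inverse-variance weighting with a method-of-moments
between-deployment variance per coefficient (a random-slope surrogate).
"Posterior" summaries are draws from the asymptotic normal distribution of
the maximum-likelihood estimator; relative selection strength (RSS) is the
exponential of a coefficient, the factor by which selection of a category
exceeds the crop-rotation reference at equal availability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import RankError, SchemaError
from .focal import total_prey_by_habitat
from .landscape import CATEGORIES

MODEL_TAGS = ("habitat", "density", "total_prey")

#: dominant-category dummies, crop rotation as reference
_HABITAT_LEVELS = [c for c in CATEGORIES if c != "crop_rotation"]


@dataclass
class RSFDesign:
    """Design matrix for one RSF model.

    ``X`` includes the intercept; numeric columns are z-scaled over the
    design and the scaling is recorded in ``scaling`` as (mean, sd).
    """

    X: pd.DataFrame
    y: np.ndarray
    weights: np.ndarray
    groups: np.ndarray
    model: str
    scaling: dict = field(default_factory=dict)

    def check_invariants(self, atol: float = 1e-8) -> None:
        assert set(np.unique(self.weights)) <= {1.0, float(self.weights.max())}
        for col in self.scaling:
            v = self.X[col].to_numpy()
            assert abs(v.mean()) < atol, f"{col} not centred"
            assert abs(v.std(ddof=0) - 1) < atol, f"{col} not scaled"


@dataclass
class RSFFit:
    """Weighted-logistic fit: coefficients on the log relative-selection
    scale with their asymptotic covariance."""

    beta: pd.Series
    cov: pd.DataFrame
    n_used: int
    n_available: int
    converged: bool
    n_iter: int
    model: str = ""
    message: str = ""
    between_variance: dict = field(default_factory=dict)
    n_deployments: int = 1

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.beta.index)


def _zscale(df: pd.DataFrame, cols, scaling: dict) -> None:
    for col in cols:
        v = df[col].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            warnings.warn(f"constant column {col!r}; left uncentred")
            continue
        scaling[col] = (float(v.mean()), float(sd))
        df[col] = (v - v.mean()) / sd


def build_design(
    table: pd.DataFrame,
    model: str,
    available_weight: float = 5000.0,
    interactions: bool | None = None,
    merge_grassland: bool = False,
) -> RSFDesign:
    """Build the design for one of the three RSF models.

    habitat     — dominant category (ref crop rotation), biodiversity
                  presence, structural richness, sex; optional habitat x
                  biodiversity interactions.
    density     — vole and small-mammal activity density per focal area,
                  biodiversity presence, sex; density x biodiversity
                  interactions on by default.
    total_prey  — combined prey activity per habitat stratum and focal
                  area, structural richness, sex; requires the foraging
                  filter.
    """
    if model not in MODEL_TAGS:
        raise SchemaError(f"unknown model {model!r}")
    required = {"case", "y", "deployment_id", "sex", "coverage_keep"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")

    df = table[table["coverage_keep"]].copy()
    if model == "habitat":
        df = df[df["dominant_known"]]
        if interactions is None:
            interactions = False
    else:
        df = df[df["foraging_keep"]]
        if interactions is None:
            interactions = model == "density"

    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    scaling: dict = {}

    if model == "habitat":
        for cat in _HABITAT_LEVELS:
            X[f"dominant_{cat}"] = (df["dominant"] == cat).astype(float)
        X["biodiv_present"] = df["biodiv_present"].astype(float)
        X["structural_richness"] = df["structural_richness"].astype(float)
        _zscale(X, ["structural_richness"], scaling)
        if interactions:
            for cat in _HABITAT_LEVELS:
                X[f"dominant_{cat}:biodiv"] = X[f"dominant_{cat}"] * X["biodiv_present"]
    elif model == "density":
        X["vole_density"] = df["vole_density"].astype(float)
        X["smallmammal_density"] = df["smallmammal_density"].astype(float)
        _zscale(X, ["vole_density", "smallmammal_density"], scaling)
        X["biodiv_present"] = df["biodiv_present"].astype(float)
        if interactions:
            X["vole_density:biodiv"] = X["vole_density"] * X["biodiv_present"]
            X["smallmammal_density:biodiv"] = (
                X["smallmammal_density"] * X["biodiv_present"]
            )
    else:  # total_prey
        prey = total_prey_by_habitat(df, merge_grassland=merge_grassland)
        for col in prey.columns:
            X[col] = prey[col].to_numpy()
        _zscale(X, list(prey.columns), scaling)
        X["structural_richness"] = df["structural_richness"].astype(float)
        _zscale(X, ["structural_richness"], scaling)

    X["sex_m"] = (df["sex"] == "m").astype(float)

    # a covariate with no variation in this table (single-sex data, absent
    # category) carries no information and would only alias the intercept
    constant = [c for c in X.columns if c != "intercept" and X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant columns: {constant}")
        X = X.drop(columns=constant)

    y = df["y"].to_numpy(dtype=float)
    w = np.where(y == 1, 1.0, float(available_weight))
    return RSFDesign(
        X=X,
        y=y,
        weights=w,
        groups=df["deployment_id"].to_numpy(),
        model=model,
        scaling=scaling,
    )


def _find_aliased(X: np.ndarray, names) -> list:
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[i] for i in piv[rank:]]


def fit_weighted_logistic(
    design: RSFDesign | None = None,
    X: pd.DataFrame | None = None,
    y: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    model: str = "",
) -> RSFFit:
    """Maximise the case-weighted Bernoulli log-likelihood by IRLS.

    Converged when ``max |delta beta| < tol`` (default 1e-8) within
    ``max_iter`` iterations; covariance is the inverse weighted information
    matrix.  Diverging coefficients flag separation; rank deficiency raises
    RankError naming the aliased columns.
    """
    if design is not None:
        X, y, weights, model = design.X, design.y, design.weights, design.model
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise RankError("rank-deficient design", _find_aliased(Xm, names))

    beta = np.zeros(Xm.shape[1])
    if "intercept" in names:
        p0 = float(np.clip((w * y).sum() / w.sum(), 1e-12, 1 - 1e-12))
        beta[names.index("intercept")] = np.log(p0 / (1 - p0))

    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xm @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        wirls = w * p * (1 - p)
        # guard against exact 0/1 fitted values
        wirls = np.maximum(wirls, 1e-300)
        z = wirls * eta + w * (y - p)
        info = Xm.T @ (wirls[:, None] * Xm)
        try:
            new = np.linalg.solve(info, Xm.T @ z)
        except np.linalg.LinAlgError:
            if np.max(np.abs(beta)) > 10:
                message = "separation suspected (fitted probabilities saturated)"
            else:
                message = "singular information matrix"
            break
        delta = np.max(np.abs(new - beta))
        beta = new
        if np.max(np.abs(beta)) > 50:
            message = "separation suspected (diverging coefficients)"
            break
        if delta < tol:
            converged = True
            break

    eta = Xm @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    info = Xm.T @ ((w * p * (1 - p))[:, None] * Xm)
    cov = np.linalg.pinv(info)
    return RSFFit(
        beta=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        n_used=int((y == 1).sum()),
        n_available=int((y == 0).sum()),
        converged=converged,
        n_iter=it,
        model=model,
        message=message,
    )


def fit_per_deployment(design: RSFDesign, min_rows: int = 30) -> list[RSFFit]:
    """Fixed weighted-logistic fit within each tag deployment."""
    fits = []
    for dep in pd.unique(design.groups):
        mask = design.groups == dep
        if mask.sum() < min_rows:
            continue
        X = design.X.loc[mask]
        keep_cols = [c for c in X.columns if X[c].nunique() > 1 or c == "intercept"]
        try:
            fit = fit_weighted_logistic(
                X=X[keep_cols],
                y=design.y[mask],
                weights=design.weights[mask],
                model=design.model,
            )
        except RankError:
            continue
        fit.message = str(dep)
        fits.append(fit)
    return fits


def fit_population(per_deployment_fits: list[RSFFit]) -> RSFFit:
    """Pool per-deployment estimates across tags.

    Per coefficient: inverse-variance-weighted mean with a method-of-moments
    (DerSimonian-Laird) between-deployment variance, reported in
    ``between_variance`` as the random-slope surrogate.
    """
    fits = [f for f in per_deployment_fits if f.converged]
    if not fits:
        raise RankError("no converged deployment fits to pool")
    terms = sorted({t for f in fits for t in f.beta.index})
    pooled, pooled_var, tau2 = {}, {}, {}
    for t in terms:
        b = np.array([f.beta[t] for f in fits if t in f.beta.index])
        v = np.array([f.cov.loc[t, t] for f in fits if t in f.beta.index])
        v = np.maximum(v, 1e-12)
        w = 1.0 / v
        b_fe = (w * b).sum() / w.sum()
        k = len(b)
        if k > 1:
            q = (w * (b - b_fe) ** 2).sum()
            denom = w.sum() - (w**2).sum() / w.sum()
            t2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        else:
            t2 = 0.0
        w_re = 1.0 / (v + t2)
        pooled[t] = (w_re * b).sum() / w_re.sum()
        pooled_var[t] = 1.0 / w_re.sum()
        tau2[t] = t2
    beta = pd.Series(pooled)[terms]
    cov = pd.DataFrame(np.diag([pooled_var[t] for t in terms]), index=terms, columns=terms)
    return RSFFit(
        beta=beta,
        cov=cov,
        n_used=sum(f.n_used for f in fits),
        n_available=sum(f.n_available for f in fits),
        converged=True,
        n_iter=0,
        model=fits[0].model,
        between_variance=tau2,
        n_deployments=len(fits),
    )


@dataclass
class RSSReport:
    """Relative selection strengths with simulated 95% intervals."""

    table: pd.DataFrame
    n_draws: int
    seed: int


def rss(fit: RSFFit, n_draws: int = 1000, seed: int = 0) -> RSSReport:
    """RSS = exp(beta) with intervals from draws of the estimator's normal
    sampling distribution (mean beta-hat, covariance V-hat).

    ``rss`` is the exponential of the point estimate; ``rss_draw_mean`` is
    the mean of exp over the draws (slightly larger, by Jensen).  A term is
    meaningful iff its beta interval excludes 0.
    """
    rng = np.random.default_rng(seed)
    names = list(fit.beta.index)
    draws = rng.multivariate_normal(
        fit.beta.to_numpy(), fit.cov.to_numpy(), size=n_draws, method="svd"
    )
    lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
    table = pd.DataFrame(
        {
            "term": names,
            "beta": fit.beta.to_numpy(),
            "beta_lo": lo,
            "beta_hi": hi,
            "rss": np.exp(fit.beta.to_numpy()),
            "rss_lo": np.exp(lo),
            "rss_hi": np.exp(hi),
            "rss_draw_mean": np.exp(draws).mean(axis=0),
            "meaningful": (lo > 0) | (hi < 0),
        }
    )
    return RSSReport(table=table, n_draws=n_draws, seed=seed)


def ratio_sensitivity(
    table: pd.DataFrame,
    model: str = "habitat",
    ratios=(10, 50, 100),
    seed: int = 0,
    available_weight: float = 5000.0,
) -> pd.DataFrame:
    """Refit the RSF with the availability sample thinned to each ratio.

    The full design is scaled once, then available rows are subsampled per
    deployment to ``n_used x ratio``; returns one row per (ratio, term) with
    the max pairwise coefficient difference in ``max_abs_diff``.
    """
    design = build_design(table, model, available_weight=available_weight)
    rng = np.random.default_rng(seed)
    rows = []
    betas = {}
    used_mask = design.y == 1
    for ratio in ratios:
        keep = np.where(used_mask)[0].tolist()
        for dep in pd.unique(design.groups):
            dep_used = used_mask & (design.groups == dep)
            dep_avail = np.where(~used_mask & (design.groups == dep))[0]
            n_take = min(len(dep_avail), int(dep_used.sum()) * int(ratio))
            keep.extend(rng.choice(dep_avail, size=n_take, replace=False).tolist())
        idx = np.sort(np.array(keep))
        fit = fit_weighted_logistic(
            X=design.X.iloc[idx],
            y=design.y[idx],
            weights=design.weights[idx],
            model=model,
        )
        betas[ratio] = fit.beta
        for term in fit.beta.index:
            rows.append(
                {
                    "ratio": ratio,
                    "term": term,
                    "beta": float(fit.beta[term]),
                    "se": float(fit.se[term]),
                }
            )
    out = pd.DataFrame(rows)
    diffs, slope_diffs = [], []
    for i, r1 in enumerate(ratios):
        for r2 in ratios[i + 1 :]:
            d = (betas[r1] - betas[r2]).abs()
            diffs.append(float(d.max()))
            slope_diffs.append(float(d.drop("intercept", errors="ignore").max()))
    # the intercept shifts by log(ratio2/ratio1) by construction; only the
    # slopes are expected to stabilise
    out.attrs["max_abs_diff"] = max(diffs) if diffs else 0.0
    out.attrs["max_slope_diff"] = max(slope_diffs) if slope_diffs else 0.0
    return out


@dataclass
class ValidationResult:
    slope: float
    intercept: float
    r_squared: float
    bins: pd.DataFrame
    n_bins_merged: int = 0


def cross_validate(
    table_or_design,
    model: str = "habitat",
    k_folds: int = 5,
    n_bins: int = 10,
    seed: int = 0,
    available_weight: float = 5000.0,
    permute: bool = False,
) -> ValidationResult:
    """Calibration check: regress observed against expected used counts.

    K-fold split; per held-out fold, locations are binned by predicted
    relative selection (quantile bins over the fold's available scores) and
    the used counts observed per bin are regressed on the counts expected
    from the availability-weighted scores.  A calibrated model gives slope
    near 1; ``permute`` shuffles the predictions as a null check.
    """
    if isinstance(table_or_design, RSFDesign):
        design = table_or_design
    else:
        design = build_design(table_or_design, model, available_weight=available_weight)
    rng = np.random.default_rng(seed)
    fold = rng.integers(0, k_folds, size=len(design.y))
    slope_terms = [c for c in design.X.columns if c != "intercept"]
    records = []
    merged = 0
    for f in range(k_folds):
        train = fold != f
        test = ~train
        fit = fit_weighted_logistic(
            X=design.X.loc[train],
            y=design.y[train],
            weights=design.weights[train],
            model=design.model,
        )
        score = design.X.loc[test, slope_terms].to_numpy() @ fit.beta[slope_terms].to_numpy()
        score = np.exp(score - score.max())
        if permute:
            score = rng.permutation(score)
        y_test = design.y[test]
        avail = y_test == 0
        if avail.sum() < n_bins or (y_test == 1).sum() == 0:
            continue
        edges = np.unique(np.quantile(score[avail], np.linspace(0, 1, n_bins + 1)))
        if len(edges) - 1 < n_bins:
            merged += n_bins - (len(edges) - 1)
        if len(edges) < 3:
            warnings.warn("degenerate binning: fewer than 2 distinct bins")
            continue
        which = np.clip(np.searchsorted(edges, score, side="right") - 1, 0, len(edges) - 2)
        n_used_test = int((y_test == 1).sum())
        denom = score[avail].sum()
        for b in range(len(edges) - 1):
            in_bin = which == b
            expected = n_used_test * score[avail & in_bin].sum() / denom
            observed = int((in_bin & (y_test == 1)).sum())
            records.append({"fold": f, "bin": b, "expected": expected, "observed": observed})
    bins = pd.DataFrame(records)
    if len(bins) < 2:
        raise SchemaError("not enough bins for validation regression")
    x = bins["expected"].to_numpy()
    yb = bins["observed"].to_numpy()
    slope, intercept = np.polyfit(x, yb, 1)
    pred = slope * x + intercept
    ss_res = ((yb - pred) ** 2).sum()
    ss_tot = ((yb - yb.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return ValidationResult(float(slope), float(intercept), float(r2), bins, merged)
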