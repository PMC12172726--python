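"""Hierarchical Bayesian regression ensemble for region-wise field summaries.

Every model is a Gaussian linear mixed model: a fixed-effect design built
from subsets of the four factors (region, hemisphere, montage, group) with
full interactions among the included factors, plus a random intercept per
subject.  The ensemble enumerates the sixteen factor subsets (null, four
singles, six pairs, four triplets, full), optionally adding a seventeenth
model in which group enters as a main effect on top of the full
region x hemisphere x montage interaction structure.

Fitting uses a conjugate blocked Gibbs sampler (the model is jointly
Gaussian given the two variances, so all conditionals are exact); priors
are weakly informative on the standardized response scale: coefficients
N(0, 5^2), variances InvGamma(0.01, 0.01).  Convergence is judged by
split-R-hat < 1.05; model selection by PSIS-LOO (LOOIC = -2 elpd_loo,
lower is better), both computed with ArviZ.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats as sps

FACTORS = ("region", "hemisphere", "montage", "group")


# ---------------------------------------------------------------------------
# Model specifications and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One mean structure: factor subset with full interactions (or the
    group-main-effect-only variant), plus the always-on subject intercept."""

    response: str
    factors: tuple[str, ...] = ()
    group_main_only: bool = False

    @property
    def name(self) -> str:
        if self.group_main_only:
            return "region x hemisphere x montage + group"
        if not self.factors:
            return "null"
        return " x ".join(self.factors)

    def includes_group(self) -> bool:
        return self.group_main_only or "group" in self.factors


def build_model_ensemble(
    response: str = "mean_normal",
    factors: tuple[str, ...] = FACTORS,
    include_group_main_only: bool = False,
) -> list[ModelSpec]:
    """The 16-model ensemble (17 with the group-main-effect-only variant)."""
    specs = [ModelSpec(response, ())]
    for k in (1, 2, 3, 4):
        for sub in itertools.combinations(factors, k):
            specs.append(ModelSpec(response, sub))
    if include_group_main_only:
        others = tuple(f for f in factors if f != "group")
        specs.append(ModelSpec(response, others, group_main_only=True))
    return specs


def _dummies(values: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded dummies, reference = first level in sorted order."""
    levels = sorted(pd.unique(values))
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((values == lev).to_numpy(dtype=float))
        names.append(f"{prefix}[{lev}]")
    return (np.column_stack(cols) if cols else np.empty((len(values), 0))), names


def design_matrix(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design (with intercept) for a model specification."""
    base = {f: _dummies(data[f], f) for f in FACTORS if f in data.columns}
    blocks = [np.ones((len(data), 1))]
    names = ["intercept"]
    for k in range(1, len(spec.factors) + 1):
        for combo in itertools.combinations(spec.factors, k):
            mats = [base[f][0] for f in combo]
            labs = [base[f][1] for f in combo]
            cur = mats[0]
            curnames = labs[0]
            for mat, lab in zip(mats[1:], labs[1:]):
                cur = cur[:, :, None] * mat[:, None, :]
                cur = cur.reshape(len(data), -1)
                curnames = [f"{a}:{b}" for a in curnames for b in lab]
            blocks.append(cur)
            names.extend(curnames)
    if spec.group_main_only:
        g, gnames = base["group"]
        blocks.append(g)
        names.extend(gnames)
    return np.concatenate(blocks, axis=1), names


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings (defaults: 4 chains of 2000 iterations, half warm-up)."""

    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    seed: int = 0
    beta_prior_sd: float = 5.0  # on the standardized response scale
    var_prior_a: float = 0.01
    var_prior_b: float = 0.01
    rhat_threshold: float = 1.05
    #: Pointwise likelihood used for PSIS-LOO: "marginal" integrates the
    #: subject intercept out of every row (the right scope for comparing
    #: between-subject predictors such as diagnosis group); "conditional"
    #: conditions on the fitted intercepts.
    loo_scope: str = "marginal"


@dataclass
class PosteriorFit:
    """Posterior draws plus diagnostics for one model."""

    spec: ModelSpec
    coef_names: list[str]
    idata: az.InferenceData
    rhat_max: float
    converged: bool
    looic: float
    looic_se: float
    n_high_pareto_k: int
    r2: float
    subjects: list[str]
    _data: pd.DataFrame = field(repr=False, default=None)

    def coef_draws(self, name: str) -> np.ndarray:
        i = self.coef_names.index(name)
        return self.idata.posterior["beta"].values[:, :, i].ravel()

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        """Posterior mean and HDI per fixed-effect coefficient."""
        rows = []
        for i, nm in enumerate(self.coef_names):
            d = self.idata.posterior["beta"].values[:, :, i].ravel()
            lo, hi = hdi(d, mass)
            rows.append({"coefficient": nm, "mean": d.mean(), "hdi_lo": lo, "hdi_hi": hi})
        return pd.DataFrame(rows)

    def group_contrast(self, mass: float = 0.95) -> dict:
        """Posterior of the marginal group contrast, averaged over the
        observed design.  With AD/control groups this is the atrophy effect
        AD minus control (negative = reduced in the atrophic group);
        otherwise the second sorted level minus the first.  Zero for models
        without a group term."""
        if not self.spec.includes_group() or self._data is None:
            zeros = np.zeros(10)
            return {"mean": 0.0, "hdi_lo": 0.0, "hdi_hi": 0.0, "draws": zeros}
        levels = sorted(pd.unique(self._data["group"]))
        if set(levels) == {"AD", "control"}:
            levels = ["control", "AD"]  # contrast = AD - control
        rowmeans = []
        for lev in levels:
            d = self._data.copy()
            d["group"] = pd.Series([lev] * len(d), index=d.index)
            Xl, _ = _design_with_levels(d, self.spec, self._data)
            rowmeans.append(Xl.mean(axis=0))
        delta = rowmeans[1] - rowmeans[0]
        beta = self.idata.posterior["beta"].values  # (c, d, p)
        draws = beta.reshape(-1, beta.shape[-1]) @ delta
        lo, hi = hdi(draws, mass)
        return {"mean": float(draws.mean()), "hdi_lo": lo, "hdi_hi": hi, "draws": draws}


def _design_with_levels(
    d: pd.DataFrame, spec: ModelSpec, template: pd.DataFrame
) -> tuple[np.ndarray, list[str]]:
    """Design for counterfactual data ``d`` using the level sets of
    ``template`` (so dummy columns line up)."""
    full = pd.concat([template, d], ignore_index=True)
    X, names = design_matrix(full, spec)
    return X[len(template):], names


def fit_hierarchical(
    spec: ModelSpec,
    data: pd.DataFrame,
    sampler: SamplerConfig = SamplerConfig(),
) -> PosteriorFit:
    """Fit one hierarchical model by blocked Gibbs sampling.

    The subject random intercept is always included.  Draws, R-hat, PSIS-LOO
    (on the original response scale) and Bayesian R^2 are returned in a
    :class:`PosteriorFit`; non-convergence sets a flag rather than raising.
    """
    if spec.response not in data.columns:
        raise ValueError(f"response column {spec.response!r} missing")
    y = data[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    subjects, j = np.unique(data["subject"].to_numpy(), return_inverse=True)
    X, names = design_matrix(data, spec)
    N, p = X.shape
    J = len(subjects)
    my, sy = float(y.mean()), float(y.std())
    if sy == 0:
        sy = 1.0  # degenerate constant response: fit on raw scale
    ys = (y - my) / sy

    XtX = X.T @ X
    Xty = X.T @ ys
    XtZ = np.zeros((p, J))
    np.add.at(XtZ.T, j, X)
    counts = np.bincount(j, minlength=J).astype(float)
    ysums = np.bincount(j, weights=ys, minlength=J)

    a0, b0 = sampler.var_prior_a, sampler.var_prior_b
    s2b = sampler.beta_prior_sd**2
    n_iter = sampler.warmup + sampler.draws
    ss = np.random.SeedSequence(sampler.seed)
    chain_seeds = ss.spawn(sampler.chains)

    beta_out = np.empty((sampler.chains, sampler.draws, p))
    b_out = np.empty((sampler.chains, sampler.draws, J))
    sig_out = np.empty((sampler.chains, sampler.draws))
    tau_out = np.empty((sampler.chains, sampler.draws))

    eye_p = np.eye(p)
    for c in range(sampler.chains):
        rng = np.random.default_rng(chain_seeds[c])
        b = rng.normal(0, 0.1, J)
        sig2, tau2 = 1.0, 1.0
        for it in range(n_iter):
            # beta with the random intercepts collapsed out:
            # y ~ N(X beta, sigma^2 I + tau^2 Z Z'); Woodbury gives
            # per-subject corrections with weights w_j
            w = tau2 / (sig2 * (sig2 + counts * tau2))
            P = XtX / sig2 - (XtZ * w) @ XtZ.T + eye_p / s2b
            rhs = Xty / sig2 - XtZ @ (w * ysums)
            L = np.linalg.cholesky(P)
            tmp = np.linalg.solve(L, rhs)
            mean = np.linalg.solve(L.T, tmp)
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
            mu = X @ beta
            resid = ys - mu
            # subject intercepts given beta
            sums = np.bincount(j, weights=resid, minlength=J)
            prec = counts / sig2 + 1.0 / tau2
            b = sums / sig2 / prec + rng.standard_normal(J) / np.sqrt(prec)
            r = resid - b[j]
            sig2 = 1.0 / rng.gamma(a0 + 0.5 * N, 1.0 / (b0 + 0.5 * float(r @ r)))
            tau2 = 1.0 / rng.gamma(a0 + 0.5 * J, 1.0 / (b0 + 0.5 * float(b @ b)))
            if it >= sampler.warmup:
                k = it - sampler.warmup
                beta_out[c, k] = beta
                b_out[c, k] = b
                sig_out[c, k] = sig2
                tau_out[c, k] = tau2

    # back to the original response scale
    beta_orig = beta_out * sy
    beta_orig[:, :, 0] += my
    b_orig = b_out * sy
    sigma_orig = np.sqrt(sig_out) * sy
    tau_orig = np.sqrt(tau_out) * sy

    # pointwise log-likelihood and Bayesian R^2, chunked over draws
    if sampler.loo_scope not in ("marginal", "conditional"):
        raise ValueError("loo_scope must be 'marginal' or 'conditional'")
    ll = np.empty((sampler.chains, sampler.draws, N))
    r2_parts = []
    for c in range(sampler.chains):
        fit_c = beta_orig[c] @ X.T + b_orig[c][:, j]  # (draws, N)
        s = sigma_orig[c][:, None]
        if sampler.loo_scope == "marginal":
            # subject intercept integrated out: y_i ~ N(x_i beta, sigma^2 + tau^2)
            mfit = beta_orig[c] @ X.T
            v = (sigma_orig[c] ** 2 + tau_orig[c] ** 2)[:, None]
            ll[c] = -0.5 * np.log(2 * np.pi * v) - (y[None, :] - mfit) ** 2 / (2 * v)
        else:
            ll[c] = -0.5 * np.log(2 * np.pi * s**2) - (y[None, :] - fit_c) ** 2 / (2 * s**2)
        var_fit = fit_c.var(axis=1)
        r2_parts.append(var_fit / (var_fit + sigma_orig[c] ** 2))
    r2 = float(np.mean(np.concatenate(r2_parts)))

    idata = az.from_dict(
        posterior={
            "beta": beta_orig,
            "sigma": sigma_orig,
            "tau": tau_orig,
            "b_subject": b_orig,
        },
        log_likelihood={"y": ll},
        coords={"coef": names, "subject": list(map(str, subjects))},
        dims={"beta": ["coef"], "b_subject": ["subject"]},
    )
    rh = az.rhat(idata.posterior)
    rhat_max = float(
        max(np.nanmax(np.atleast_1d(rh[v].values)) for v in ("beta", "sigma", "tau"))
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loo = az.loo(idata, pointwise=True)
    looic = float(-2.0 * loo.elpd_loo)
    looic_se = float(2.0 * loo.se)
    n_bad = int((loo.pareto_k.values > 0.7).sum())
    converged = bool(rhat_max < sampler.rhat_threshold)
    if not converged:
        warnings.warn(
            f"model {spec.name!r}: max R-hat {rhat_max:.3f} >= "
            f"{sampler.rhat_threshold}; fit flagged non-converged"
        )
    return PosteriorFit(
        spec=spec,
        coef_names=names,
        idata=idata,
        rhat_max=rhat_max,
        converged=converged,
        looic=looic,
        looic_se=looic_se,
        n_high_pareto_k=n_bad,
        r2=r2,
        subjects=list(map(str, subjects)),
        _data=data,
    )


# ---------------------------------------------------------------------------
# LOO ranking, HDI, t-test
# ---------------------------------------------------------------------------

@dataclass
class EnsembleRanking:
    """Models ordered by ascending LOOIC (lower = better predictive fit)."""

    table: pd.DataFrame
    winner: PosteriorFit

    def winner_name(self) -> str:
        return self.winner.spec.name


def compare_loo(fits: list[PosteriorFit]) -> EnsembleRanking:
    """Rank converged fits by LOOIC; non-converged fits are excluded with a
    warning, models with high Pareto-k counts are annotated."""
    usable = [f for f in fits if f.converged]
    dropped = [f for f in fits if not f.converged]
    for f in dropped:
        warnings.warn(f"excluding non-converged model {f.spec.name!r} from ranking")
    if len(usable) < 1:
        raise RuntimeError("no converged fits to rank")
    rows = [
        {
            "model": f.spec.name,
            "looic": f.looic,
            "se": f.looic_se,
            "r2": f.r2,
            "rhat_max": f.rhat_max,
            "n_high_pareto_k": f.n_high_pareto_k,
        }
        for f in usable
    ]
    table = pd.DataFrame(rows).sort_values("looic", kind="stable").reset_index(drop=True)
    winner = usable[int(np.argmin([f.looic for f in usable]))]
    return EnsembleRanking(table=table, winner=winner)


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``mass`` of the draws (unimodal HDI)."""
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must lie in (0, 1]")
    x = np.sort(np.asarray(draws).ravel())
    n = len(x)
    k = max(1, int(np.ceil(mass * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def two_sample_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance independent-samples t-test from summary statistics.

    Returns (t, df, two-sided p).  With equal group sizes the pooled and
    unpooled statistics coincide.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)
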