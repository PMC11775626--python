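"""Single-season site-occupancy model with imperfect detection.

The model treats each camera site i as used (z_i = 1) with probability
psi_i and, conditional on use, detected on each active occasion j with
probability p_i.  Both probabilities carry logit-linear covariate effects:

    logit(psi_i) = x_i' beta          (space use / occupancy)
    logit(p_i)   = w_i' alpha         (detection)

Marginalising the latent state gives the site likelihood

    L_i = psi_i * prod_j p_i^{y_ij} (1 - p_i)^{1 - y_ij}
          + (1 - psi_i) * 1[site never detected],

with the product over unmasked (camera-active) occasions.  ``psi`` is read
as *space use* — the probability the species uses the site during the
window — rather than closed-population occupancy.

Fitting follows the statsmodels pattern: :class:`OccupancyModel` is built
from a detection history and design matrices; ``fit()`` returns a
maximum-likelihood results object and ``sample()`` a Bayesian results
object from a Metropolis-within-Gibbs sampler (exact Gibbs draw of the
latent states, adaptive random-walk Metropolis on the coefficient blocks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

__all__ = [
    "OccupancyModel",
    "OccupancyMLEResults",
    "OccupancyMCMCResults",
    "site_likelihood",
    "summarize_draws",
    "split_rhat",
]

_PROB_EPS = 1e-12


def site_likelihood(y_row, psi, p, mask=None) -> float:
    """Marginal likelihood of one site's detection history.

    Parameters
    ----------
    y_row : array of 0/1 detections over occasions
    psi : probability the site is used
    p : scalar or per-occasion detection probability given use
    mask : boolean array, True where the camera was active; inactive
        occasions contribute nothing.
    """
    y = np.asarray(y_row, dtype=float)
    p = np.broadcast_to(np.asarray(p, dtype=float), y.shape)
    if mask is None:
        mask = np.ones_like(y, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    y, p = y[mask], p[mask]
    cond = float(np.prod(np.where(y > 0, p, 1.0 - p)))
    never = float(np.all(y == 0))
    return psi * cond + (1.0 - psi) * never


@dataclass
class PosteriorSummaryRow:
    """One row of a posterior summary table (Table-style record)."""

    name: str
    mean: float
    sd: float
    lcl: float
    ucl: float
    rhat: float
    ess: float
    overlap0: int


def split_rhat(draws: np.ndarray) -> float:
    """Classical split-chain Gelman-Rubin potential scale reduction.

    ``draws`` has shape (chains, iterations).  Each chain is split in half,
    and Rhat = sqrt(((N-1)/N * W + B/N) / W) over the split chains.
    """
    draws = np.asarray(draws, dtype=float)
    c, n = draws.shape
    half = n // 2
    if half < 2:
        return np.nan
    parts = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n2 = parts.shape
    means = parts.mean(axis=1)
    W = parts.var(axis=1, ddof=1).mean()
    B = n2 * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (n2 - 1) / n2 * W + B / n2
    return float(np.sqrt(var_hat / W))


def _rhat_ess(draws: np.ndarray, method: str = "rank"):
    """Rhat and bulk ESS for (chains, iterations) draws.

    Rank-normalized split Rhat and autocorrelation-based ESS are delegated
    to arviz; ``method='classical'`` uses the in-package split Rhat.
    Degenerate (zero-variance) draws report Rhat 1 and ESS 0 with a flag.
    """
    draws = np.asarray(draws, dtype=float)
    if np.ptp(draws) == 0:
        return 1.0, 0.0, True
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "classical":
            r = split_rhat(draws)
        else:
            r = float(az.rhat(draws))
        ess = float(az.ess(draws))
    if not np.isfinite(r):
        return 1.0, ess, True
    return float(r), ess, False


def summarize_draws(draws: dict[str, np.ndarray], level: float = 0.95,
                    rhat_method: str = "rank") -> pd.DataFrame:
    """Posterior summary table from named (chains, iterations) draw arrays.

    Columns: mean, sd, equal-tailed credible limits (LCL/UCL), split-chain
    Rhat, effective sample size, and ``overlap0`` — 1 when the interval
    contains zero, 0 when it excludes zero (the significance rule).
    """
    lo, hi = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    rows = []
    for name, d in draws.items():
        d = np.asarray(d, dtype=float)
        pooled = d.reshape(-1)
        lcl, ucl = np.quantile(pooled, [lo, hi])
        rhat, ess, flagged = _rhat_ess(d, method=rhat_method)
        rows.append({
            "parameter": name,
            "mean": pooled.mean(),
            "sd": pooled.std(ddof=1) if pooled.size > 1 else 0.0,
            "LCL": lcl,
            "UCL": ucl,
            "Rhat": rhat,
            "ESS": ess,
            "overlap0": int(lcl <= 0.0 <= ucl),
            "flag_degenerate": flagged,
        })
    return pd.DataFrame(rows).set_index("parameter")


class OccupancyModel:
    """Occupancy model for a site x occasion detection history.

    Parameters
    ----------
    y : (n_sites, n_occasions) 0/1 array of detections.
    psi_design : (n_sites, k_psi) design matrix for space use; defaults to
        an intercept-only column.  Covariates are expected standardized.
    p_design : (n_sites, k_p) design matrix for detection, or None for an
        intercept-only model.  Detection is constant across occasions
        within a site.
    mask : boolean effort mask, True where the camera was active.
    psi_names, p_names : coefficient labels.
    prior_sd : sd of the independent Normal(0, sd) priors on all
        logit-scale coefficients (Bayesian fit only).
    """

    def __init__(self, y, psi_design=None, p_design=None, mask=None,
                 psi_names=None, p_names=None, prior_sd: float = 2.0):
        self.y = np.asarray(y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be 2-d (sites x occasions)")
        n = self.y.shape[0]
        self.mask = (np.ones_like(self.y, dtype=bool) if mask is None
                     else np.asarray(mask, dtype=bool))
        if self.mask.shape != self.y.shape:
            raise ValueError("mask shape must match y")
        self.X = (np.ones((n, 1)) if psi_design is None
                  else np.asarray(psi_design, dtype=float))
        self.W = (np.ones((n, 1)) if p_design is None
                  else np.asarray(p_design, dtype=float))
        if self.X.shape[0] != n or self.W.shape[0] != n:
            raise ValueError(
                f"design rows ({self.X.shape[0]}, {self.W.shape[0]}) must "
                f"match the {n} detection-history rows")
        self.k_psi = self.X.shape[1]
        self.k_p = self.W.shape[1]
        self.psi_names = list(psi_names) if psi_names is not None else [
            "psi_intercept" if j == 0 else f"psi_x{j}" for j in range(self.k_psi)]
        self.p_names = list(p_names) if p_names is not None else [
            "p_intercept" if j == 0 else f"p_x{j}" for j in range(self.k_p)]
        if len(self.psi_names) != self.k_psi or len(self.p_names) != self.k_p:
            raise ValueError("coefficient name lengths must match design widths")
        self.prior_sd = float(prior_sd)

        yy = np.where(self.mask, self.y, 0.0)
        self.detections = yy.sum(axis=1)            # d_i
        self.effort = self.mask.sum(axis=1)         # J_i effective occasions
        self.any_det = self.detections > 0

    @classmethod
    def from_history(cls, history, covariates: pd.DataFrame | None = None,
                     psi_columns=(), p_columns=(), standardize: bool = True,
                     **kwargs):
        """Build from a DetectionHistory and a per-site covariate table.

        Covariate columns are z-scored (mean/sd of the analysed sites)
        unless ``standardize=False``; an intercept column is prepended to
        both designs.
        """
        y, mask = history.y, history.mask
        n = y.shape[0]

        def design(cols):
            mats, names = [np.ones((n, 1))], ["(Intercept)"]
            for c in cols:
                v = covariates.loc[history.site_ids, c].to_numpy(dtype=float)
                if standardize:
                    sd = v.std(ddof=0)
                    v = (v - v.mean()) / (sd if sd > 0 else 1.0)
                mats.append(v[:, None])
                names.append(c)
            return np.hstack(mats), names

        X, xn = design(psi_columns)
        W, wn = design(p_columns)
        return cls(y, psi_design=X, p_design=W, mask=mask,
                   psi_names=[f"psi:{s}" for s in xn],
                   p_names=[f"p:{s}" for s in wn], **kwargs)

    # -- likelihood ---------------------------------------------------------

    def _split(self, params):
        params = np.asarray(params, dtype=float)
        return params[: self.k_psi], params[self.k_psi :]

    def loglike(self, params) -> float:
        """Total log-likelihood with the latent state marginalised out."""
        beta, alpha = self._split(params)
        psi = expit(self.X @ beta)
        p = expit(self.W @ alpha)
        psi = np.clip(psi, _PROB_EPS, 1 - _PROB_EPS)
        p = np.clip(p, _PROB_EPS, 1 - _PROB_EPS)
        # detection log-lik per site given z=1 (mask-aware, p constant per site)
        ll_det = (self.detections * np.log(p)
                  + (self.effort - self.detections) * np.log1p(-p))
        with_det = np.log(psi) + ll_det
        no_det = np.logaddexp(np.log(psi) + ll_det, np.log1p(-psi))
        return float(np.sum(np.where(self.any_det, with_det, no_det)))

    def _logprior(self, params):
        params = np.asarray(params, dtype=float)
        return float(-0.5 * np.sum((params / self.prior_sd) ** 2))

    # -- maximum likelihood -------------------------------------------------

    def fit(self, start=None, fix_p_at: float | None = None,
            method: str = "L-BFGS-B") -> "OccupancyMLEResults":
        """Maximum-likelihood fit; standard errors from the observed
        information (numerical Hessian at the optimum).

        ``fix_p_at`` fixes detection at a constant (e.g. 1.0), leaving only
        the space-use coefficients free; with ``fix_p_at=1`` and an
        intercept-only design, psi-hat is the naive occupancy proportion.
        """
        if fix_p_at is not None:
            pfix = float(fix_p_at)
            if pfix >= 1.0:
                # perfect detection: z is observed, the history collapses to
                # the ever-detected indicator and psi-hat is naive occupancy
                def nll(beta):
                    psi = np.clip(expit(self.X @ beta), _PROB_EPS, 1 - _PROB_EPS)
                    ll = np.where(self.any_det, np.log(psi), np.log1p(-psi))
                    return -float(np.sum(ll))
            else:
                def nll(beta):
                    psi = np.clip(expit(self.X @ beta), _PROB_EPS, 1 - _PROB_EPS)
                    ll_det = (self.detections * np.log(pfix)
                              + (self.effort - self.detections) * np.log1p(-pfix))
                    with_det = np.log(psi) + ll_det
                    no_det = np.logaddexp(np.log(psi) + ll_det, np.log1p(-psi))
                    return -float(np.sum(np.where(self.any_det, with_det, no_det)))

            x0 = np.zeros(self.k_psi) if start is None else np.asarray(start)
            res = optimize.minimize(nll, x0, method=method)
            names = list(self.psi_names)
        else:
            def nll(params):
                return -self.loglike(params)

            x0 = (np.zeros(self.k_psi + self.k_p) if start is None
                  else np.asarray(start, dtype=float))
            res = optimize.minimize(nll, x0, method=method)
            names = list(self.psi_names) + list(self.p_names)

        cov = _numerical_cov(nll, res.x)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        return OccupancyMLEResults(
            model=self, params=pd.Series(res.x, index=names),
            bse=pd.Series(bse, index=names), llf=-float(res.fun),
            converged=bool(res.success), fixed_p=fix_p_at, cov=cov,
        )

    # -- Bayesian fit -------------------------------------------------------

    def sample(self, chains: int = 3, adapt: int = 1000, burnin: int = 1000,
               iterations: int = 10000, seed=None, rhat_threshold: float = 1.1,
               target_accept: float = 0.375) -> "OccupancyMCMCResults":
        """Metropolis-within-Gibbs posterior sampling.

        Each sweep draws the latent states z_i from their exact full
        conditional — z_i = 1 whenever the site has a detection, otherwise
        Bernoulli(psi_i q_i / (psi_i q_i + 1 - psi_i)) with
        q_i = (1 - p_i)^{J_i} over unmasked occasions — then updates the
        space-use and detection coefficient blocks by random-walk
        Metropolis.  Proposal scales adapt during the ``adapt`` phase
        toward a 0.30-0.45 acceptance rate; adaptation and burn-in draws
        are discarded.  Retained draws: ``chains x iterations``.
        """
        rng = np.random.default_rng(seed)
        C = int(chains)
        X, W = self.X, self.W
        d, J, any_det = self.detections, self.effort, self.any_det

        beta = rng.normal(0.0, 0.25, size=(C, self.k_psi))
        alpha = rng.normal(0.0, 0.25, size=(C, self.k_p))
        scale_b = np.full(C, 0.3)
        scale_a = np.full(C, 0.3)

        def lp_beta(b, z):
            eta = b @ X.T                      # (C, n)
            # z*eta - log(1+e^eta) is the Bernoulli log-lik under the logit link
            ll = z * eta - np.logaddexp(0.0, eta)
            return ll.sum(axis=1) - 0.5 * np.sum((b / self.prior_sd) ** 2, axis=1)

        def lp_alpha(a, z):
            eta = a @ W.T
            p = expit(eta)
            p = np.clip(p, _PROB_EPS, 1 - _PROB_EPS)
            ll = z * (d * np.log(p) + (J - d) * np.log1p(-p))
            return ll.sum(axis=1) - 0.5 * np.sum((a / self.prior_sd) ** 2, axis=1)

        total = adapt + burnin + iterations
        out_b = np.empty((C, iterations, self.k_psi))
        out_a = np.empty((C, iterations, self.k_p))
        acc_b = np.zeros(C)
        acc_a = np.zeros(C)
        batch = 50
        z = np.where(any_det, 1.0, rng.integers(0, 2, size=(C, X.shape[0])).astype(float))
        cur_lb = lp_beta(beta, z)
        cur_la = lp_alpha(alpha, z)

        for it in range(total):
            # -- Gibbs draw of latent states
            psi = expit(beta @ X.T)
            p = np.clip(expit(alpha @ W.T), _PROB_EPS, 1 - _PROB_EPS)
            q = (1.0 - p) ** J                 # prob of no detection given use
            cond = psi * q / (psi * q + (1.0 - psi))
            z = np.where(any_det, 1.0,
                         (rng.random(cond.shape) < cond).astype(float))
            cur_lb = lp_beta(beta, z)
            cur_la = lp_alpha(alpha, z)

            # -- RW Metropolis on the space-use block
            prop = beta + scale_b[:, None] * rng.standard_normal(beta.shape)
            lp = lp_beta(prop, z)
            acc = np.log(rng.random(C)) < lp - cur_lb
            beta = np.where(acc[:, None], prop, beta)
            cur_lb = np.where(acc, lp, cur_lb)
            acc_b += acc

            # -- RW Metropolis on the detection block
            prop = alpha + scale_a[:, None] * rng.standard_normal(alpha.shape)
            lp = lp_alpha(prop, z)
            acc = np.log(rng.random(C)) < lp - cur_la
            alpha = np.where(acc[:, None], prop, alpha)
            cur_la = np.where(acc, lp, cur_la)
            acc_a += acc

            if it < adapt and (it + 1) % batch == 0:
                scale_b *= np.exp(acc_b / batch - target_accept)
                scale_a *= np.exp(acc_a / batch - target_accept)
                acc_b[:] = 0.0
                acc_a[:] = 0.0
            elif (it + 1) % batch == 0:
                acc_b[:] = 0.0
                acc_a[:] = 0.0

            k = it - adapt - burnin
            if k >= 0:
                out_b[:, k, :] = beta
                out_a[:, k, :] = alpha

        draws = {}
        for j, nm in enumerate(self.psi_names):
            draws[nm] = out_b[:, :, j]
        for j, nm in enumerate(self.p_names):
            draws[nm] = out_a[:, :, j]
        res = OccupancyMCMCResults(
            model=self, coef_draws={"psi": out_b, "p": out_a}, draws=draws,
            seed=seed, settings=dict(chains=C, adapt=adapt, burnin=burnin,
                                     iterations=iterations),
            rhat_threshold=rhat_threshold,
        )
        bad = res.check_convergence()
        if bad:
            warnings.warn(
                "Rhat above threshold for: " + ", ".join(bad), RuntimeWarning)
        return res


def _numerical_cov(nll, x, rel_step: float = 1e-5):
    """Inverse numerical Hessian of the negative log-likelihood."""
    k = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((k, k))
    f0 = nll(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (nll(x + ei) - 2 * f0 + nll(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    nll(x + ei + ej) - nll(x + ei - ej)
                    - nll(x - ei + ej) + nll(x - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full((k, k), np.nan)


@dataclass
class OccupancyMLEResults:
    """Maximum-likelihood estimates with observed-information SEs."""

    model: OccupancyModel
    params: pd.Series
    bse: pd.Series
    llf: float
    converged: bool
    fixed_p: float | None = None
    cov: np.ndarray | None = None

    def predict_psi(self) -> np.ndarray:
        beta = self.params.to_numpy()[: self.model.k_psi]
        return expit(self.model.X @ beta)

    def summary(self) -> pd.DataFrame:
        z = self.params / self.bse.replace(0.0, np.nan)
        return pd.DataFrame({
            "coef": self.params, "se": self.bse,
            "z": z,
            "LCL": self.params - 1.959963984540054 * self.bse,
            "UCL": self.params + 1.959963984540054 * self.bse,
        })


@dataclass
class OccupancyMCMCResults:
    """Posterior draws and Table-style summaries of an occupancy fit."""

    model: OccupancyModel
    coef_draws: dict           # {"psi": (C, N, k_psi), "p": (C, N, k_p)}
    draws: dict                # name -> (C, N)
    seed: object
    settings: dict
    rhat_threshold: float = 1.1
    _summary_cache: dict = field(default_factory=dict, repr=False)

    def derived_draws(self) -> dict:
        """Study-level mean space use and mean detection probability."""
        psi = expit(np.einsum("cnk,ik->cni", self.coef_draws["psi"], self.model.X))
        p = expit(np.einsum("cnk,ik->cni", self.coef_draws["p"], self.model.W))
        return {"psi": psi.mean(axis=2), "p": p.mean(axis=2)}

    def summary(self, level: float = 0.95, derived: bool = True,
                rhat_method: str = "rank") -> pd.DataFrame:
        key = (level, derived, rhat_method)
        if key not in self._summary_cache:
            d = {}
            if derived:
                d.update(self.derived_draws())
            d.update(self.draws)
            self._summary_cache[key] = summarize_draws(
                d, level=level, rhat_method=rhat_method)
        return self._summary_cache[key]

    def check_convergence(self) -> list[str]:
        s = self.summary()
        return list(s.index[s["Rhat"] > self.rhat_threshold])

    @property
    def converged(self) -> bool:
        return not self.check_convergence()

    def predict_psi(self) -> pd.DataFrame:
        """Per-site posterior mean and sd of space-use probability."""
        psi = expit(np.einsum("cnk,ik->cni", self.coef_draws["psi"], self.model.X))
        flat = psi.reshape(-1, psi.shape[2])
        return pd.DataFrame({"psi_mean": flat.mean(axis=0),
                             "psi_sd": flat.std(axis=0, ddof=1)})

    def report(self) -> dict:
        s = self.summary()
        return {
            "seed": self.seed if not isinstance(self.seed, np.integer) else int(self.seed),
            "settings": self.settings,
            "rhat_threshold": self.rhat_threshold,
            "max_rhat": float(s["Rhat"].max()),
            "converged": self.converged,
            "nonconverged": self.check_convergence(),
        }
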