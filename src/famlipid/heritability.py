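"""Polygenic mixed models for family-based heritability.

Gaussian model:  y = X b + g + e,  g ~ N(0, A sigma_g^2),  e ~ N(0, I sigma_e^2),
with A the additive relationship matrix (2 * kinship).  Narrow-sense
family heritability is h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2); because A
comes from the pedigree alone, this quantity absorbs shared-environment
resemblance as well as additive genetics.

Two estimators are provided:

* :func:`fit_polygenic_ml` — (restricted) maximum likelihood via a one-time
  eigendecomposition of A and a 1-D profile likelihood over h2 on [0, 1].
* :func:`gibbs_gaussian` / :func:`gibbs_probit` — Gibbs samplers with
  scaled-inverse-chi-square priors on the variance components; the probit
  sampler handles binary outcomes by latent-liability data augmentation
  (residual liability variance fixed at 1, so h2 = sigma_g^2 / (sigma_g^2 + 1)).

Pedigree relationship matrices are block-diagonal by family; all linear
algebra here exploits that through connected components of A's sparsity
pattern, so cohorts of thousands of individuals stay cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse
from scipy.optimize import minimize_scalar
from scipy.sparse.csgraph import connected_components
from scipy.special import ndtr, ndtri

log = logging.getLogger(__name__)

__all__ = [
    "BlockEigh",
    "VarianceComponents",
    "MCMCConfig",
    "GibbsResult",
    "fit_polygenic_ml",
    "gibbs_gaussian",
    "gibbs_probit",
    "gelman_rubin",
    "summarize_posterior",
]

_EIG_FLOOR = 1e-10
_PSD_TOL = -1e-8


class BlockEigh:
    """Eigendecomposition of a symmetric PSD matrix, block by block.

    Connected components of the sparsity pattern (families, for a pedigree
    relationship matrix) are eigendecomposed separately; rotations to and
    from the eigenbasis are applied per block.
    """

    def __init__(self, A: np.ndarray):
        A = np.asarray(A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be square")
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValueError("A must be symmetric")
        n = A.shape[0]
        n_comp, labels = connected_components(
            sparse.csr_matrix(A != 0.0), directed=False
        )
        self.n = n
        self.blocks: list[np.ndarray] = [
            np.flatnonzero(labels == c) for c in range(n_comp)
        ]
        lam = np.empty(n)
        rows, cols, vals = [], [], []
        for idx in self.blocks:
            w, U = linalg.eigh(A[np.ix_(idx, idx)])
            if w.min() < _PSD_TOL:
                raise ValueError(
                    f"matrix is not positive semi-definite (min eigenvalue {w.min():.3g})"
                )
            lam[idx] = np.clip(w, 0.0, None)
            rr, cc = np.meshgrid(idx, idx, indexing="ij")
            rows.append(rr.ravel())
            cols.append(cc.ravel())
            vals.append(U.ravel())
        self.lam = lam
        # single sparse block-diagonal U keeps rotations cheap on big cohorts
        self._U = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        self._Ut = self._U.T.tocsr()

    def to_eigen(self, v: np.ndarray) -> np.ndarray:
        """U' v (columns handled if v is 2-D)."""
        return self._Ut @ v

    def from_eigen(self, v: np.ndarray) -> np.ndarray:
        """U v."""
        return self._U @ v

    def sqrt_apply(self, z: np.ndarray) -> np.ndarray:
        """L z with L = U diag(sqrt(lambda)); Cov(Lz) = A for z ~ N(0, I)."""
        return self.from_eigen(np.sqrt(self.lam) * z)


@dataclass
class VarianceComponents:
    """Variance decomposition of a Gaussian polygenic fit."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    se_h2: float | None
    loglik: float
    method: str
    beta: np.ndarray
    boundary: bool = False

    @property
    def sigma_p2(self) -> float:
        return self.sigma_g2 + self.sigma_e2


def _profile_loglik(h: float, lam, yt, Xt, reml: bool):
    """Profile (RE)ML log-likelihood over h2, with sigma_p2 and beta profiled out."""
    n = len(yt)
    d = h * lam + (1.0 - h)
    w = 1.0 / d
    XtW = Xt * w[:, None]
    G = Xt.T @ XtW
    beta = np.linalg.solve(G, XtW.T @ yt)
    r = yt - Xt @ beta
    rss = float(np.sum(w * r * r))
    logdet = float(np.sum(np.log(d)))
    if reml:
        p = Xt.shape[1]
        s2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * s2)
            + logdet
            + np.linalg.slogdet(G)[1]
            + (n - p)
        )
    else:
        s2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return float(ll), float(s2), beta


def fit_polygenic_ml(
    y,
    X=None,
    A=None,
    method: str = "REML",
    eig: BlockEigh | None = None,
) -> VarianceComponents:
    """(RE)ML variance components by 1-D profile likelihood over h2.

    ``X`` defaults to an intercept column (appropriate when the trait was
    residualized upstream).  Pass a precomputed :class:`BlockEigh` via
    ``eig`` to amortize the eigendecomposition over traits/scenarios.

    The standard error of h2 comes from the numerical curvature of the
    profile log-likelihood; estimates at the boundary (h2 = 0 or 1) are
    flagged and get no SE.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    # drop collinear columns
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    if not keep.all():
        log.warning("fit_polygenic_ml: dropping %d collinear design columns", (~keep).sum())
        X = X[:, keep]
    if method.upper() not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    reml = method.upper() == "REML"
    if eig is None:
        eig = BlockEigh(np.asarray(A, dtype=float))
    if eig.n != n:
        raise ValueError("dimension mismatch between y and A")
    yt = eig.to_eigen(y)
    Xt = eig.to_eigen(X)

    eps = 1e-9

    def negll(h):
        return -_profile_loglik(h, eig.lam, yt, Xt, reml)[0]

    res = minimize_scalar(negll, bounds=(eps, 1.0 - eps), method="bounded",
                          options={"xatol": 1e-8})
    h_hat = float(res.x)
    # compare against the boundaries explicitly
    cands = [(negll(eps), eps), (negll(1.0 - eps), 1.0 - eps), (res.fun, h_hat)]
    best = min(cands, key=lambda t: t[0])
    h_hat = best[1]
    ll, s2, beta = _profile_loglik(h_hat, eig.lam, yt, Xt, reml)

    boundary = h_hat <= 2 * eps or h_hat >= 1.0 - 2 * eps
    se = None
    if not boundary:
        step = min(1e-4, h_hat / 2, (1 - h_hat) / 2)
        d2 = (negll(h_hat + step) - 2 * negll(h_hat) + negll(h_hat - step)) / step**2
        if d2 > 0:
            se = float(1.0 / np.sqrt(d2))
    if boundary:
        h_hat = float(np.clip(round(h_hat), 0.0, 1.0))
        log.warning("fit_polygenic_ml: h2 estimate at boundary (%g)", h_hat)
    return VarianceComponents(
        sigma_g2=float(h_hat * s2),
        sigma_e2=float((1.0 - h_hat) * s2),
        h2=float(h_hat),
        se_h2=se,
        loglik=float(ll),
        method=method.upper(),
        beta=beta,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# Gibbs samplers


@dataclass
class MCMCConfig:
    """Gibbs schedule.  ``retained`` samples per chain are kept after
    burn-in at the given thinning interval."""

    n_iter: int = 50_000
    burn_in: int = 25_000
    thin: int = 25
    n_chains: int = 2
    seed: int = 0
    prior_df: float = 5.0
    prior_scale: float | None = None  # default: half the response variance

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class GibbsResult:
    """Posterior samples: ``chains`` has shape (n_chains, retained, n_params)."""

    chains: np.ndarray
    names: list[str]
    cfg: MCMCConfig
    model: str = "gaussian"

    def per_chain(self, name: str) -> np.ndarray:
        return self.chains[:, :, self.names.index(name)]

    def samples(self, name: str) -> np.ndarray:
        return self.per_chain(name).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        m, s, p = self.chains.shape
        df = pd.DataFrame(self.chains.reshape(m * s, p), columns=self.names)
        df.insert(0, "chain", np.repeat(np.arange(m), s))
        df.insert(1, "draw", np.tile(np.arange(s), m))
        return df


def _draw_scaled_inv_chi2(rng, df, scale_ss):
    """sigma2 ~ scaled-inv-chi2: scale_ss / chisq(df)."""
    return scale_ss / rng.chisquare(df)


def _gibbs_core(
    yt,
    Xt,
    eig: BlockEigh | None,
    cfg: MCMCConfig,
    rng: np.random.Generator,
    var_y: float,
    fix_sigma_e: bool = False,
    latent_update=None,
):
    """Shared Gibbs loop in the eigenbasis of A.

    ``latent_update(k_eigen, beta, iteration) -> new response in eigenbasis``
    hooks in the probit data augmentation; for the Gaussian model it is None
    and ``yt`` is fixed.  With ``fix_sigma_e`` the residual variance stays 1.
    """
    n = len(yt)
    p = Xt.shape[1] if Xt is not None else 0
    nu0 = cfg.prior_df
    s0 = cfg.prior_scale if cfg.prior_scale is not None else 0.5 * var_y
    prior_ss = nu0 * s0

    if eig is not None:
        lam = eig.lam
        pos = lam > _EIG_FLOOR
        lam_pos = lam[pos]
        m_pos = int(pos.sum())
    else:
        pos = np.zeros(0, dtype=bool)
        lam_pos = np.zeros(0)
        m_pos = 0

    if p:
        XtX = Xt.T @ Xt
        cF = linalg.cho_factor(XtX)
        Lbeta = linalg.cholesky(np.linalg.inv(XtX), lower=True)

    sigma_g2 = max(0.5 * var_y, 1e-6)
    sigma_e2 = 1.0 if fix_sigma_e else max(0.5 * var_y, 1e-6)
    beta = np.zeros(p)
    k = np.zeros(n)
    resp = yt.copy()

    out = np.empty((cfg.retained, p + 3))
    kept = 0
    for it in range(1, cfg.n_iter + 1):
        if latent_update is not None:
            resp = latent_update(k, beta)
        # fixed effects
        if p:
            r = resp - k
            mean = linalg.cho_solve(cF, Xt.T @ r)
            beta = mean + np.sqrt(sigma_e2) * (Lbeta @ rng.standard_normal(p))
        # genetic values (eigenbasis: independent scalar conditionals)
        if n and m_pos:
            r = resp - (Xt @ beta if p else 0.0)
            prec = 1.0 / sigma_e2 + 1.0 / (lam_pos * sigma_g2)
            var = 1.0 / prec
            mean = var * r[pos] / sigma_e2
            k = np.zeros(n)
            k[pos] = mean + np.sqrt(var) * rng.standard_normal(m_pos)
        # variance components
        ss_g = float(np.sum(k[pos] ** 2 / lam_pos)) if m_pos else 0.0
        sigma_g2 = _draw_scaled_inv_chi2(rng, nu0 + m_pos, prior_ss + ss_g)
        if not fix_sigma_e:
            resid = resp - (Xt @ beta if p else 0.0) - k
            ss_e = float(resid @ resid)
            sigma_e2 = _draw_scaled_inv_chi2(rng, nu0 + n, prior_ss + ss_e)
        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            h2 = sigma_g2 / (sigma_g2 + sigma_e2)
            out[kept, :p] = beta
            out[kept, p] = sigma_g2
            out[kept, p + 1] = sigma_e2
            out[kept, p + 2] = h2
            kept += 1
    return out[:kept]


def gibbs_gaussian(y, X=None, A=None, cfg: MCMCConfig | None = None) -> GibbsResult:
    """Gibbs sampler for the Gaussian polygenic model.

    Full conditionals: normal for the fixed effects (flat prior) and for the
    genetic values (independent scalars in the eigenbasis of A), and
    scaled-inverse-chi-square for both variance components (prior df 5,
    prior scale half the response variance by default).  With no data rows
    the sampler draws from the prior.  ``h2`` is recorded per retained
    sample as sigma_g2 / (sigma_g2 + sigma_e2).
    """
    cfg = cfg or MCMCConfig()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n:
        if X is None:
            X = np.ones((n, 1))
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        eig = BlockEigh(np.asarray(A, dtype=float))
        if eig.n != n:
            raise ValueError("dimension mismatch between y and A")
        yt = eig.to_eigen(y)
        Xt = eig.to_eigen(X)
        var_y = float(np.var(y))
        p = X.shape[1]
    else:
        eig, yt, Xt, var_y, p = None, y, None, 1.0, 0

    names = [f"beta_{j}" for j in range(p)] + ["sigma_g2", "sigma_e2", "h2"]
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chains = np.stack(
        [
            _gibbs_core(yt, Xt, eig, cfg, np.random.default_rng(s), var_y)
            for s in seeds
        ]
    )
    return GibbsResult(chains=chains, names=names, cfg=cfg, model="gaussian")


def gibbs_probit(status, X=None, A=None, cfg: MCMCConfig | None = None) -> GibbsResult:
    """Probit liability-threshold model via latent-variable augmentation.

    Each observed binary status constrains a latent liability
    z_i ~ N(eta_i, 1) to be positive (affected) or negative; the liability
    then feeds the Gaussian machinery with residual variance fixed at 1, so
    the heritability on the liability scale is sigma_g2 / (sigma_g2 + 1).
    The default prior scale is half the variance of the observed 0/1
    response (hence at most 0.125), keeping the genetic-variance prior
    weak relative to the fixed unit residual.
    """
    cfg = cfg or MCMCConfig()
    s = np.asarray(status).astype(bool)
    n = len(s)
    if n == 0 or s.all() or (~s).all():
        raise ValueError("probit model needs both affected and unaffected individuals")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    eig = BlockEigh(np.asarray(A, dtype=float))
    if eig.n != n:
        raise ValueError("dimension mismatch between status and A")
    Xt = eig.to_eigen(X)
    p = X.shape[1]
    names = [f"beta_{j}" for j in range(p)] + ["sigma_g2", "sigma_e2", "h2"]

    tiny = 1e-12

    def run_chain(seed_seq):
        rng = np.random.default_rng(seed_seq)

        def latent_update(k_eigen, beta):
            eta = X @ beta + eig.from_eigen(k_eigen)
            u = rng.uniform(tiny, 1.0 - tiny, size=n)
            p0 = ndtr(-eta)  # P(z < 0)
            q = np.where(s, p0 + u * (1.0 - p0), u * p0)
            z = eta + ndtri(np.clip(q, tiny, 1.0 - tiny))
            return eig.to_eigen(np.clip(z, -12.0, 12.0))

        return _gibbs_core(
            np.zeros(n),
            Xt,
            eig,
            cfg,
            rng,
            var_y=float(np.var(s.astype(float))),
            fix_sigma_e=True,
            latent_update=latent_update,
        )

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chains = np.stack([run_chain(s_) for s_ in seeds])
    return GibbsResult(chains=chains, names=names, cfg=cfg, model="probit")


# ---------------------------------------------------------------------------
# diagnostics


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor sqrt(((n-1)/n * W + B/n) / W).

    ``chains``: array-like of shape (m, n) with m >= 2 chains of equal
    length n >= 10.  W is the mean within-chain variance; B/n the variance
    of chain means.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need >= 2 equal-length chains")
    m, n = c.shape
    if n < 10:
        raise ValueError("chains too short for a PSRF")
    W = float(np.mean(np.var(c, axis=1, ddof=1)))
    if W == 0:
        raise ValueError("zero within-chain variance")
    B = n * float(np.var(np.mean(c, axis=1), ddof=1))
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def summarize_posterior(result: GibbsResult) -> pd.DataFrame:
    """Posterior mean, sd, equal-tailed 95% interval and PSRF per parameter."""
    rows = []
    for j, name in enumerate(result.names):
        flat = result.chains[:, :, j].reshape(-1)
        lo, hi = np.percentile(flat, [2.5, 97.5])
        try:
            psrf = gelman_rubin(result.chains[:, :, j])
        except ValueError:
            psrf = np.nan
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)) if len(flat) > 1 else 0.0,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "psrf": psrf,
            }
        )
    return pd.DataFrame(rows, columns=["parameter", "mean", "sd", "ci_low", "ci_high", "psrf"])
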