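"""Bayesian animal models for ordinal and continuous traits.

The animal model is a mixed model in which every individual carries an
additive-genetic effect (breeding value) whose covariance across individuals
is ``V_A · A``, with ``A`` the pedigree additive-relationship matrix.  For a
four-grade ordinal trait such as a radiographic hip score the model is a
probit *threshold* model: a continuous latent liability with unit residual
variance is cut at ordered thresholds into the observed grades, and the
variance components live on that latent scale.

Samplers
--------
All models are fitted by Gibbs sampling with liability augmentation
(truncated-normal draws given the observed grade).  Breeding values and
permanent-environment effects are drawn *jointly* per iteration: the
permanent-environment block and the fixed effects are eliminated analytically
(their conditional precisions are diagonal / low-dimensional), and the
remaining genetic system  S = λ A⁻¹ + D  is sampled exactly via the
perturbation identity  a = S⁻¹(b + u),  u ~ N(0, S),  where a draw from
N(0, A⁻¹) costs one sparse mat-vec because Henderson's inverse factors as
A⁻¹ = Wᵀ D_m⁻¹ W  (W maps an individual to itself minus half its parents).
The solve uses Jacobi-preconditioned conjugate gradients; no matrix is ever
factorised, so a ~3000-individual pedigree costs a few milliseconds per
iteration.

Variance components get conjugate scaled-inverse-χ² (univariate) or
inverse-Wishart (bivariate) updates, each interweaved with a non-centred
(ASIS) rescale; free cutpoints are slice-sampled on their liability-marginal
conditionals, and a translation interweaving keeps the intercept and the
mean genetic level mixing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import cg
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart

from .pedigree import (
    Pedigree,
    inbreeding_coefficients,
    mendelian_sampling_variance,
)

__all__ = [
    "VarianceComponents",
    "GeneticCovariance",
    "PosteriorChain",
    "fit_threshold_animal_model",
    "fit_gaussian_animal_model",
    "fit_bivariate_animal_model",
    "h2_latent",
    "h2_observed_scale",
    "genetic_correlation",
    "mcmc_diagnostics",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of a univariate fit (latent scale for ordinal)."""

    v_a: float
    v_pe: float = 0.0
    v_r: float = 1.0
    cutpoints: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.v_a < 0 or self.v_pe < 0 or self.v_r < 0:
            raise ValueError("variance components must be non-negative")
        cp = self.cutpoints
        if any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError("cutpoints must be strictly increasing")

    @property
    def v_p(self) -> float:
        return self.v_a + self.v_pe + self.v_r


@dataclass(frozen=True)
class GeneticCovariance:
    """2x2 additive-genetic (co)variance matrix for a bivariate fit."""

    g: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        if g.shape != (2, 2) or not np.allclose(g, g.T):
            raise ValueError("G must be symmetric 2x2")
        if np.linalg.eigvalsh(g).min() < -1e-10:
            raise ValueError("G must be positive semi-definite")

    @property
    def r_g(self) -> float:
        denom = np.sqrt(self.g[0, 0] * self.g[1, 1])
        return float(self.g[0, 1] / denom) if denom > 0 else np.nan


class ChainDivergenceError(RuntimeError):
    """Chains failed the convergence gate (R-hat too large)."""


@dataclass
class PosteriorChain:
    """Posterior draws (post burn-in, thinned) from one or more chains.

    ``chains`` holds one DataFrame per chain with one column per monitored
    parameter.  Summaries are posterior means with central 95% credible
    intervals, computed on the pooled draws.
    """

    chains: list[pd.DataFrame]
    burn_in: int
    thin: int
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def draws(self) -> pd.DataFrame:
        return pd.concat(self.chains, ignore_index=True)

    def summary(self, params: Sequence[str] | None = None) -> pd.DataFrame:
        df = self.draws
        params = list(params) if params is not None else list(df.columns)
        rows = []
        for p in params:
            x = df[p].to_numpy()
            lo, hi = np.quantile(x, [0.025, 0.975])
            rows.append({"parameter": p, "mean": x.mean(),
                         "ci_2.5%": lo, "ci_97.5%": hi})
        return pd.DataFrame(rows).set_index("parameter")

    def diagnostics(self, params: Sequence[str] | None = None) -> pd.DataFrame:
        return mcmc_diagnostics(self.chains, params)

    def check_convergence(self, rhat_max: float = 1.1) -> None:
        if len(self.chains) < 2:
            return
        diag = self.diagnostics()
        bad = diag[diag["rhat"] > rhat_max]
        if len(bad):
            raise ChainDivergenceError(
                f"R-hat > {rhat_max} for: {list(bad.index)}")


# ---------------------------------------------------------------------------
# heritability on latent and observed scales


def h2_latent(vc: VarianceComponents | pd.DataFrame) -> float | np.ndarray:
    """Latent-scale heritability h² = V_A / (V_A + V_PE + V_R).

    For ordinal threshold fits V_R is the fixed unit residual.  Accepts a
    single :class:`VarianceComponents` or a draws DataFrame with columns
    ``v_a``, ``v_pe`` (optional) and ``v_r`` (optional, default 1); in the
    latter case the formula is applied *per draw* (summarising afterwards is
    the caller's job -- the mean of ratios is not the ratio of means).
    """
    if isinstance(vc, VarianceComponents):
        return vc.v_a / vc.v_p
    v_a = vc["v_a"].to_numpy()
    v_pe = vc["v_pe"].to_numpy() if "v_pe" in vc else 0.0
    v_r = vc["v_r"].to_numpy() if "v_r" in vc else 1.0
    return v_a / (v_a + v_pe + v_r)


def _gh_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    t, w = np.polynomial.hermite.hermgauss(n_nodes)
    return t, w / np.sqrt(np.pi)


def _category_funcs(cutpoints: np.ndarray, ell: np.ndarray, n_cat: int
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """psi, psi' and conditional variance of the ordinal response at ℓ.

    ``cutpoints`` are the K-1 finite thresholds; the residual sd is 1.
    """
    ks = np.arange(n_cat)
    # cdf at each finite threshold, padded with 0 / 1 at ∓∞
    z = cutpoints[:, None] - ell[None, :]               # (K-1, L)
    cdf = ndtr(z)
    pdf = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
    upper = np.vstack([cdf, np.ones_like(ell)])          # Φ(γ_{k+1} − ℓ)
    lower = np.vstack([np.zeros_like(ell), cdf])         # Φ(γ_k − ℓ)
    probs = upper - lower                                # (K, L)
    pdf_up = np.vstack([pdf, np.zeros_like(ell)])
    pdf_lo = np.vstack([np.zeros_like(ell), pdf])
    psi = ks @ probs
    dpsi = ks @ (pdf_lo - pdf_up)
    var_cond = (ks**2) @ probs - psi**2
    return psi, dpsi, var_cond


def h2_observed_scale(v_a, v_pe, cutpoints, mu, *, n_categories: int = 4,
                      n_nodes: int = 48):
    """Transform latent-scale variance components to the observed ordinal scale.

    For each posterior draw the expected response ``ψ(ℓ)`` and its derivative
    are integrated over the latent non-residual liability
    ``ℓ ~ N(μ, V_A + V_PE)`` by Gauss–Hermite quadrature (unit residual inside
    ψ).  The observed-scale phenotypic variance is ``Var ψ(ℓ) + E v(ℓ)`` with
    ``v`` the conditional categorical variance, and the additive part is
    ``V_A · (E ψ′(ℓ))²``; their ratio is the data-scale h².

    Parameters are scalars or aligned arrays of draws; ``cutpoints`` has one
    row per draw (K-1 strictly increasing thresholds).  Returns an array (or
    scalar) of data-scale h² values.
    """
    v_a = np.atleast_1d(np.asarray(v_a, dtype=float))
    v_pe = np.broadcast_to(np.asarray(v_pe, dtype=float), v_a.shape)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), v_a.shape)
    cp = np.atleast_2d(np.asarray(cutpoints, dtype=float))
    if cp.shape[0] == 1:
        cp = np.broadcast_to(cp, (v_a.size, cp.shape[1]))
    if np.any(np.diff(cp, axis=1) <= 0):
        raise ValueError("cutpoints must be strictly increasing")
    t, w = _gh_nodes(n_nodes)
    out = np.empty(v_a.size)
    for d in range(v_a.size):
        sd = np.sqrt(v_a[d] + v_pe[d])
        ell = mu[d] + np.sqrt(2.0) * sd * t
        psi, dpsi, vc = _category_funcs(cp[d], ell, n_categories)
        e_psi = w @ psi
        var_psi = w @ psi**2 - e_psi**2
        v_p_obs = var_psi + w @ vc
        v_a_obs = v_a[d] * (w @ dpsi) ** 2
        out[d] = v_a_obs / v_p_obs
    return out if out.size > 1 else float(out[0])


def genetic_correlation(g_draws: pd.DataFrame | np.ndarray) -> dict:
    """Posterior r_G = COV_A / √(V_A1 · V_A2), per draw then summarised.

    Draws with a non-positive genetic variance are excluded (their count is
    reported).  Input: DataFrame with columns ``g11, g12, g22`` or an
    (n, 3) array in that order.
    """
    if isinstance(g_draws, pd.DataFrame):
        g11 = g_draws["g11"].to_numpy()
        g12 = g_draws["g12"].to_numpy()
        g22 = g_draws["g22"].to_numpy()
    else:
        arr = np.asarray(g_draws, dtype=float)
        g11, g12, g22 = arr[:, 0], arr[:, 1], arr[:, 2]
    ok = (g11 > 0) & (g22 > 0)
    r = g12[ok] / np.sqrt(g11[ok] * g22[ok])
    if r.size == 0:
        raise ValueError("no draws with positive genetic variances")
    lo, hi = np.quantile(r, [0.025, 0.975])
    return {"mean": float(r.mean()), "ci_2.5%": float(lo),
            "ci_97.5%": float(hi), "n_excluded": int((~ok).sum()),
            "draws": r}


# ---------------------------------------------------------------------------
# diagnostics


def mcmc_diagnostics(chains: Sequence[pd.DataFrame],
                     params: Sequence[str] | None = None) -> pd.DataFrame:
    """Split R-hat and effective sample size per parameter (via ArviZ).

    Requires ≥ 2 chains for R-hat; constant chains yield NaN with a warning.
    """
    if len(chains) < 2:
        raise ValueError("need at least 2 chains for R-hat")
    cols = list(params) if params is not None else list(chains[0].columns)
    import arviz as az

    data = {c: np.stack([ch[c].to_numpy() for ch in chains]) for c in cols}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=data)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = {}
    for c in cols:
        r = float(rhat[c].values)
        e = float(ess[c].values)
        if np.ptp(data[c]) == 0:
            warnings.warn(f"parameter {c!r} is constant; R-hat undefined")
            r, e = np.nan, np.nan
        rows[c] = {"rhat": r, "ess": e}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# shared sampler machinery


class _PedigreeOps:
    """Sparse pedigree operators shared by the samplers.

    ``W = I − ½P`` (individual minus half each known parent) and the
    Mendelian-sampling variances ``d`` give Henderson's sparse inverse
    ``A⁻¹ = Wᵀ diag(1/d) W``; a draw from N(0, A⁻¹) is ``Wᵀ (z/√d)``.
    """

    def __init__(self, ped: Pedigree) -> None:
        n = len(ped)
        F = inbreeding_coefficients(ped)
        self.d = mendelian_sampling_variance(ped, F)
        rows = [np.arange(n)]
        cols = [np.arange(n)]
        vals = [np.ones(n)]
        for parent in (ped.sire, ped.dam):
            has = parent >= 0
            rows.append(np.where(has)[0])
            cols.append(parent[has])
            vals.append(np.full(has.sum(), -0.5))
        W = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n)).tocsr()
        self.W = W
        self.Wt = W.T.tocsr()
        self.d_isqrt = 1.0 / np.sqrt(self.d)
        self.Ainv = (W.T @ sparse.diags(1.0 / self.d) @ W).tocsr()
        self.n = n

        ones = np.ones(n)
        self._W1_over_d = (W @ ones) / self.d
        self.one_Ainv_one = float(self._W1_over_d @ (W @ ones))

    def draw_prior(self, rng: np.random.Generator, scale: float = 1.0
                   ) -> np.ndarray:
        """One draw from N(0, scale · A⁻¹)."""
        z = rng.standard_normal(self.n)
        return np.sqrt(scale) * (self.Wt @ (z * self.d_isqrt))

    def one_Ainv(self, a: np.ndarray) -> float:
        """1ᵀ A⁻¹ a (used by the intercept/genetic-mean interweaving step)."""
        return float(self._W1_over_d @ (self.W @ a))

    def quad_form(self, a: np.ndarray) -> np.ndarray:
        """aᵀ A⁻¹ b for columns of ``a``: returns the Gram matrix."""
        wa = (self.W @ a) * (self.d_isqrt[:, None] if a.ndim == 2
                             else self.d_isqrt)
        return wa.T @ wa if a.ndim == 2 else float(wa @ wa)


def _solve_spd(S: sparse.spmatrix, b: np.ndarray, x0: np.ndarray | None = None
               ) -> np.ndarray:
    M = sparse.diags(1.0 / S.diagonal())
    x, info = cg(S, b, x0=x0, M=M, rtol=1e-10, atol=0.0, maxiter=10_000)
    if info != 0:  # pragma: no cover - CG on SPD systems converges
        raise RuntimeError(f"conjugate gradients failed (info={info})")
    return x


def _trunc_norm(rng: np.random.Generator, mean: np.ndarray, lo: np.ndarray,
                hi: np.ndarray) -> np.ndarray:
    """Vectorised truncated-normal(mean, 1) draws on [lo, hi]."""
    a = ndtr(lo - mean)
    b = ndtr(hi - mean)
    u = a + (b - a) * rng.random(mean.shape)
    tiny = 1e-12
    return mean + ndtri(np.clip(u, tiny, 1 - tiny))


def _scaled_inv_chi2(rng: np.random.Generator, df: float, scale_sum: float
                     ) -> float:
    """Draw from scaled-inv-χ²: scale_sum / χ²_df."""
    return scale_sum / rng.chisquare(df)


def _slice_1d(logf, x0: float, rng: np.random.Generator, *,
              lo: float = -np.inf, hi: float = np.inf, w: float = 1.0,
              max_steps: int = 30) -> float:
    """Univariate slice sampler (stepping out + shrinkage, Neal 2003)."""
    y = logf(x0) + np.log(rng.random())
    u = rng.random()
    left = x0 - w * u
    right = left + w
    for _ in range(max_steps):
        if left <= lo or logf(left) <= y:
            break
        left -= w
    for _ in range(max_steps):
        if right >= hi or logf(right) <= y:
            break
        right += w
    left, right = max(left, lo), min(right, hi)
    for _ in range(200):
        x1 = rng.uniform(left, right)
        if logf(x1) >= y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # pragma: no cover - shrinkage virtually always succeeds


def _sample_cutpoints(cuts: np.ndarray, eta: np.ndarray, y: np.ndarray,
                      cat_idx: list[np.ndarray],
                      rng: np.random.Generator) -> np.ndarray:
    """Slice-sample each free cutpoint given η (residual marginalised).

    Cutpoint k only enters the likelihood of the two adjacent categories, so
    each conditional is univariate on (γ_{k-1}, γ_{k+1}) and needs no
    proposal tuning.
    """
    n_cut = len(cuts)
    cuts = cuts.copy()
    for k in range(1, n_cut):  # cut 0 fixed at 0 for identification
        below = cat_idx[k]      # records in category k: upper bound is γ_k
        above = cat_idx[k + 1]  # records in category k+1: lower bound is γ_k
        eta_b, eta_a = eta[below], eta[above]
        lo_b = (cuts[k - 1] if k >= 1 else -np.inf) - eta_b
        hi_a = (cuts[k + 1] if k + 1 < n_cut else np.inf) - eta_a

        cdf_lo_b = ndtr(lo_b)
        cdf_hi_a = ndtr(hi_a)

        def logf(g: float) -> float:
            pb = np.clip(ndtr(g - eta_b) - cdf_lo_b, 1e-300, None)
            pa = np.clip(cdf_hi_a - ndtr(g - eta_a), 1e-300, None)
            return float(np.log(pb).sum() + np.log(pa).sum())

        lo = cuts[k - 1]
        hi = cuts[k + 1] if k + 1 < n_cut else np.inf
        cuts[k] = _slice_1d(logf, cuts[k], rng, lo=lo, hi=hi, w=0.1)
    return cuts


def _asis_rescale(resid: np.ndarray, tt: np.ndarray, v0: float, v_r: float,
                  nu: float, s2: float, rng: np.random.Generator) -> float:
    """Non-centred (ASIS) redraw of a variance component's scale.

    Given the effect in non-centred form (effect = s · tilde, tilde fixed),
    the conditional of s is a truncated Gaussian in the likelihood times the
    scaled-inv-χ²(ν, s²) prior mapped through v = s²; one slice-sampling
    update on s interweaves with the conjugate centred draw and breaks the
    slow scale coupling.  ``tt`` is tilde expanded to record level.
    """
    sum_t2 = float(tt @ tt)
    if sum_t2 <= 0:
        return v0
    sum_lt = float(resid @ tt)
    s0 = np.sqrt(max(v0, 1e-12))

    def logf(s: float) -> float:
        v = s * s
        loglik = -(0.5 * v * sum_t2 - s * sum_lt) / v_r
        logpr = -(nu / 2 + 1) * np.log(v) - nu * s2 / (2 * v) + np.log(2 * s)
        return loglik + logpr

    s1 = _slice_1d(logf, s0, rng, lo=1e-8, hi=np.inf, w=max(s0 / 3, 0.02))
    return s1 * s1


def _ordinal_loglik(eta: np.ndarray, y: np.ndarray, cuts: np.ndarray) -> float:
    """Log-likelihood of ordinal outcomes with liability marginalised."""
    upper = np.concatenate([cuts, [np.inf]])
    lower = np.concatenate([[-np.inf], cuts])
    p = ndtr(upper[y] - eta) - ndtr(lower[y] - eta)
    return float(np.log(np.clip(p, 1e-300, None)).sum())


def _repeat_correlation(y: np.ndarray, indiv: np.ndarray) -> float | None:
    """Correlation between the first two records of each individual, or
    None when fewer than 30 individuals have repeated records."""
    order = np.argsort(indiv, kind="stable")
    ys, ids = y[order], indiv[order]
    first_of = np.r_[True, ids[1:] != ids[:-1]]
    second = np.r_[False, (ids[1:] == ids[:-1]) & first_of[:-1]]
    firsts = ys[np.flatnonzero(second) - 1]
    seconds = ys[second]
    if len(firsts) < 30 or np.std(firsts) == 0 or np.std(seconds) == 0:
        return None
    return float(np.corrcoef(firsts, seconds)[0, 1])


def _init_cutpoints(y: np.ndarray, n_cat: int) -> np.ndarray:
    freq = np.bincount(y, minlength=n_cat) + 0.5
    cum = np.cumsum(freq)[:-1] / freq.sum()
    cuts = ndtri(cum) * 1.5
    return cuts - cuts[0]  # identification: first cutpoint at 0


def _design(df: pd.DataFrame, fixed: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for f in fixed:
        v = df[f]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            levels = sorted(v.unique())
            for lev in levels[1:]:
                cols.append((v == lev).to_numpy(float))
        else:
            x = v.to_numpy(float)
            s = x.std()
            cols.append((x - x.mean()) / (s if s > 0 else 1.0))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# univariate sampler


def _univariate_gibbs(y: np.ndarray, X: np.ndarray, indiv: np.ndarray,
                      ops: _PedigreeOps, *, ordinal: bool, include_pe: bool,
                      n_cat: int, n_iter: int, burn_in: int, thin: int,
                      rng: np.random.Generator,
                      prior_nu: float, prior_s2: float,
                      prior_nu_pe: float, prior_s2_pe: float,
                      prior_nu_r: float, prior_s2_r: float) -> pd.DataFrame:
    m, p = X.shape
    n = ops.n
    counts = np.bincount(indiv, minlength=n).astype(float)

    XtX = X.T @ X + 1e-10 * np.eye(p)
    XtX_chol = np.linalg.cholesky(np.linalg.inv(XtX))

    beta = np.zeros(p)
    a = np.zeros(n)
    pe = np.zeros(n)
    # start variance components near a moment estimate of the liability
    # variance so burn-in is short: for repeated ordinal records the
    # within-individual score correlation rho approximates
    # (V_A+V_PE)/(V_A+V_PE+1) (attenuated by the coarse scale)
    if ordinal:
        v_tot0 = 2.0
        rho = _repeat_correlation(y, indiv)
        if rho is not None:
            v_tot0 = max(np.clip(rho, 0.05, 0.95) / (1 - min(rho, 0.95)),
                         0.5)
        v_a = v_tot0 / 2 if include_pe else v_tot0
        v_pe = v_tot0 / 2 if include_pe else 0.0
    else:
        v_a = prior_s2
        v_pe = prior_s2_pe if include_pe else 0.0
    v_r = 1.0 if ordinal else max(prior_s2_r, np.var(y.astype(float)))

    if ordinal:
        cuts = _init_cutpoints(y, n_cat)
        cat_idx = [np.where(y == c)[0] for c in range(n_cat)]
        liab = _trunc_norm(
            rng, np.zeros(m),
            np.concatenate([[-np.inf], cuts])[y],
            np.concatenate([cuts, [np.inf]])[y])
    else:
        liab = y.astype(float)
        cuts = np.zeros(0)

    keep: list[dict] = []
    x_prev = None
    for it in range(n_iter):
        # --- cutpoints (slice, residual marginalised given η), then
        #     liabilities given the updated cutpoints
        if ordinal:
            eta = X @ beta + a[indiv] + (pe[indiv] if include_pe else 0.0)
            if n_cat > 2:
                cuts = _sample_cutpoints(cuts, eta, y, cat_idx, rng)
            lo = np.concatenate([[-np.inf], cuts])[y]
            hi = np.concatenate([cuts, [np.inf]])[y]
            liab = _trunc_norm(rng, eta, lo, hi)

        # --- joint (a, pe) block given beta: eliminate the diagonal pe block
        resid = liab - X @ beta
        b_a = np.bincount(indiv, weights=resid, minlength=n) / v_r
        lam_a = 1.0 / max(v_a, 1e-8)
        if include_pe:
            lam_pe = 1.0 / max(v_pe, 1e-8)
            shrink = lam_pe / (lam_pe + counts / v_r)
            diag = (counts / v_r) * shrink
            b_eff = b_a * shrink
        else:
            diag = counts / v_r
            b_eff = b_a
        S = (ops.Ainv * lam_a + sparse.diags(diag)).tocsr()
        u = ops.draw_prior(rng, lam_a) + np.sqrt(diag) * rng.standard_normal(n)
        a = _solve_spd(S, b_eff + u, x0=x_prev)
        x_prev = a
        if include_pe:
            prec_pe = lam_pe + counts / v_r
            mean_pe = (b_a - (counts / v_r) * a) / prec_pe
            pe = mean_pe + rng.standard_normal(n) / np.sqrt(prec_pe)

        # --- fixed effects (flat prior)
        r2 = liab - a[indiv] - (pe[indiv] if include_pe else 0.0)
        bhat = np.linalg.solve(XtX, X.T @ r2)
        beta = bhat + np.sqrt(v_r) * (XtX_chol @ rng.standard_normal(p))

        # --- interweaving: translate mass between the intercept and the mean
        #     genetic / permanent-environment level (the likelihood is
        #     invariant along this direction; only the random-effect priors
        #     constrain it, giving an exact Gaussian conditional for the
        #     shift).  Without this the intercept mixes very slowly.
        q = ops.one_Ainv_one
        delta = rng.normal(ops.one_Ainv(a) / q, np.sqrt(v_a / q))
        a = a - delta
        beta[0] += delta
        if include_pe:
            delta = rng.normal(pe.mean(), np.sqrt(v_pe / n))
            pe = pe - delta
            beta[0] += delta

        # --- variance components: conjugate scaled-inv-chi² draw, then an
        #     interweaved non-centred rescale (ASIS) to decouple scale and
        #     effect vector
        ss_a = ops.quad_form(a)
        v_a = _scaled_inv_chi2(rng, prior_nu + n, ss_a + prior_nu * prior_s2)
        resid_a = liab - X @ beta - (pe[indiv] if include_pe else 0.0)
        s_old = np.sqrt(max(v_a, 1e-12))
        v_a_new = _asis_rescale(resid_a, (a / s_old)[indiv], v_a, v_r,
                                prior_nu, prior_s2, rng)
        a = a * np.sqrt(v_a_new / v_a)
        v_a = v_a_new
        if include_pe:
            v_pe = _scaled_inv_chi2(
                rng, prior_nu_pe + n, pe @ pe + prior_nu_pe * prior_s2_pe)
            resid_pe = liab - X @ beta - a[indiv]
            s_old = np.sqrt(max(v_pe, 1e-12))
            v_pe_new = _asis_rescale(resid_pe, (pe / s_old)[indiv], v_pe, v_r,
                                     prior_nu_pe, prior_s2_pe, rng)
            pe = pe * np.sqrt(v_pe_new / v_pe)
            v_pe = v_pe_new
        if not ordinal:
            res = r2 - X @ beta
            v_r = _scaled_inv_chi2(
                rng, prior_nu_r + m, res @ res + prior_nu_r * prior_s2_r)

        if it >= burn_in and (it - burn_in) % thin == 0:
            row = {"v_a": v_a, "v_r": v_r, "mu": float(np.mean(X @ beta))}
            if include_pe:
                row["v_pe"] = v_pe
            for k, c in enumerate(cuts[1:], start=2):
                row[f"cut{k}"] = c
            for k in range(p):
                row[f"beta{k}"] = beta[k]
            keep.append(row)
    return pd.DataFrame(keep)


def _prepare_univariate(data: pd.DataFrame, pedigree: Pedigree,
                        response: str, fixed: Sequence[str]):
    if not set(data["id"]).issubset(set(pedigree.ids)):
        missing = sorted(set(data["id"]) - set(pedigree.ids))[:5]
        raise ValueError(f"phenotyped ids missing from pedigree: {missing}")
    indiv = data["id"].map(pedigree.index).to_numpy(np.int64)
    X = _design(data, fixed)
    y = data[response].to_numpy()
    return y, X, indiv


def fit_threshold_animal_model(
        data: pd.DataFrame, pedigree: Pedigree, *,
        response: str = "score",
        fixed: Sequence[str] = ("sex", "age_days"),
        include_pe: bool = True,
        n_categories: int = 4,
        n_iter: int = 3000, burn_in: int = 1000, thin: int = 2,
        n_chains: int = 2, seed: int = 0,
        prior_nu: float = 1.0, prior_s2: float = 0.5,
        prior_nu_pe: float = 1.0, prior_s2_pe: float = 0.5,
        check: bool = True, rhat_max: float = 1.1) -> PosteriorChain:
    """Ordinal (probit threshold) animal model for a 0..K-1 graded trait.

    ``data`` needs columns ``id`` (pedigree member; may repeat for repeated
    measures, e.g. one row per hip), the ordinal ``response``, and the
    ``fixed`` covariates (numeric covariates are standardised internally;
    string columns are dummy-coded).  Identification fixes the residual
    liability variance at 1 and the first cutpoint at 0, with a free
    intercept.  Returns draws of ``v_a``, ``v_pe`` (if requested), the free
    cutpoints, fixed effects, and ``mu`` (mean fixed-effect predictor, used
    by the observed-scale transform).

    With unrelated individuals and no repeated measures V_A and V_PE are only
    jointly identified; their sum remains interpretable, the split follows
    the priors (scaled-inv-χ²(ν, s²), weakly informative by default).
    """
    y, X, indiv = _prepare_univariate(data, pedigree, response, fixed)
    y = y.astype(np.int64)
    if y.min() < 0 or y.max() > n_categories - 1:
        raise ValueError("response outside 0..K-1")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 observed categories")
    ops = _PedigreeOps(pedigree)
    chains = []
    for c in range(n_chains):
        rng = np.random.default_rng([seed, c])
        chains.append(_univariate_gibbs(
            y, X, indiv, ops, ordinal=True, include_pe=include_pe,
            n_cat=n_categories, n_iter=n_iter, burn_in=burn_in, thin=thin,
            rng=rng, prior_nu=prior_nu, prior_s2=prior_s2,
            prior_nu_pe=prior_nu_pe, prior_s2_pe=prior_s2_pe,
            prior_nu_r=0.0, prior_s2_r=0.0))
    out = PosteriorChain(chains, burn_in, thin, seed,
                         meta={"model": "threshold", "response": response,
                               "include_pe": include_pe})
    if check and n_chains >= 2:
        out.check_convergence(rhat_max)
    return out


def fit_gaussian_animal_model(
        data: pd.DataFrame, pedigree: Pedigree, *,
        response: str = "residual_mass",
        fixed: Sequence[str] = ("sex",),
        include_pe: bool = False,
        n_iter: int = 3000, burn_in: int = 1000, thin: int = 2,
        n_chains: int = 2, seed: int = 0,
        prior_nu: float = 1.0, prior_s2: float | None = None,
        prior_nu_r: float = 1.0, prior_s2_r: float | None = None,
        check: bool = True, rhat_max: float = 1.1) -> PosteriorChain:
    """Gaussian animal model (e.g. for residual body mass), V_R estimated."""
    y, X, indiv = _prepare_univariate(data, pedigree, response, fixed)
    y = y.astype(float)
    vy = float(np.var(y))
    s2 = vy / 2 if prior_s2 is None else prior_s2
    s2r = vy / 2 if prior_s2_r is None else prior_s2_r
    ops = _PedigreeOps(pedigree)
    chains = []
    for c in range(n_chains):
        rng = np.random.default_rng([seed, c])
        chains.append(_univariate_gibbs(
            y, X, indiv, ops, ordinal=False, include_pe=include_pe,
            n_cat=0, n_iter=n_iter, burn_in=burn_in, thin=thin, rng=rng,
            prior_nu=prior_nu, prior_s2=s2,
            prior_nu_pe=1.0, prior_s2_pe=s2 / 2,
            prior_nu_r=prior_nu_r, prior_s2_r=s2r))
    out = PosteriorChain(chains, burn_in, thin, seed,
                         meta={"model": "gaussian", "response": response,
                               "include_pe": include_pe})
    if check and n_chains >= 2:
        out.check_convergence(rhat_max)
    return out


# ---------------------------------------------------------------------------
# bivariate sampler


def _bivariate_gibbs(ys, Xs, indivs, kinds, ops: _PedigreeOps, *,
                     n_cats, include_pe, n_iter, burn_in, thin, rng,
                     iw_df: float, iw_scale: np.ndarray,
                     prior_nu_r: float, prior_s2_r: float,
                     prior_nu_pe: float, prior_s2_pe: float) -> pd.DataFrame:
    n = ops.n
    G = np.array(iw_scale, dtype=float) / max(iw_df - 3.0, 1.0) \
        if iw_df > 3 else np.eye(2) * 0.5
    a = np.zeros((n, 2))
    pes = [np.zeros(n), np.zeros(n)]
    v_pe = [prior_s2_pe, prior_s2_pe]
    betas = [np.zeros(X.shape[1]) for X in Xs]
    v_r = [1.0, 1.0]
    liabs, cuts, cat_idxs = [], [], []
    XtXs, Xchols = [], []
    for t in range(2):
        X = Xs[t]
        XtX = X.T @ X + 1e-10 * np.eye(X.shape[1])
        XtXs.append(XtX)
        Xchols.append(np.linalg.cholesky(np.linalg.inv(XtX)))
        if kinds[t] == "ordinal":
            c0 = _init_cutpoints(ys[t], n_cats[t])
            cuts.append(c0)
            cat_idxs.append([np.where(ys[t] == c)[0]
                             for c in range(n_cats[t])])
            liabs.append(_trunc_norm(
                rng, np.zeros(len(ys[t])),
                np.concatenate([[-np.inf], c0])[ys[t]],
                np.concatenate([c0, [np.inf]])[ys[t]]))
        else:
            cuts.append(np.zeros(0))
            cat_idxs.append([])
            liabs.append(ys[t].astype(float))
            v_r[t] = max(float(np.var(ys[t])) / 2, 1e-6)

    counts = [np.bincount(indivs[t], minlength=n).astype(float)
              for t in range(2)]
    # moment-based starting scale for ordinal traits with repeated records
    for t in range(2):
        if kinds[t] != "ordinal":
            continue
        rho = _repeat_correlation(ys[t], indivs[t])
        if rho is not None:
            v_tot0 = max(np.clip(rho, 0.05, 0.95) / (1 - min(rho, 0.95)),
                         0.5)
            if include_pe[t]:
                v_pe[t] = v_tot0 / 2
                G[t, t] = max(G[t, t], v_tot0 / 2)
            else:
                G[t, t] = max(G[t, t], v_tot0)
    keep: list[dict] = []
    x_prev = None
    for it in range(n_iter):
        # liabilities and cutpoints per ordinal trait
        for t in range(2):
            if kinds[t] != "ordinal":
                continue
            eta = (Xs[t] @ betas[t] + a[indivs[t], t]
                   + (pes[t][indivs[t]] if include_pe[t] else 0.0))
            if n_cats[t] > 2:
                cuts[t] = _sample_cutpoints(cuts[t], eta, ys[t],
                                            cat_idxs[t], rng)
            lo = np.concatenate([[-np.inf], cuts[t]])[ys[t]]
            hi = np.concatenate([cuts[t], [np.inf]])[ys[t]]
            liabs[t] = _trunc_norm(rng, eta, lo, hi)

        # joint genetic block: S = G⁻¹⊗A⁻¹ + diag, with each trait's
        # permanent-environment block (diagonal) eliminated by Schur
        # complement exactly as in the univariate sampler
        Gi = np.linalg.inv(G)
        diags, beffs = [], []
        for t in range(2):
            b_t = np.bincount(indivs[t],
                              weights=(liabs[t] - Xs[t] @ betas[t]) / v_r[t],
                              minlength=n)
            d_t = counts[t] / v_r[t]
            if include_pe[t]:
                lam_pe = 1.0 / max(v_pe[t], 1e-8)
                shrink = lam_pe / (lam_pe + d_t)
                d_t = d_t * shrink
                b_t = b_t * shrink
            diags.append(d_t)
            beffs.append(b_t)
        diag = np.concatenate(diags)
        b = np.concatenate(beffs)
        S = sparse.bmat(
            [[ops.Ainv * Gi[0, 0], ops.Ainv * Gi[0, 1]],
             [ops.Ainv * Gi[1, 0], ops.Ainv * Gi[1, 1]]],
            format="csr") + sparse.diags(diag)
        Lg = np.linalg.cholesky(Gi)
        z = rng.standard_normal((n, 2))
        u_g = (ops.Wt @ (z * ops.d_isqrt[:, None])) @ Lg.T
        u = u_g.T.ravel() + np.sqrt(diag) * rng.standard_normal(2 * n)
        sol = _solve_spd(S.tocsr(), b + u, x0=x_prev)
        x_prev = sol
        a = sol.reshape(2, n).T

        # permanent-environment effects given a
        for t in range(2):
            if not include_pe[t]:
                continue
            lam_pe = 1.0 / max(v_pe[t], 1e-8)
            b_t = np.bincount(indivs[t],
                              weights=(liabs[t] - Xs[t] @ betas[t]) / v_r[t],
                              minlength=n)
            prec = lam_pe + counts[t] / v_r[t]
            mean = (b_t - (counts[t] / v_r[t]) * a[:, t]) / prec
            pes[t] = mean + rng.standard_normal(n) / np.sqrt(prec)

        # fixed effects and gaussian residual variances
        for t in range(2):
            r2 = (liabs[t] - a[indivs[t], t]
                  - (pes[t][indivs[t]] if include_pe[t] else 0.0))
            bhat = np.linalg.solve(XtXs[t], Xs[t].T @ r2)
            betas[t] = bhat + np.sqrt(v_r[t]) * (
                Xchols[t] @ rng.standard_normal(len(bhat)))
            if kinds[t] == "gaussian":
                res = r2 - Xs[t] @ betas[t]
                v_r[t] = _scaled_inv_chi2(
                    rng, prior_nu_r + len(res),
                    res @ res + prior_nu_r * prior_s2_r)

        # interweaving: shift each trait's intercept against its genetic
        # (and permanent-environment) mean; exact Gaussian conditionals,
        # likelihood invariant along the shift
        q = ops.one_Ainv_one
        for t in range(2):
            lin = sum(Gi[t, s] * ops.one_Ainv(a[:, s]) for s in range(2))
            prec = Gi[t, t] * q
            delta = rng.normal(lin / prec, 1.0 / np.sqrt(prec))
            a[:, t] -= delta
            betas[t][0] += delta
            if include_pe[t]:
                delta = rng.normal(pes[t].mean(), np.sqrt(v_pe[t] / n))
                pes[t] = pes[t] - delta
                betas[t][0] += delta

        # G | a ~ inverse-Wishart; V_PE conjugate + ASIS rescale
        Sa = ops.quad_form(a)
        G = invwishart.rvs(df=iw_df + n, scale=iw_scale + Sa, random_state=rng)
        for t in range(2):
            if not include_pe[t]:
                continue
            v_pe[t] = _scaled_inv_chi2(
                rng, prior_nu_pe + n,
                pes[t] @ pes[t] + prior_nu_pe * prior_s2_pe)
            resid_pe = liabs[t] - Xs[t] @ betas[t] - a[indivs[t], t]
            s_old = np.sqrt(max(v_pe[t], 1e-12))
            v_new = _asis_rescale(resid_pe, (pes[t] / s_old)[indivs[t]],
                                  v_pe[t], v_r[t], prior_nu_pe, prior_s2_pe,
                                  rng)
            pes[t] = pes[t] * np.sqrt(v_new / v_pe[t])
            v_pe[t] = v_new

        if it >= burn_in and (it - burn_in) % thin == 0:
            row = {"g11": G[0, 0], "g12": G[0, 1], "g22": G[1, 1],
                   "v_r1": v_r[0], "v_r2": v_r[1],
                   "r_g": G[0, 1] / np.sqrt(G[0, 0] * G[1, 1])}
            for t in range(2):
                if include_pe[t]:
                    row[f"t{t+1}_v_pe"] = v_pe[t]
                for k, c in enumerate(cuts[t][1:], start=2):
                    row[f"t{t+1}_cut{k}"] = c
                row[f"t{t+1}_mu"] = float(np.mean(Xs[t] @ betas[t]))
            keep.append(row)
    return pd.DataFrame(keep)


def fit_bivariate_animal_model(
        data1: pd.DataFrame, data2: pd.DataFrame, pedigree: Pedigree, *,
        responses: tuple[str, str] = ("score", "residual_mass"),
        kinds: tuple[str, str] = ("ordinal", "gaussian"),
        fixed: tuple[Sequence[str], Sequence[str]] = (("sex",), ("sex",)),
        n_categories: tuple[int, int] = (4, 4),
        include_pe: tuple[bool, bool] = (False, False),
        n_iter: int = 3000, burn_in: int = 1000, thin: int = 2,
        n_chains: int = 2, seed: int = 0,
        iw_df: float = 3.0, iw_scale: np.ndarray | None = None,
        prior_nu_r: float = 1.0, prior_s2_r: float = 0.1,
        prior_nu_pe: float = 1.0, prior_s2_pe: float = 0.5,
        check: bool = True, rhat_max: float = 1.1) -> PosteriorChain:
    """Bivariate animal model partitioning covariance between two traits.

    Each trait brings its own record table (``id``, response, fixed
    covariates) -- the two sets of individuals may differ (e.g. body mass
    measured on a subset).  Genetic effects are bivariate with covariance
    ``G ⊗ A`` and an inverse-Wishart(ν, scale) prior on G; ordinal traits
    have their residual fixed at 1, Gaussian residual variances are
    estimated, and the residual cross-covariance is fixed at 0 (with one
    record per individual per trait it is weakly identified on the liability
    scale).  Draws include ``g11, g12, g22`` and the per-draw ``r_g``.
    """
    if iw_scale is None:
        iw_scale = np.eye(2)
    ys, Xs, indivs = [], [], []
    for data, resp, kind, fx in zip((data1, data2), responses, kinds, fixed):
        y, X, ind = _prepare_univariate(data, pedigree, resp, fx)
        ys.append(y.astype(np.int64) if kind == "ordinal" else y.astype(float))
        Xs.append(X)
        indivs.append(ind)
    ops = _PedigreeOps(pedigree)
    chains = []
    for c in range(n_chains):
        rng = np.random.default_rng([seed, 7 + c])
        chains.append(_bivariate_gibbs(
            ys, Xs, indivs, kinds, ops, n_cats=n_categories,
            include_pe=include_pe,
            n_iter=n_iter, burn_in=burn_in, thin=thin, rng=rng,
            iw_df=iw_df, iw_scale=np.asarray(iw_scale, float),
            prior_nu_r=prior_nu_r, prior_s2_r=prior_s2_r,
            prior_nu_pe=prior_nu_pe, prior_s2_pe=prior_s2_pe))
    out = PosteriorChain(chains, burn_in, thin, seed,
                         meta={"model": "bivariate", "responses": responses,
                               "kinds": kinds})
    if check and n_chains >= 2:
        out.check_convergence(rhat_max)
    return out
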