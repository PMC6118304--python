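"""Bayesian linear mixed model fit by an eigen-rotated Gibbs sampler.

The model is

    y = mu 1 + Xf beta + sum_r u_r + eps,
    u_r ~ N(0, sigma2_r K_r),   eps ~ N(0, sigma2_e I),

with each K_r a known symmetric PSD observation-level kernel and
homoscedastic errors.  Each random term is rotated through the truncated
eigen-decomposition K = U S U': writing b = U'u, the full conditional of
each rotated coefficient b_i is an independent univariate normal

    b_i | .  ~  N( s_i v d_i / (s_i v + ve),  s_i v ve / (s_i v + ve) ),

where d = U' (partial residual), v = sigma2_r, ve = sigma2_e — so a scan
costs two thin matrix-vector products per term instead of a joint
multivariate draw.  Variances carry scaled-inverse-chi-squared priors, so
their full conditionals are

    sigma2 | .  =  (sum_sq + nu * Sc) / chi2(nu + n_eff),

with sum_sq = sum b_i^2 / s_i (n_eff = number of retained eigenvalues)
for a genetic term and the residual sum of squares (n_eff = N) for the
error.  Block-diagonal kernels are eigen-decomposed and rotated per
diagonal block, never materialising the full decomposition.  Missing
phenotypes are handled by data augmentation: each scan imputes them from
their conditional predictive distribution, which is what produces
predictions for unobserved records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve

from ._exceptions import DegenerateDataError, InputError, NumericalError
from .ge_models import KernelSet, PhenotypeTable
from .kernels import Kernel

__all__ = [
    "DEFAULT_EIGEN_TOL",
    "EigenBasis",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSummary",
    "eigen_decompose",
    "default_priors",
    "sample_rotated_effects",
    "sample_variance",
    "sample_location",
    "gibbs_fit",
    "predict",
]

#: eigenvalues below this are treated as numerical noise and dropped
DEFAULT_EIGEN_TOL = 1e-10


@dataclass(frozen=True)
class EigenBasis:
    """Truncated eigen-decomposition of a kernel, stored per block.

    ``blocks`` holds ``(offset, U, s)`` triples: ``U`` has orthonormal
    columns, ``s`` the retained (> tol) eigenvalues of the diagonal block
    starting at row ``offset``.  A dense kernel has a single block at
    offset 0.  Zero blocks contribute nothing (rank 0 is legal).
    """

    blocks: tuple[tuple[int, np.ndarray, np.ndarray], ...]
    n: int
    tol: float

    @property
    def rank(self) -> int:
        return sum(len(s) for _, _, s in self.blocks)

    def reconstruct(self) -> np.ndarray:
        """Rebuild ``U S U'`` (testing aid)."""
        K = np.zeros((self.n, self.n))
        for off, U, s in self.blocks:
            m = U.shape[0]
            K[off:off + m, off:off + m] = (U * s) @ U.T
        return K


def eigen_decompose(K: Kernel, tol: float = DEFAULT_EIGEN_TOL) -> EigenBasis:
    """Eigen-decompose a kernel, truncating eigenvalues below ``tol``.

    Block-diagonal kernels are decomposed one diagonal block at a time —
    for m equal blocks this is m times an (N/m)-sized problem rather than
    one N-sized one, the main source of speed-up for GxE deviation terms.
    """
    blocks: list[tuple[int, np.ndarray, np.ndarray]] = []
    if K.structure == "block_diagonal":
        offsets, sizes = K.block_offsets, K.block_sizes
    else:
        offsets, sizes = (0,), (K.n,)
    for off, size in zip(offsets, sizes):
        sub = K.values[off:off + size, off:off + size]
        w, V = np.linalg.eigh(sub)
        keep = w > tol
        if keep.any():
            # ascending order from eigh; store descending for readability
            w, V = w[keep][::-1], V[:, keep][:, ::-1]
            blocks.append((off, np.ascontiguousarray(V), w))
    return EigenBasis(blocks=tuple(blocks), n=K.n, tol=tol)


@dataclass(frozen=True)
class PriorSpec:
    """Scaled-inverse-chi-squared hyperparameters for all variances.

    ``Sc_u`` maps each random-term name to its prior scale.  Degrees of
    freedom default to 3 for every term — small enough to be weakly
    informative while keeping the prior mean finite (it exists only for
    nu > 2).
    """

    nu_u: float
    Sc_u: dict[str, float]
    nu_e: float
    Sc_e: float
    R2: float = 0.5

    def __post_init__(self) -> None:
        if self.nu_u <= 2 or self.nu_e <= 2:
            raise InputError("degrees of freedom must exceed 2")
        if self.Sc_e <= 0 or any(v <= 0 for v in self.Sc_u.values()):
            raise InputError("prior scales must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Gibbs sampler settings: total scans, burn-in, thinning, seed."""

    ite: int = 1000
    burn: int = 200
    thin: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn >= self.ite:
            raise InputError("burn-in must be smaller than the iteration count")
        if self.thin < 1:
            raise InputError("thinning interval must be >= 1")
        if self.n_retained < 2:
            raise InputError(
                f"only {self.n_retained} retained samples; increase ite or "
                "decrease burn/thin"
            )

    @property
    def n_retained(self) -> int:
        return (self.ite - self.burn) // self.thin


def default_priors(
    y_obs: np.ndarray,
    kset: KernelSet,
    bases: dict[str, EigenBasis] | None = None,
    R2: float = 0.5,
    nu_u: float = 3.0,
    nu_e: float = 3.0,
) -> PriorSpec:
    """Data-driven prior scales that partition var(y) according to ``R2``.

    The residual scale is set so the prior mode of sigma2_e is
    ``(1 − R2) var(y)``; each of the q random terms gets a scale whose
    prior mode is ``R2 var(y) / q`` after accounting for its kernel's
    mean diagonal (the mode of a scaled-inverse-chi-squared is
    ``nu Sc / (nu + 2)``).  This is a partition heuristic in the style of
    Bayesian whole-genome regression software; see docs/methods.md.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_obs = y_obs[~np.isnan(y_obs)]
    if len(y_obs) < 2:
        raise DegenerateDataError("need at least 2 observed values for priors")
    vy = float(np.var(y_obs, ddof=1))
    if vy <= 0:
        raise DegenerateDataError("observed phenotypes are constant")
    if not 0 < R2 < 1:
        raise InputError(f"R2 must be in (0, 1), got {R2}")
    q = len(kset)
    Sc_u: dict[str, float] = {}
    for name, kern in kset.entries.items():
        mean_diag = float(np.mean(np.diag(kern.values)))
        if mean_diag <= 0:
            raise DegenerateDataError(f"kernel {name!r} has non-positive mean diagonal")
        Sc_u[name] = vy * (R2 / q) * (nu_u + 2.0) / (nu_u * mean_diag)
    Sc_e = vy * (1.0 - R2) * (nu_e + 2.0) / nu_e
    return PriorSpec(nu_u=nu_u, Sc_u=Sc_u, nu_e=nu_e, Sc_e=Sc_e, R2=R2)


def sample_rotated_effects(
    resid: np.ndarray,
    basis: EigenBasis,
    var_u: float,
    var_e: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one random-effect vector in the rotated space.

    Returns ``(b, u)``: the rotated coefficients (concatenated over
    blocks, length = basis.rank) and the effect ``u = U b`` on the
    observation scale (length N).  With ``var_u = 0`` the prior puts all
    mass at zero, so both are exactly zero.
    """
    if var_u < 0 or var_e <= 0:
        raise InputError("variances must satisfy var_u >= 0, var_e > 0")
    if len(resid) != basis.n:
        raise InputError(f"residual length {len(resid)} != basis dimension {basis.n}")
    u = np.zeros(basis.n)
    if var_u == 0.0 or basis.rank == 0:
        return np.zeros(basis.rank), u
    b_parts = []
    for off, U, s in basis.blocks:
        d = U.T @ resid[off:off + U.shape[0]]
        denom = s * var_u + var_e
        mean = s * var_u * d / denom
        sd = np.sqrt(s * var_u * var_e / denom)
        b = mean + sd * rng.standard_normal(len(s))
        u[off:off + U.shape[0]] = U @ b
        b_parts.append(b)
    return np.concatenate(b_parts), u


def sample_variance(
    sum_sq: float,
    n_eff: int,
    nu: float,
    Sc: float,
    rng: np.random.Generator,
) -> float:
    """One scaled-inverse-chi-squared draw: ``(sum_sq + nu Sc) / chi2(nu + n_eff)``."""
    if sum_sq < 0:
        raise InputError("sum of squares must be nonnegative")
    if nu + n_eff <= 0:
        raise InputError("nu + n_eff must be positive")
    return float((sum_sq + nu * Sc) / rng.chisquare(nu + n_eff))


def sample_location(
    resid_plus: np.ndarray,
    XF: np.ndarray | None,
    var_e: float,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """Joint draw of intercept and fixed effects from their normal conditional.

    ``resid_plus`` is the working response with all random effects
    removed.  With design Xt = [1, XF] the draw is from
    N(ls-solution, var_e (Xt'Xt)^{-1}); flat priors on (mu, beta).
    Xt must have full column rank.
    """
    n = len(resid_plus)
    if XF is None:
        Xt = np.ones((n, 1))
    else:
        XF = np.asarray(XF, dtype=float)
        if XF.ndim == 1:
            XF = XF[:, None]
        if XF.shape[0] != n:
            raise InputError("fixed-effect design rows != record count")
        Xt = np.column_stack([np.ones(n), XF])
    Q = Xt.T @ Xt
    if np.linalg.matrix_rank(Q) < Q.shape[0]:
        raise NumericalError(
            "[1, XF] is rank deficient; the fixed-effect design must be full rank"
        )
    L = np.linalg.cholesky(Q)
    mean = cho_solve((L, True), Xt.T @ resid_plus)
    # cov = var_e Q^{-1}; draw = mean + sqrt(var_e) L^{-T} z
    z = rng.standard_normal(Q.shape[0])
    draw = mean + np.sqrt(var_e) * np.linalg.solve(L.T, z)
    return float(draw[0]), draw[1:]


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior means/SDs, fitted values and stored chains from one fit."""

    mu: float
    beta: np.ndarray
    varu: dict[str, tuple[float, float]]
    varE: tuple[float, float]
    u_hat: dict[str, np.ndarray]
    y_hat: np.ndarray
    chains: pd.DataFrame
    env: np.ndarray = field(repr=False, default=None)
    gid: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    @property
    def n_retained(self) -> int:
        return len(self.chains)


def gibbs_fit(
    pheno: PhenotypeTable,
    kset: KernelSet,
    XF: np.ndarray | None = None,
    config: MCMCConfig | None = None,
    priors: PriorSpec | None = None,
    tol: float = DEFAULT_EIGEN_TOL,
    debug: bool = False,
    verbose: bool = False,
) -> PosteriorSummary:
    """Fit the Bayesian GxE mixed model by the rotated Gibbs sampler.

    Each scan, in fixed RNG order: (1) impute every missing phenotype as
    its current fitted value plus N(0, var_e) noise; (2) draw (mu, beta)
    jointly; (3) for each random term in kernel-set order, form its
    partial residual, draw the rotated effects, then its variance;
    (4) draw the residual variance from the full residual.  Post-burn-in
    samples at the thinning interval are retained; chains of the
    intercept and all variances are stored, and effect vectors are
    summarised by their running posterior means.

    Returns a :class:`PosteriorSummary`; ``y_hat`` is the posterior mean
    of ``mu + XF beta + sum_r u_r``, which for unobserved records is the
    posterior mean of their imputed values.
    """
    config = config or MCMCConfig()
    y = np.asarray(pheno.y, dtype=float).copy()
    N = len(y)
    if kset.n_records != N:
        raise InputError("kernel set and phenotype table disagree on record count")
    obs = pheno.observed
    if not obs.any():
        raise InputError("all phenotypes are missing; nothing to fit")
    miss = ~obs

    bases = {name: eigen_decompose(k, tol) for name, k in kset.entries.items()}
    if priors is None:
        priors = default_priors(y[obs], kset, bases)
    names = list(kset.names)

    rng = np.random.default_rng(config.seed)

    # initial state: intercept at the observed mean, effects at zero,
    # variances at their prior scales
    mu = float(np.mean(y[obs]))
    if XF is not None:
        XFa = np.asarray(XF, dtype=float)
        if XFa.ndim == 1:
            XFa = XFa[:, None]
    else:
        XFa = None
    beta = np.zeros(0 if XFa is None else XFa.shape[1])
    u = {name: np.zeros(N) for name in names}
    var_u = {name: priors.Sc_u[name] for name in names}
    var_e = priors.Sc_e

    y_work = y.copy()
    y_work[miss] = mu

    n_ret = config.n_retained
    chain_rows = np.zeros((n_ret, 2 + len(names)))
    kept_iter = np.zeros(n_ret, dtype=int)
    mu_sum = 0.0
    beta_sum = np.zeros_like(beta)
    u_sum = {name: np.zeros(N) for name in names}
    yhat_sum = np.zeros(N)
    kept = 0

    fixed_part = np.zeros(N)
    for it in range(1, config.ite + 1):
        total_u = sum(u.values()) if names else np.zeros(N)
        if XFa is not None:
            fixed_part = XFa @ beta
        fitted = mu + fixed_part + total_u
        if miss.any():
            y_work[miss] = fitted[miss] + np.sqrt(var_e) * rng.standard_normal(
                int(miss.sum())
            )

        mu, beta = sample_location(y_work - total_u, XFa, var_e, rng)
        if XFa is not None:
            fixed_part = XFa @ beta

        resid = y_work - mu - fixed_part - total_u
        for name in names:
            resid += u[name]
            b, u_new = sample_rotated_effects(
                resid, bases[name], var_u[name], var_e, rng
            )
            r_eff = bases[name].rank
            sum_sq = 0.0
            if r_eff:
                s_all = np.concatenate([s for _, _, s in bases[name].blocks])
                sum_sq = float(np.sum(b * b / s_all))
            var_u[name] = sample_variance(
                sum_sq, r_eff, priors.nu_u, priors.Sc_u[name], rng
            )
            u[name] = u_new
            resid -= u_new

        if debug:
            total_u = sum(u.values()) if names else np.zeros(N)
            check = y_work - mu - fixed_part - total_u
            assert np.allclose(check, resid, atol=1e-10), "residual bookkeeping broken"

        var_e = sample_variance(float(resid @ resid), N, priors.nu_e, priors.Sc_e, rng)

        if verbose and it % 100 == 0:
            vs = " ".join(f"{n}={var_u[n]:.4g}" for n in names)
            print(f"iter {it:>6d}  varE={var_e:.4g}  {vs}")

        if it > config.burn and (it - config.burn) % config.thin == 0:
            chain_rows[kept, 0] = mu
            chain_rows[kept, 1] = var_e
            for j, name in enumerate(names):
                chain_rows[kept, 2 + j] = var_u[name]
            kept_iter[kept] = it
            mu_sum += mu
            beta_sum += beta
            for name in names:
                u_sum[name] += u[name]
            yhat_sum += mu + fixed_part + sum(u.values())
            kept += 1

    assert kept == n_ret
    chains = pd.DataFrame(
        chain_rows, columns=["mu", "varE"] + [f"varu_{n}" for n in names]
    )
    chains.insert(0, "iteration", kept_iter)

    varu_summary = {
        name: (
            float(chains[f"varu_{name}"].mean()),
            float(chains[f"varu_{name}"].std(ddof=1)),
        )
        for name in names
    }
    return PosteriorSummary(
        mu=mu_sum / n_ret,
        beta=beta_sum / n_ret,
        varu=varu_summary,
        varE=(float(chains["varE"].mean()), float(chains["varE"].std(ddof=1))),
        u_hat={name: u_sum[name] / n_ret for name in names},
        y_hat=yhat_sum / n_ret,
        chains=chains,
        env=pheno.env.copy(),
        gid=pheno.gid.copy(),
        y=pheno.y.copy(),
    )


def predict(fit: PosteriorSummary, env: str | None = None) -> pd.DataFrame:
    """Tabulate fitted/predicted values, optionally for one environment.

    Unobserved records carry the posterior means of their imputed values.
    """
    df = pd.DataFrame(
        {
            "env": fit.env,
            "gid": fit.gid,
            "observed": ~np.isnan(fit.y),
            "y": fit.y,
            "y_hat": fit.y_hat,
        }
    )
    if env is not None:
        if env not in set(fit.env):
            raise InputError(f"environment {env!r} not present in the fit")
        df = df[df["env"] == env].reset_index(drop=True)
    return df
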