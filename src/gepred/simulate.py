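"""Synthetic marker and multi-environment phenotype generation.

Fixtures mirror the structure of a maize multi-environment trial at
reduced scale: a shared panel of genotypes scored on biallelic 0/1/2
markers and evaluated in m environments (default 4), with phenotypes
generated under the same linear mixed model the sampler fits —
``y = mu + sum_r u_r + eps`` with ``u_r ~ N(0, sigma2_r K_r)`` and
homoscedastic noise — so every fit can be checked against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import InputError
from .ge_models import KernelSet, PhenotypeTable
from .kernels import MarkerMatrix
from .sampler import eigen_decompose

__all__ = [
    "SimTruth",
    "simulate_markers",
    "design_table",
    "simulate_phenotypes",
    "recode_dominance",
]


@dataclass(frozen=True)
class SimTruth:
    """Ground truth behind one simulated phenotype vector."""

    variances: dict[str, float]
    var_e: float
    mu_true: float
    effects: dict[str, np.ndarray]
    y_full: np.ndarray
    seed: int


def simulate_markers(
    n_gen: int,
    p: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> MarkerMatrix:
    """Simulate a 0/1/2 biallelic marker matrix.

    Marker k gets an allele frequency ``f_k`` uniform in ``maf_range``
    and genotype codes Binomial(2, f_k) per individual (Hardy-Weinberg,
    no linkage disequilibrium).  Monomorphic columns are resampled so the
    output never contains them.
    """
    if n_gen < 2 or p < 1:
        raise InputError("need n_gen >= 2 and p >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise InputError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    rng = np.random.default_rng(seed)
    f = rng.uniform(lo, hi, size=p)
    X = rng.binomial(2, f, size=(n_gen, p)).astype(float)
    # resample monomorphic columns until every marker segregates
    while True:
        mono = np.flatnonzero(np.all(X == X[0], axis=0))
        if len(mono) == 0:
            break
        X[:, mono] = rng.binomial(2, f[mono], size=(n_gen, len(mono)))
    return MarkerMatrix(
        X,
        genotype_ids=tuple(f"g{i + 1}" for i in range(n_gen)),
        marker_ids=tuple(f"m{k + 1}" for k in range(p)),
    )


def design_table(
    genotype_ids,
    n_env: int = 4,
    drop_fraction: float = 0.0,
    seed: int = 0,
) -> PhenotypeTable:
    """Lay out a multi-environment trial design with unknown phenotypes.

    Every genotype appears once in each of ``n_env`` environments
    (labelled ``env1..envm``); ``drop_fraction > 0`` removes that share
    of records at random to emulate unbalanced trials (never emptying an
    environment).  The returned table has all-NaN phenotypes — pass it
    through :func:`simulate_phenotypes` or fill in real data.
    """
    if n_env < 1:
        raise InputError("need at least one environment")
    if not 0 <= drop_fraction < 1:
        raise InputError("drop_fraction must be in [0, 1)")
    gids = [str(g) for g in genotype_ids]
    envs = [f"env{j + 1}" for j in range(n_env)]
    env_col = [e for e in envs for _ in gids]
    gid_col = [g for _ in envs for g in gids]
    keep = np.ones(len(env_col), dtype=bool)
    if drop_fraction > 0:
        rng = np.random.default_rng(seed)
        n_drop = int(round(drop_fraction * len(env_col)))
        # protect one record per environment so no block vanishes
        protected = {j * len(gids) for j in range(n_env)}
        candidates = np.array(sorted(set(range(len(env_col))) - protected))
        drop = rng.choice(candidates, size=min(n_drop, len(candidates)), replace=False)
        keep[drop] = False
    env_arr = np.asarray(env_col)[keep]
    gid_arr = np.asarray(gid_col)[keep]
    return PhenotypeTable(env=env_arr, gid=gid_arr, y=np.full(keep.sum(), np.nan))


def simulate_phenotypes(
    kset: KernelSet,
    variances: dict[str, float],
    var_e: float,
    mu_true: float = 0.0,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[PhenotypeTable, SimTruth]:
    """Draw phenotypes from the mixed model implied by a kernel set.

    Each random effect is drawn as ``u_r = U sqrt(S) z`` from the
    truncated eigen-factorisation of ``sigma2_r K_r`` (block by block for
    block-diagonal kernels), noise is i.i.d. N(0, var_e), and
    ``round(missing_fraction * N)`` records are masked as unobserved.
    ``variances`` must name exactly the kernel-set entries.
    """
    if set(variances) != set(kset.names):
        raise InputError(
            f"variance names {sorted(variances)} do not match kernel names "
            f"{sorted(kset.names)}"
        )
    if any(v < 0 for v in variances.values()) or var_e < 0:
        raise InputError("variances must be nonnegative")
    if not 0 <= missing_fraction < 1:
        raise InputError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    N = kset.n_records
    effects: dict[str, np.ndarray] = {}
    y = np.full(N, float(mu_true))
    for name in kset.names:
        sigma2 = variances[name]
        u = np.zeros(N)
        if sigma2 > 0:
            basis = eigen_decompose(kset[name])
            for off, U, s in basis.blocks:
                z = rng.standard_normal(len(s))
                u[off:off + U.shape[0]] = U @ (np.sqrt(sigma2 * s) * z)
        effects[name] = u
        y += u
    if var_e > 0:
        y += np.sqrt(var_e) * rng.standard_normal(N)
    y_masked = y.copy()
    n_miss = int(round(missing_fraction * N))
    if n_miss:
        masked = rng.choice(N, size=n_miss, replace=False)
        y_masked[masked] = np.nan
    pheno = PhenotypeTable(env=kset.env.copy(), gid=kset.gid.copy(), y=y_masked)
    truth = SimTruth(
        variances=dict(variances), var_e=float(var_e), mu_true=float(mu_true),
        effects=effects, y_full=y, seed=seed,
    )
    return pheno, truth


def recode_dominance(X: MarkerMatrix) -> MarkerMatrix:
    """Recode 0/1/2 additive dosages to a 0/1 heterozygote indicator.

    Homozygous codes (0 and 2) map to 0, heterozygotes stay 1 — the input
    for a dominance relationship matrix.
    """
    vals = X.values.copy()
    vals[vals == 2] = 0
    return MarkerMatrix(vals, X.genotype_ids, X.marker_ids)
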