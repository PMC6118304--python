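"""Multi-environment variance-covariance structures for GxE models.

Given a long-format phenotype table (one record per environment x
genotype) and one or more genotype-level kernels, these builders expand
each kernel to the observation level and assemble the random-effect
covariance structure of the chosen model:

============  ==========================================================
model         random terms (observation-level covariances)
============  ==========================================================
``SM``        single environment: Zu K Zu'
``MM``        main genotypic effect across environments: Zu K Zu'
``MDs``       MM plus a single-variance GxE deviation
              (Zu K Zu') ∘ Ze Ze'  (Hadamard product, block-diagonal)
``MDe``       MM plus one environment-specific deviation kernel per
              environment (zero except that environment's block)
============  ==========================================================

Adding a genotype random intercept Zu I Zu' to MM / MDs / MDe yields the
``l``-suffixed variants; here that is the ``intercept_random`` flag
rather than a separate model tag.  Records must be grouped contiguously
by environment: the block-diagonal tags and per-block eigen-decomposition
downstream are only valid under that ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import InputError
from .kernels import Kernel

__all__ = [
    "GE_MODELS",
    "PhenotypeTable",
    "IncidenceSet",
    "KernelSet",
    "build_incidence",
    "main_effect_kernel",
    "interaction_kernel_mds",
    "env_specific_kernels_mde",
    "random_intercept_kernel",
    "build_ge_kernels",
]

GE_MODELS = ("SM", "MM", "MDs", "MDe")


@dataclass(frozen=True)
class PhenotypeTable:
    """Observation-level records, grouped contiguously by environment.

    ``y`` may contain NaN: those records are unobserved and will be
    predicted.  Duplicate (environment, genotype) pairs are rejected.
    """

    env: np.ndarray
    gid: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        env = np.asarray(self.env, dtype=str)
        gid = np.asarray(self.gid, dtype=str)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "env", env)
        object.__setattr__(self, "gid", gid)
        object.__setattr__(self, "y", y)
        if not (len(env) == len(gid) == len(y)):
            raise InputError("env, gid and y must have equal length")
        if len(env) == 0:
            raise InputError("phenotype table is empty")
        # contiguous grouping: each environment label forms a single run
        change = np.flatnonzero(env[1:] != env[:-1])
        runs = [env[0]] + [env[i + 1] for i in change]
        if len(runs) != len(set(runs)):
            raise InputError(
                "records are not grouped by environment; sort the table so all "
                "records of each environment are contiguous"
            )
        pairs = list(zip(env.tolist(), gid.tolist()))
        if len(set(pairs)) != len(pairs):
            raise InputError("duplicate (environment, genotype) records")

    @property
    def n_records(self) -> int:
        return len(self.env)

    @property
    def environments(self) -> tuple[str, ...]:
        """Environment labels in record order."""
        idx = np.unique(self.env, return_index=True)[1]
        return tuple(self.env[np.sort(idx)])

    @property
    def genotypes(self) -> tuple[str, ...]:
        """Genotype labels in first-appearance order."""
        idx = np.unique(self.gid, return_index=True)[1]
        return tuple(self.gid[np.sort(idx)])

    @property
    def ne(self) -> tuple[int, ...]:
        """Number of records per environment, in environment order."""
        return tuple(int(np.sum(self.env == e)) for e in self.environments)

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.y)

    @property
    def record_labels(self) -> tuple[str, ...]:
        return tuple(f"{e}:{g}" for e, g in zip(self.env, self.gid))


@dataclass(frozen=True)
class IncidenceSet:
    """0/1 incidence matrices relating records to genotypes and environments.

    ``Zu`` (N x n_gen) has a single 1 per row marking the record's
    genotype; ``Ze`` (N x m) marks its environment.  ``ne`` holds the
    per-environment record counts (column sums of ``Ze``).
    """

    Zu: np.ndarray
    Ze: np.ndarray
    ne: tuple[int, ...]
    genotypes: tuple[str, ...]
    environments: tuple[str, ...]
    record_gid: tuple[str, ...]
    record_env: tuple[str, ...]

    @property
    def n_records(self) -> int:
        return self.Zu.shape[0]


def build_incidence(pheno: PhenotypeTable) -> IncidenceSet:
    """Build genotype and environment incidence matrices from the table."""
    genotypes = pheno.genotypes
    environments = pheno.environments
    g_index = {g: j for j, g in enumerate(genotypes)}
    e_index = {e: j for j, e in enumerate(environments)}
    N = pheno.n_records
    Zu = np.zeros((N, len(genotypes)))
    Ze = np.zeros((N, len(environments)))
    Zu[np.arange(N), [g_index[g] for g in pheno.gid]] = 1.0
    Ze[np.arange(N), [e_index[e] for e in pheno.env]] = 1.0
    return IncidenceSet(
        Zu=Zu, Ze=Ze, ne=pheno.ne,
        genotypes=genotypes, environments=environments,
        record_gid=tuple(pheno.gid), record_env=tuple(pheno.env),
    )


def _genotype_positions(inc: IncidenceSet, K: Kernel) -> np.ndarray:
    """Map each record's genotype to its row in K, validating coverage."""
    index = K.label_index()
    missing = sorted(set(inc.record_gid) - index.keys())
    if missing:
        raise InputError(
            f"genotypes absent from kernel labels: {', '.join(missing[:5])}"
            + (" ..." if len(missing) > 5 else "")
        )
    return np.array([index[g] for g in inc.record_gid])


def _record_labels(inc: IncidenceSet) -> tuple[str, ...]:
    return tuple(f"{e}:{g}" for e, g in zip(inc.record_env, inc.record_gid))


def main_effect_kernel(inc: IncidenceSet, K: Kernel) -> Kernel:
    """Observation-level main genotypic effect covariance ``Zu K Zu'``.

    Entry (i, j) is ``K[gid_i, gid_j]`` regardless of environment: the
    genetic effect is constant across environments.
    """
    pos = _genotype_positions(inc, K)
    V = K.values[np.ix_(pos, pos)]
    return Kernel(V, _record_labels(inc), structure="dense")


def interaction_kernel_mds(inc: IncidenceSet, K: Kernel) -> Kernel:
    """Single-variance GxE deviation covariance ``(Zu K Zu') ∘ Ze Ze'``.

    The Hadamard product with the environment indicator zeroes every
    cross-environment entry, so with records grouped by environment the
    result is block-diagonal with one block per environment; the blocks
    are built directly so off-block entries are exactly zero.
    """
    pos = _genotype_positions(inc, K)
    N = inc.n_records
    V = np.zeros((N, N))
    off = 0
    for size in inc.ne:
        sl = slice(off, off + size)
        p = pos[sl]
        V[sl, sl] = K.values[np.ix_(p, p)]
        off += size
    return Kernel(V, _record_labels(inc), structure="block_diagonal",
                  block_sizes=inc.ne)


def env_specific_kernels_mde(inc: IncidenceSet, K: Kernel) -> dict[str, Kernel]:
    """Environment-specific deviation covariances, one kernel per environment.

    The kernel for environment j is zero everywhere except its own
    diagonal block, which holds K restricted to that environment's
    genotypes in record order.  Summed over j they reproduce the MDs
    interaction kernel.
    """
    pos = _genotype_positions(inc, K)
    N = inc.n_records
    labels = _record_labels(inc)
    out: dict[str, Kernel] = {}
    off = 0
    for env_label, size in zip(inc.environments, inc.ne):
        sl = slice(off, off + size)
        p = pos[sl]
        V = np.zeros((N, N))
        V[sl, sl] = K.values[np.ix_(p, p)]
        out[env_label] = Kernel(V, labels, structure="block_diagonal",
                                block_sizes=inc.ne)
        off += size
    return out


def random_intercept_kernel(inc: IncidenceSet) -> Kernel:
    """Genotype random-intercept covariance ``Zu I Zu'``.

    A 0/1 matrix: entry (i, j) is 1 iff records i and j share a genotype.
    """
    gid = np.asarray(inc.record_gid)
    V = (gid[:, None] == gid[None, :]).astype(float)
    return Kernel(V, _record_labels(inc), structure="dense")


@dataclass(frozen=True)
class KernelSet:
    """Ordered, named observation-level kernels — one per random effect.

    Carries the record layout (env, gid, ne) so downstream code can
    simulate or fit without re-deriving the design.  Entry counts follow
    the model: MM -> 1, MDs -> 2, MDe -> 1 + m per base kernel, plus one
    shared random-intercept term when requested; with v base kernels the
    per-model counts multiply.
    """

    entries: dict[str, Kernel]
    model_tag: str
    env: np.ndarray
    gid: np.ndarray
    ne: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "env", np.asarray(self.env, dtype=str))
        object.__setattr__(self, "gid", np.asarray(self.gid, dtype=str))
        if not self.entries:
            raise InputError("kernel set has no entries")
        N = len(self.env)
        for name, k in self.entries.items():
            if k.n != N:
                raise InputError(
                    f"kernel {name!r} is {k.n}x{k.n} for {N} records"
                )

    @property
    def n_records(self) -> int:
        return len(self.env)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> Kernel:
        return self.entries[name]


def build_ge_kernels(
    pheno: PhenotypeTable,
    base_kernels: dict[str, Kernel] | Kernel,
    model: str = "MM",
    intercept_random: bool = False,
) -> KernelSet:
    """Assemble the full observation-level kernel set for a GxE model.

    Parameters
    ----------
    pheno
        Phenotype table defining the record layout (grouped by environment).
    base_kernels
        A single genotype-level Kernel, or an ordered name -> Kernel
        mapping (e.g. several Gaussian-kernel bandwidths for kernel
        averaging, or additive + dominance matrices).  With one base
        kernel entries are named ``G`` / ``GE`` / ``<env>``; with several
        the base-kernel name is appended (``G_1``, ``GE_1``, ``G_Ga``...).
    model
        One of ``SM``, ``MM``, ``MDs``, ``MDe``.  ``SM`` is the
        single-environment model and requires exactly one environment.
    intercept_random
        Append the genotype random-intercept term (named ``l``), turning
        MM / MDs / MDe into their ``l``-suffixed variants.
    """
    if model not in GE_MODELS:
        raise InputError(f"unknown model {model!r}; choose from {GE_MODELS}")
    if isinstance(base_kernels, Kernel):
        base_kernels = {"": base_kernels}
    if not base_kernels:
        raise InputError("no base kernels supplied")
    inc = build_incidence(pheno)
    if model == "SM" and len(inc.environments) != 1:
        raise InputError(
            f"model SM requires a single environment, got {len(inc.environments)}"
        )

    multi = len(base_kernels) > 1
    entries: dict[str, Kernel] = {}

    def tag(stem: str, base_name: str) -> str:
        return f"{stem}_{base_name}" if (multi or base_name) else stem

    for base_name, K in base_kernels.items():
        entries[tag("G", base_name)] = main_effect_kernel(inc, K)
        if model == "MDs":
            entries[tag("GE", base_name)] = interaction_kernel_mds(inc, K)
        elif model == "MDe":
            for env_label, kern in env_specific_kernels_mde(inc, K).items():
                entries[tag(env_label, base_name)] = kern
    if intercept_random:
        entries["l"] = random_intercept_kernel(inc)

    return KernelSet(entries=entries, model_tag=model,
                     env=pheno.env, gid=pheno.gid, ne=pheno.ne)
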