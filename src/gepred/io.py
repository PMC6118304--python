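"""File formats: phenotype/marker CSVs, kernel archives, result sets.

A *kernel archive* is a directory with a ``manifest.json`` describing the
model tag, the record layout (``records.csv`` with columns env,gid) and
one matrix CSV per kernel, so a kernel set built once can be re-used
across fits.  Result sets are plain CSVs mirroring the posterior-summary
accessors (variance components, fitted values, chains) plus a JSON run
manifest for reproducibility.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import InputError
from .ge_models import KernelSet, PhenotypeTable
from .kernels import Kernel, MarkerMatrix
from .sampler import PosteriorSummary

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_markers",
    "write_markers",
    "write_kernel_archive",
    "read_kernel_archive",
    "write_results",
]

_PHENO_COLUMNS = ("env", "gid", "value")


def read_phenotypes(path, auto_sort: bool = False) -> PhenotypeTable:
    """Read a phenotype CSV with columns ``env,gid,value``.

    An empty ``value`` cell marks a record whose phenotype is to be
    predicted; any other non-numeric content is an error.  Records must
    be grouped by environment; with ``auto_sort`` an interleaved file is
    stably sorted by environment (first-appearance order) instead of
    rejected, with a warning.
    """
    df = pd.read_csv(path, dtype={"env": str, "gid": str})
    missing_cols = [c for c in _PHENO_COLUMNS if c not in df.columns]
    if missing_cols:
        raise InputError(f"phenotype file lacks column(s): {', '.join(missing_cols)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna() & (df["value"].astype(str).str.strip() != "")
    if bad.any():
        raise InputError(
            f"non-numeric phenotype values at rows {list(df.index[bad][:5])}"
        )
    env = df["env"].to_numpy(dtype=str)
    gid = df["gid"].to_numpy(dtype=str)
    y = values.to_numpy(dtype=float)
    change = np.flatnonzero(env[1:] != env[:-1])
    runs = [env[0]] + [env[i + 1] for i in change]
    if len(runs) != len(set(runs)):
        if not auto_sort:
            raise InputError(
                "records are not grouped by environment; re-sort the file or "
                "pass auto_sort=True / --auto-sort"
            )
        import warnings

        warnings.warn("phenotype records interleaved; applying stable sort by environment")
        first = {e: i for i, e in reversed(list(enumerate(env)))}
        order = np.argsort([first[e] for e in env], kind="stable")
        env, gid, y = env[order], gid[order], y[order]
    return PhenotypeTable(env=env, gid=gid, y=y)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    df = pd.DataFrame({"env": pheno.env, "gid": pheno.gid, "value": pheno.y})
    df.to_csv(path, index=False)


def read_markers(path) -> MarkerMatrix:
    """Read a marker CSV: first column genotype ID, header row marker IDs."""
    df = pd.read_csv(path, index_col=0)
    if df.isna().any().any():
        raise InputError("marker file contains missing entries")
    return MarkerMatrix(
        df.to_numpy(dtype=float),
        genotype_ids=tuple(str(g) for g in df.index),
        marker_ids=tuple(str(m) for m in df.columns),
    )


def write_markers(X: MarkerMatrix, path) -> None:
    pd.DataFrame(X.values, index=list(X.genotype_ids),
                 columns=list(X.marker_ids)).to_csv(path)


def write_kernel_archive(kset: KernelSet, outdir) -> Path:
    """Write a kernel set as manifest + records + one matrix CSV per kernel."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"env": kset.env, "gid": kset.gid}).to_csv(
        outdir / "records.csv", index=False
    )
    entries = []
    for i, (name, kern) in enumerate(kset.entries.items()):
        fname = f"kernel_{i:02d}.csv"
        np.savetxt(outdir / fname, kern.values, delimiter=",")
        entries.append(
            {
                "name": name,
                "structure": kern.structure,
                "block_sizes": list(kern.block_sizes),
                "matrix_path": fname,
            }
        )
    manifest = {
        "format": "gepred-kernel-archive-v1",
        "model": kset.model_tag,
        "records": "records.csv",
        "kernels": entries,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir / "manifest.json"


def read_kernel_archive(manifest_path) -> KernelSet:
    """Load a kernel set written by :func:`write_kernel_archive`."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    base = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    rec = pd.read_csv(base / manifest["records"], dtype=str)
    env = rec["env"].to_numpy(dtype=str)
    gid = rec["gid"].to_numpy(dtype=str)
    labels = tuple(f"{e}:{g}" for e, g in zip(env, gid))
    entries: dict[str, Kernel] = {}
    for item in manifest["kernels"]:
        values = np.loadtxt(base / item["matrix_path"], delimiter=",", ndmin=2)
        entries[item["name"]] = Kernel(
            values, labels, structure=item["structure"],
            block_sizes=tuple(item["block_sizes"]),
        )
    ne_counts: list[int] = []
    for e in dict.fromkeys(env):
        ne_counts.append(int(np.sum(env == e)))
    return KernelSet(entries=entries, model_tag=manifest["model"],
                     env=env, gid=gid, ne=tuple(ne_counts))


def write_results(summary: PosteriorSummary, outdir, run_config: dict | None = None) -> dict:
    """Write variance components, fitted values, chains and a run manifest.

    Returns the paths written.  Output is deterministic: two runs with
    the same seed produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = [
        {"term": name, "posterior_mean": m, "posterior_sd": s}
        for name, (m, s) in summary.varu.items()
    ]
    rows.append(
        {"term": "varE", "posterior_mean": summary.varE[0],
         "posterior_sd": summary.varE[1]}
    )
    vc_path = outdir / "variance_components.csv"
    pd.DataFrame(rows).to_csv(vc_path, index=False)

    yhat_path = outdir / "y_hat.csv"
    pd.DataFrame(
        {
            "env": summary.env,
            "gid": summary.gid,
            "observed": ~np.isnan(summary.y),
            "y": summary.y,
            "y_hat": summary.y_hat,
        }
    ).to_csv(yhat_path, index=False)

    chains_path = outdir / "chains.csv"
    summary.chains.to_csv(chains_path, index=False)

    import gepred

    manifest = {
        "package": "gepred",
        "version": gepred.__version__,
        "chain_length": summary.n_retained,
        "terms": list(summary.varu),
        "config": run_config or {},
    }
    manifest_path = outdir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "variance_components": vc_path,
        "y_hat": yhat_path,
        "chains": chains_path,
        "manifest": manifest_path,
    }
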