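"""End-to-end orchestration: simulate/load -> networks -> indices -> comparisons.

A run is a pure function of its :class:`~persistnet.config.PipelineConfig`:
all randomness flows from the config seeds, so rerunning an identical config
reproduces identical tables byte for byte. Each invocation writes one run
directory containing the per-subject index table, the comparison table,
(optionally) per-subject matrices and group-mean persistence curves, and a
machine-readable ``run_manifest.json`` with the config snapshot, its hash and
the software version.

Per-subject failures quarantine the subject with a logged reason; the run
aborts only if a whole group empties out.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import FiberProfileMatrix, generate_cohort, write_cohort
from .config import PipelineConfig
from .connectome import ConnectomeTransformer, SignificanceThreshold
from .exceptions import ValidationError
from .groupstats import compare_all
from .metrics import GraphMetricsTransformer
from .persistence import PersistentFeatureTransformer, betti0_curve, ipf_curve, maximal_graph_filtration

logger = logging.getLogger(__name__)

__all__ = ["read_matrix", "write_matrix", "load_cohort", "run_pipeline"]

INDEX_COLUMNS = ["ipf", "bnp", "cpl", "ge", "ns", "mod", "cc", "ec"]


def _detect_sep(path: Path) -> str:
    if path.suffix.lower() == ".tsv":
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return "\t"


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a labelled square matrix from TSV/CSV (dialect auto-detected).

    Returns ``(values, labels)``. Non-square shape, NaN entries, mismatched
    row/column labels or asymmetry beyond 1e-9 raise a parse error naming
    the offending coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"{path}: matrix is not square, shape {df.shape}")
    if list(map(str, df.index)) != list(map(str, df.columns)):
        raise ValidationError(f"{path}: row labels do not match column labels")
    values = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"{path}: non-finite entry at ({df.index[i]}, {df.columns[j]})"
        )
    if not np.allclose(values, values.T, atol=1e-9):
        i, j = np.argwhere(~np.isclose(values, values.T, atol=1e-9))[0]
        raise ValidationError(
            f"{path}: matrix asymmetric at ({df.index[i]}, {df.columns[j]}): "
            f"{values[i, j]!r} vs {values[j, i]!r}"
        )
    return values, [str(c) for c in df.columns]


def write_matrix(values: np.ndarray, labels: list[str], path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() != ".csv" else ","
    # %.17g guarantees float round-trips through text exactly
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, sep=sep, float_format="%.17g")


def load_cohort(input_dir) -> tuple[pd.DataFrame, list[FiberProfileMatrix]]:
    """Load a cohort from ``manifest.csv`` (columns subject_id,group,path)."""
    input_dir = Path(input_dir)
    manifest = pd.read_csv(input_dir / "manifest.csv")
    for col in ("subject_id", "group", "path"):
        if col not in manifest.columns:
            raise ValidationError(f"manifest.csv: missing column {col!r}")
    if manifest["subject_id"].duplicated().any():
        dup = manifest.loc[manifest["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"manifest.csv: duplicate subject_id {dup!r}")
    matrices = []
    for p in manifest["path"]:
        p = Path(p)
        if not p.is_absolute():
            p = input_dir / p
        values, labels = read_matrix(p)
        matrices.append(FiberProfileMatrix(values, labels))
    return manifest[["subject_id", "group"]].copy(), matrices


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _group_mean_curves(networks, manifest, cfg) -> pd.DataFrame:
    """Per-group mean BNP/IPF curves on a common filtration grid."""
    rows = []
    for group in sorted(manifest["group"].unique()):
        nets = [w for w, g in zip(networks, manifest["group"]) if g == group]
        filts = [maximal_graph_filtration(w) for w in nets]
        lam_max = max(f.filtration_values[-1] for f in filts)
        grid = np.linspace(0.0, lam_max, cfg.persistence.n_grid)
        bnp = np.mean([betti0_curve(f).evaluate(grid) for f in filts], axis=0)
        ipf = np.mean(
            [ipf_curve(f, cfg.persistence.ipf_formula).evaluate(grid) for f in filts], axis=0
        )
        for lam, b, i in zip(grid, bnp, ipf):
            rows.append({"group": group, "lambda": lam, "bnp": b, "ipf": i})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run the full analysis; returns the run directory path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.io.input_dir:
        manifest, matrices = load_cohort(config.io.input_dir)
    else:
        manifest, matrices = generate_cohort(config.cohort.to_spec())
        if config.io.write_matrices:
            write_cohort(manifest, matrices, outdir / "matrices")

    conn = ConnectomeTransformer(
        method=config.connectivity.method,
        exclude_pair=config.connectivity.exclude_pair,
        shrinkage=config.connectivity.shrinkage,
        on_degenerate=config.connectivity.on_degenerate,
    ).fit(matrices)
    thresh = SignificanceThreshold(
        alpha=config.connectivity.alpha, on_unsupported=config.connectivity.on_unsupported
    )
    pers = PersistentFeatureTransformer(
        ipf_formula=config.persistence.ipf_formula,
        sampling=config.persistence.sampling,
        n_grid=config.persistence.n_grid,
    )
    gmet = GraphMetricsTransformer(
        seed=config.graphmetrics.seed,
        affinity=config.graphmetrics.affinity,
        ec_summary=config.graphmetrics.ec_summary,
        mod_solver=config.graphmetrics.mod_solver,
    )

    rows, kept_networks, kept_manifest_rows, quarantined = [], [], [], []
    for (_, mrow), T in zip(manifest.iterrows(), matrices):
        sid = mrow["subject_id"]
        try:
            W = conn.transform([T])[0]
            ipf_idx, bnp_idx = pers.fit([W]).transform([W])[0]
            N = thresh.fit([W]).transform([W])[0]
            cpl, ge, ns, mod, cc, ec = gmet.fit([N]).transform([N])[0]
        except Exception as exc:  # noqa: BLE001 - quarantine any per-subject failure
            logger.warning("quarantining subject %s: %s", sid, exc)
            quarantined.append({"subject_id": sid, "reason": str(exc)})
            continue
        kept_networks.append(W)
        kept_manifest_rows.append(mrow)
        rows.append(
            {
                "subject_id": sid,
                "group": mrow["group"],
                "ipf": ipf_idx,
                "bnp": bnp_idx,
                "cpl": cpl,
                "ge": ge,
                "ns": ns,
                "mod": mod,
                "cc": cc,
                "ec": ec,
            }
        )

    index_table = pd.DataFrame(rows, columns=["subject_id", "group"] + INDEX_COLUMNS)
    for group in manifest["group"].unique():
        if group not in set(index_table["group"]):
            raise ValidationError(f"group {group!r} lost all subjects; aborting run")

    comparisons = compare_all(
        index_table,
        n_perm=config.stats.n_permutations,
        seed=config.stats.seed,
        alpha_pairwise=config.stats.alpha_pairwise,
        alpha_omnibus=config.stats.alpha_omnibus,
    )

    index_table.to_csv(outdir / "index_table.tsv", sep="\t", index=False, float_format="%.10g")
    comparisons.to_csv(outdir / "comparisons.tsv", sep="\t", index=False, float_format="%.10g")
    if config.io.write_curves:
        kept_manifest = pd.DataFrame(kept_manifest_rows)
        _group_mean_curves(kept_networks, kept_manifest, config).to_csv(
            outdir / "group_mean_curves.tsv", sep="\t", index=False, float_format="%.10g"
        )
    if quarantined:
        pd.DataFrame(quarantined).to_csv(outdir / "quarantined.tsv", sep="\t", index=False)

    run_manifest = {
        "software": "persistnet",
        "version": __version__,
        "config": config.model_dump(),
        "config_sha256": _config_hash(config),
        "n_subjects": int(len(index_table)),
        "n_quarantined": len(quarantined),
        "seeds": {
            "cohort": config.cohort.seed,
            "graphmetrics": config.graphmetrics.seed,
            "stats": config.stats.seed,
        },
    }
    (outdir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2, sort_keys=True))
    logger.info("run complete: %d subjects, %d quarantined", len(index_table), len(quarantined))
    return outdir
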