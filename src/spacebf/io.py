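"""Readers, writers, seed derivation and the multi-pair screening driver.

Expression tables are molecules-in-rows (columns = location ids), read from
CSV/TSV or MatrixMarket (``foo.mtx`` with ``foo.mtx.rows`` and
``foo.mtx.cols`` id sidecars, one id per line).  Coordinates are a
two-column numeric table in the same location order.  All outputs are CSV
with a JSON metadata sidecar (package version, seed, config hash) so runs
are reproducible byte-for-byte given a fixed global seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from . import __version__
from .baselines import derive_seed
from .graph import build_mst, read_coords
from .inference import bh_fdr
from .models import FitConfig, GaussianSVC, NegativeBinomialSVC
from .postprocess import filter_low_expression

__all__ = ["RunConfig", "read_expression", "read_pairs", "run_pair_screen", "read_config_file"]

log = logging.getLogger("spacebf")

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Parameters of a multi-pair screening run."""

    counts: str
    coords: str
    pairs: str
    out_dir: str
    model: str = "nb"
    covariates: str | None = None
    n_iter: int = 4000
    n_burnin: int = 2000
    thin: int = 2
    seed: int = 0
    ci_level: float = 0.95
    filter_fraction: float = 0.2
    fdr_level: float = 0.1
    resume: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def read_expression(path, format: str | None = None) -> pd.DataFrame:
    """Read a molecules x locations expression table with ids.

    ``format`` is inferred from the extension when omitted; count data keep
    exact integer dtype.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(
        path.suffix.lower(), "csv"
    )
    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0)
    elif fmt == "mtx":
        rows_path = path.with_suffix(path.suffix + ".rows")
        cols_path = path.with_suffix(path.suffix + ".cols")
        if not rows_path.exists() or not cols_path.exists():
            raise FileNotFoundError(
                f"MTX sidecars missing: expected {rows_path} and {cols_path}"
            )
        raw = mmread(path)
        mat = raw.toarray() if hasattr(raw, "toarray") else np.asarray(raw)
        row_ids = rows_path.read_text().split()
        col_ids = cols_path.read_text().split()
        if mat.shape != (len(row_ids), len(col_ids)):
            raise ValueError(
                f"MTX shape {mat.shape} disagrees with sidecars "
                f"({len(row_ids)} rows, {len(col_ids)} cols)"
            )
        df = pd.DataFrame(mat, index=row_ids, columns=col_ids)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if (df.to_numpy() % 1 == 0).all():
        df = df.astype(np.int64)
    return df


def read_pairs(path) -> list[tuple[str, str]]:
    """Read a two-column pair list (predictor molecule, outcome molecule)."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("pair list must have two columns")
    first = df.iloc[0]
    if {str(first[0]).lower(), str(first[1]).lower()} & {"ligand", "receptor", "m", "mprime"}:
        df = df.iloc[1:]
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def read_config_file(path) -> dict:
    """Parse a flat ``key = value`` configuration file."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def _write_metadata(out_dir: Path, cfg: RunConfig) -> None:
    meta = {"version": __version__, "seed": cfg.seed, "config_hash": cfg.config_hash()}
    (out_dir / "metadata.json").write_text(json.dumps(meta, sort_keys=True, indent=1))


def run_pair_screen(config: RunConfig):
    """Screen every molecule pair in the pair list.

    Loads the expression/coordinate tables, filters low-expression genes,
    builds one MST shared by all pairs, fits the chosen SVC model per pair,
    runs the global and local tests, adjusts global p-values across pairs
    (Benjamini-Hochberg) and writes per-pair local CSVs plus one global
    summary CSV.  Pairs referencing unknown or filtered molecules are
    skipped with a logged reason; completed pairs are reused on resume.

    Returns the global summary data frame.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    expr = read_expression(config.counts)
    coords = read_coords(config.coords)
    if expr.shape[1] != coords.shape[0]:
        raise ValueError(
            f"expression has {expr.shape[1]} locations but coordinates have "
            f"{coords.shape[0]} rows"
        )
    covariates = None
    if config.covariates:
        covariates = pd.read_csv(config.covariates).to_numpy(dtype=float)
    pairs = read_pairs(config.pairs)

    counts = expr.to_numpy()
    if config.model == "nb":
        keep = filter_low_expression(np.maximum(counts, 0), config.filter_fraction)
        kept_ids = set(expr.index[keep])
    else:
        kept_ids = set(expr.index)

    graph = build_mst(coords, jitter_seed=config.seed)
    cls = {"nb": NegativeBinomialSVC, "gaussian": GaussianSVC}[config.model]

    rows = []
    pair_dir = out_dir / "pairs"
    pair_dir.mkdir(exist_ok=True)
    for idx, (mprime, m) in enumerate(pairs):
        pair_id = f"{mprime}__{m}"
        for mol in (mprime, m):
            if mol not in expr.index:
                log.warning("pair %s skipped: unknown molecule %s", pair_id, mol)
                break
            if mol not in kept_ids:
                log.warning("pair %s skipped: %s filtered (low expression)", pair_id, mol)
                break
        else:
            cache = pair_dir / f"{pair_id}.csv"
            pair_seed = derive_seed(config.seed, idx)
            if config.resume and cache.exists():
                local_df = pd.read_csv(cache)
                gts = json.loads((pair_dir / f"{pair_id}.json").read_text())
            else:
                est = cls(
                    n_iter=config.n_iter,
                    n_burnin=config.n_burnin,
                    thin=config.thin,
                    random_state=pair_seed,
                    ci_level=config.ci_level,
                    jitter_seed=config.seed,
                )
                est.fit(
                    expr.loc[mprime].to_numpy(),
                    expr.loc[m].to_numpy(),
                    coords=coords,
                    covariates=covariates,
                    graph=graph,
                )
                gt = est.global_test()
                lt = est.local_test()
                local_df = pd.DataFrame(
                    {
                        "location": expr.columns,
                        "x": coords[:, 0],
                        "y": coords[:, 1],
                        "beta0_mean": est.beta0_mean_,
                        "beta1_mean": lt.beta1_mean,
                        "beta1_lo": lt.ci_lo,
                        "beta1_hi": lt.ci_hi,
                        "significant_local": lt.significant.astype(int),
                    }
                )
                local_df.to_csv(cache, index=False, float_format=FLOAT_FMT)
                gts = {
                    "beta1_bar_mean": gt.beta1_bar_mean,
                    "ci_lo": gt.ci_lo,
                    "ci_hi": gt.ci_hi,
                    "pd": gt.pd,
                    "p_two_sided": gt.p_two_sided,
                    "significant": int(gt.significant),
                }
                (pair_dir / f"{pair_id}.json").write_text(json.dumps(gts, sort_keys=True))
            log.info("pair %s done (beta1_bar=%.4g)", pair_id, gts["beta1_bar_mean"])
            rows.append({"pair": pair_id, **gts})

    global_df = pd.DataFrame(
        rows,
        columns=[
            "pair", "beta1_bar_mean", "ci_lo", "ci_hi", "pd", "p_two_sided", "significant",
        ],
    )
    if len(global_df):
        global_df["p_adjusted"] = bh_fdr(global_df["p_two_sided"].to_numpy())
        global_df["significant_fdr"] = (global_df["p_adjusted"] < config.fdr_level).astype(int)
    else:
        global_df["p_adjusted"] = []
        global_df["significant_fdr"] = []
    global_df.to_csv(out_dir / "global_summary.csv", index=False, float_format=FLOAT_FMT)
    _write_metadata(out_dir, config)
    return global_df
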