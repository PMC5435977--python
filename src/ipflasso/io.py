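"""Readers and writers: datasets, block configs, fitted paths.

User-facing conventions: predictor tables are CSV/TSV with samples as
rows and a header of feature names (optional first ID column); block
configs are plain ``name = ranges`` lines with 1-based inclusive column
ranges; fits are stored as versioned JSON.  Internally everything is
0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import BlockStructure, PenaltyFactors
from .core import PathFit
from .data import DesignMatrix, Outcome

FIT_FORMAT_VERSION = 1


def parse_block_ranges(text: str, p: int = None):
    """Parse ``name = spec`` lines; spec is comma-separated 1-based items,
    each a single index or an inclusive range like ``11-100``."""
    names, blocks = [], []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"block config line {lineno}: expected 'name = ranges'")
        name, spec = (s.strip() for s in line.split("=", 1))
        idx = []
        for item in spec.split(","):
            item = item.strip()
            if "-" in item:
                lo, hi = (int(s) for s in item.split("-", 1))
            else:
                lo = hi = int(item)
            if lo < 1 or hi < lo:
                raise ValueError(f"block config line {lineno}: bad range {item!r}")
            idx.extend(range(lo - 1, hi))  # 1-based inclusive -> 0-based
        names.append(name)
        blocks.append(np.array(idx, dtype=np.intp))
    if not blocks:
        raise ValueError("block config defines no blocks")
    if p is not None:
        covered = np.concatenate(blocks)
        missing = sorted(set(range(p)) - set(covered.tolist()))
        if missing:
            raise ValueError(
                f"blocks do not cover column(s) {[m + 1 for m in missing[:5]]} (1-based)"
            )
    return BlockStructure(blocks, names)


def load_block_config(path, p: int = None) -> BlockStructure:
    return parse_block_ranges(Path(path).read_text(), p)


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def load_dataset(matrix_path, outcome_spec: dict, block_path=None):
    """Load (DesignMatrix, Outcome, BlockStructure) from a sample table.

    ``outcome_spec`` has keys: family; column (gaussian/binomial) or
    time_column + status_column (cox); optional id_column naming a
    non-feature ID column.  All remaining columns are features, in file
    order; block indices refer to those feature columns (1-based).
    """
    df = _read_table(matrix_path)
    family = outcome_spec["family"]
    drop = []
    idc = outcome_spec.get("id_column")
    if idc:
        if idc not in df.columns:
            raise ValueError(f"ID column {idc!r} not found")
        drop.append(idc)
    if family == "cox":
        tcol, scol = outcome_spec["time_column"], outcome_spec["status_column"]
        for c in (tcol, scol):
            if c not in df.columns:
                raise ValueError(f"outcome column {c!r} not found")
        status = df[scol].to_numpy(dtype=float)
        if not np.isin(status, (0.0, 1.0)).all():
            raise ValueError(f"status column {scol!r} must be coded 0/1")
        out = Outcome.cox(df[tcol].to_numpy(dtype=float), status)
        drop += [tcol, scol]
    else:
        ycol = outcome_spec["column"]
        if ycol not in df.columns:
            raise ValueError(f"outcome column {ycol!r} not found")
        y = df[ycol].to_numpy(dtype=float)
        out = Outcome.binomial(y) if family == "binomial" else Outcome.gaussian(y)
        drop.append(ycol)
    feats = df.drop(columns=drop)
    vals = feats.to_numpy(dtype=float)
    if np.isnan(vals).any():
        rows, cols = np.nonzero(np.isnan(vals))
        locs = [f"(row {r + 1}, {feats.columns[c]})" for r, c in zip(rows[:5], cols[:5])]
        raise ValueError(f"missing values at {', '.join(locs)}")
    X = DesignMatrix(vals, feats.columns)
    blocks = None
    if block_path is not None:
        blocks = load_block_config(block_path, p=X.p)
    return X, out, blocks


# ---------------------------------------------------------------------------
# fit persistence


def save_fit(fit: PathFit, path, seed=None):
    """Serialize a PathFit to versioned JSON (full float precision)."""
    doc = {
        "format_version": FIT_FORMAT_VERSION,
        "family": fit.family,
        "lambdas": fit.lambdas.tolist(),
        "coef": fit.coef_.tolist(),
        "intercept": fit.intercept_.tolist(),
        "penalty_weights": [None if not np.isfinite(w) else w for w in fit.penalty_weights],
        "feature_names": list(fit.feature_names) if fit.feature_names else None,
        "blocks": [b.tolist() for b in fit.blocks.blocks] if fit.blocks else None,
        "block_names": list(fit.blocks.names) if fit.blocks else None,
        "penalty_factors": fit.penalty_factors.factors.tolist() if fit.penalty_factors else None,
        "baseline_times": fit.baseline_times.tolist() if fit.baseline_times is not None else None,
        "baseline_cumhaz": fit.baseline_cumhaz_.tolist() if fit.baseline_cumhaz_ is not None else None,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")))


def load_fit(path) -> PathFit:
    doc = json.loads(Path(path).read_text())
    version = doc.get("format_version")
    if version != FIT_FORMAT_VERSION:
        raise ValueError(
            f"fit file format version {version!r} not supported "
            f"(expected {FIT_FORMAT_VERSION})"
        )
    blocks = None
    if doc["blocks"] is not None:
        blocks = BlockStructure(doc["blocks"], doc["block_names"])
    pf = PenaltyFactors(doc["penalty_factors"]) if doc["penalty_factors"] else None
    pw = np.array([np.inf if w is None else w for w in doc["penalty_weights"]])
    fit = PathFit(
        family=doc["family"],
        lambdas=np.asarray(doc["lambdas"], dtype=float),
        coef_=np.asarray(doc["coef"], dtype=float),
        intercept_=np.asarray(doc["intercept"], dtype=float),
        penalty_weights=pw,
        blocks=blocks,
        penalty_factors=pf,
        feature_names=tuple(doc["feature_names"]) if doc["feature_names"] else None,
    )
    if doc["baseline_times"] is not None:
        fit.baseline_times = np.asarray(doc["baseline_times"], dtype=float)
        fit.baseline_cumhaz_ = np.asarray(doc["baseline_cumhaz"], dtype=float)
    return fit


def coefficient_table(fit: PathFit, lambda_index: int) -> pd.DataFrame:
    """(feature, block, coefficient) table at one grid point."""
    names = fit.feature_names or tuple(f"V{j + 1}" for j in range(fit.p))
    if fit.blocks is not None:
        member = fit.blocks.membership()
        bnames = [fit.blocks.names[m] for m in member]
    else:
        bnames = [""] * fit.p
    return pd.DataFrame(
        {"feature": names, "block": bnames, "coefficient": fit.coef_[lambda_index]}
    )
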