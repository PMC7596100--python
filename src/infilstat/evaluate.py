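"""Validation metrics and pipeline helpers.

R-squared is computed about the identity line rho = eta (residuals are
eta - rho, the total sum of squares is about the mean of the true rho),
so a perfect estimator scores 1 and values may be negative.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .patterns import Window
from .stats import RadiusGrid, summary_features
from .synthetic import simulate_patterns

__all__ = [
    "r_squared_identity",
    "validation_report",
    "welch_ttest",
    "simulate_feature_table",
    "featurize_patterns",
    "write_table",
]


def r_squared_identity(true_rho: Sequence[float], predicted: Sequence[float]) -> float:
    """R^2 = 1 - sum((eta - rho)^2) / sum((rho - mean(rho))^2)."""
    t = np.asarray(true_rho, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.shape != p.shape or t.size < 2:
        raise ValueError("true and predicted must have equal length >= 2")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("variance of true rho is zero; R^2 undefined")
    ss_res = float(np.sum((p - t) ** 2))
    return 1.0 - ss_res / ss_tot


def validation_report(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-subset R^2 (about the identity line) and mean 95% CI width.

    ``predictions`` is the output of :func:`infilstat.mle.predict_batch`
    with the true ``rho`` column populated.
    """
    if predictions.empty:
        raise ValueError("empty predictions table")
    if predictions["rho"].isna().any():
        raise ValueError("validation requires the true rho for every row")
    rows = []
    for label, block in predictions.groupby("subset", sort=False):
        rows.append({
            "subset": label,
            "n_patterns": int(len(block)),
            "r_squared": r_squared_identity(block["rho"], block["eta"]),
            "mean_ci_width": float(block["ci_width"].mean()),
        })
    return pd.DataFrame(rows)


def report_summary(report: pd.DataFrame) -> str:
    lines = ["subset  n      R^2      mean CI width"]
    for _, r in report.iterrows():
        lines.append(f"{r['subset']:<7} {r['n_patterns']:<6d} "
                     f"{r['r_squared']:8.4f} {r['mean_ci_width']:10.4f}")
    return "\n".join(lines)


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch t-test; returns (statistic, p-value).

    Convenience for comparing feature distributions between labelled
    groups of patterns.
    """
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def featurize_patterns(patterns, grid: RadiusGrid | None = None,
                       seed: int | None = None) -> pd.DataFrame:
    """Summary features for an iterable of (metadata dict, PointPattern).

    The spherical-contact reference points for each pattern are seeded
    deterministically from ``seed`` and the pattern index.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for meta, pattern in patterns:
        fseed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        g = grid or RadiusGrid.for_window(pattern.window)
        feats = summary_features(pattern, g, seed=fseed)
        row = dict(meta)
        row.update(feats.as_dict())
        row["feature_seed"] = fseed
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_feature_table(rhos: Sequence[float], seed: int | None = None,
                           window: Window | None = None,
                           grid: RadiusGrid | None = None,
                           **simulate_kwargs) -> pd.DataFrame:
    """Generate patterns for the given rhos and return their feature table.

    One row per pattern with columns rho, d, l, n, g_max, F_max, J_min.
    All randomness (geometry, placement, reference points) derives from
    the master seed.
    """
    ss = np.random.SeedSequence(seed)
    gen_ss, feat_ss = ss.spawn(2)
    patterns = simulate_patterns(rhos, gen_ss, window=window, **simulate_kwargs)
    return featurize_patterns(patterns, grid,
                              seed=int(feat_ss.generate_state(1)[0] % (2 ** 31)))


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None,
                config_text: str | None = None) -> None:
    """Write a CSV with provenance header lines (version, seed, config hash)."""
    path = Path(path)
    cfg_hash = hashlib.sha256((config_text or "").encode()).hexdigest()[:12]
    tmp = path.with_suffix(path.suffix + ".partial")
    with open(tmp, "w") as fh:
        fh.write(f"# infilstat {__version__} seed={seed} config_sha256={cfg_hash}\n")
        df.to_csv(fh, index=False)
    tmp.rename(path)
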