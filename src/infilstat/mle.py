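"""Maximum-likelihood inference of the infiltration ratio rho.

The training ensemble provides, at each rho on the training grid, the
empirical distribution of the summary features (g_max, F_max, J_min).
Per feature, the per-rho mean and standard deviation are fitted with a
three-parameter exponential a*exp(-b*rho) + c, giving smooth mu(rho) and
sigma(rho) defined for every rho in [0, 0.5] — including values absent
from the training grid.  The cross-feature correlation structure C(rho)
is estimated empirically at each training rho (nearest-grid-point lookup
off-grid) and combined with the fitted SDs into the covariance
Sigma(rho) = D(rho) C(rho) D(rho).

Features are modelled as Gaussian at fixed rho, so the log-likelihood of
an observation x for a subset of k features is

    ln L(rho) = -0.5 * ( ln|Sigma| + (x - mu)^T Sigma^{-1} (x - mu) + k ln(2 pi) )

which reduces to the familiar univariate form for k = 1.  The MLE eta is
the argmax of ln L over a dense rho grid on [0, 0.5]; the 95% confidence
interval is the profile-likelihood set
{ rho : ln L(rho) >= ln L(eta) - 0.5 * chi2_{0.95,1} }, truncated to the
admissible interval.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit

from .stats import FEATURE_NAMES, SummaryFeatures

__all__ = [
    "ExponentialCurve",
    "InterpolatedCurve",
    "FeatureModel",
    "RhoEstimate",
    "fit_feature_curves",
    "estimate_correlation",
    "log_likelihood_single",
    "log_likelihood_multi",
    "estimate_rho",
    "predict_batch",
    "SUBSET_LABELS",
    "subset_features",
    "ModelError",
]

RHO_BOUNDS = (0.0, 0.5)
# 0.5 * 0.95-quantile of chi-squared with 1 df (Wilks profile CI drop)
CI_DROP = 0.5 * float(sps.chi2.ppf(0.95, 1))

_LABEL_TO_FEATURE = {"g": "g_max", "F": "F_max", "J": "J_min"}
SUBSET_LABELS = ("g", "F", "J", "gF", "gJ", "FJ", "gFJ")


class ModelError(RuntimeError):
    """Raised for invalid or failed feature-model operations."""


def subset_features(label: str) -> tuple[str, ...]:
    """Map a subset label like 'gFJ' to feature names ('g_max', 'F_max', 'J_min')."""
    if not label or any(ch not in _LABEL_TO_FEATURE for ch in label):
        raise ValueError(f"unknown subset label {label!r}; use e.g. 'g', 'gF', 'gFJ'")
    return tuple(_LABEL_TO_FEATURE[ch] for ch in label)


@dataclass(frozen=True)
class ExponentialCurve:
    """value(rho) = a * exp(-b * rho) + c."""

    a: float
    b: float
    c: float

    def __call__(self, rho) -> np.ndarray | float:
        return self.a * np.exp(-self.b * np.asarray(rho, dtype=float)) + self.c

    def as_dict(self) -> dict:
        return {"type": "exponential", "a": self.a, "b": self.b, "c": self.c}


@dataclass(frozen=True)
class InterpolatedCurve:
    """Piecewise-linear fallback curve through (rho, value) knots."""

    rho: tuple[float, ...]
    values: tuple[float, ...]

    def __call__(self, rho) -> np.ndarray | float:
        return np.interp(np.asarray(rho, dtype=float), self.rho, self.values)

    def as_dict(self) -> dict:
        return {"type": "interpolated", "rho": list(self.rho), "values": list(self.values)}


def _curve_from_dict(d: dict) -> ExponentialCurve | InterpolatedCurve:
    if d["type"] == "exponential":
        return ExponentialCurve(d["a"], d["b"], d["c"])
    return InterpolatedCurve(tuple(d["rho"]), tuple(d["values"]))


def _exp_model(rho, a, b, c):
    return a * np.exp(-b * rho) + c


def fit_exponential(rho: np.ndarray, y: np.ndarray) -> ExponentialCurve:
    """Least-squares fit of a*exp(-b*rho)+c to (rho, y).

    Tried from several decay-rate starting points; degenerate (constant)
    data yields a = 0.
    """
    rho = np.asarray(rho, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0.0:
        return ExponentialCurve(0.0, 1.0, float(y[0]))
    c0 = float(y[-1])
    a0 = float(y[0] - y[-1])
    fits: list[tuple[float, ExponentialCurve]] = []
    for b0 in (0.5, 1.0, 2.0, 5.0, 10.0, 20.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(_exp_model, rho, y, p0=(a0, b0, c0), maxfev=20_000)
        except RuntimeError:
            continue
        sse = float(np.sum((_exp_model(rho, *popt) - y) ** 2))
        if np.isfinite(sse):
            fits.append((sse, ExponentialCurve(*map(float, popt))))
    if not fits:
        raise ModelError("exponential fit did not converge")
    # near-linear data leaves (a, b, c) only jointly identified (a*b fixed,
    # |a|, |c| -> inf); among near-equal-SSE fits prefer the most parsimonious
    best_sse = min(s for s, _ in fits)
    candidates = [f for s, f in fits if s <= best_sse * (1 + 1e-3) + 1e-15]
    return min(candidates, key=lambda f: abs(f.c) + abs(f.a))


@dataclass
class FeatureModel:
    """Fitted mu(rho)/sigma(rho) curves and correlation structure per feature."""

    mean_curves: dict
    sd_curves: dict
    rho_grid: np.ndarray
    correlations: dict  # rho (float key) -> 3x3 ndarray, feature order FEATURE_NAMES
    training_meta: dict = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False)

    SCHEMA_VERSION = 1

    def mu(self, rho, subset: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        return np.array([self.mean_curves[s](rho) for s in subset], dtype=float)

    def sigma(self, rho, subset: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        sig = np.array([self.sd_curves[s](rho) for s in subset], dtype=float)
        if np.any(sig <= 0):
            raise ModelError(f"non-positive fitted SD at rho={rho}")
        return sig

    def _sd_floor(self, stat: str) -> float:
        """Floor the fitted SD at 5% of its peak over [0, 0.5].

        Near degenerate grid points (e.g. J_min identically 0 at rho = 0)
        the fitted SD curve can touch or cross zero; an unbounded
        precision there would let a single feature dominate any combined
        likelihood, so the Gaussian surrogate is never trusted beyond a
        20-fold precision gain over the feature's peak dispersion.
        """
        key = ("_floor", stat)
        if key not in self._cache:
            dense = np.linspace(*RHO_BOUNDS, 101)
            peak = float(np.max(self.sd_curves[stat](dense)))
            self._cache[key] = max(1e-6, 0.05 * peak)
        return self._cache[key]

    def sigma_floored(self, rho, subset: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        sig = np.array([self.sd_curves[s](rho) for s in subset], dtype=float)
        floors = np.array([self._sd_floor(s) for s in subset])
        return np.maximum(sig, floors)

    def correlation_at(self, rho: float, subset: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        """Nearest-training-grid-point empirical correlation, subset rows/cols."""
        grid = self.rho_grid
        nearest = float(grid[np.argmin(np.abs(grid - rho))])
        C = self.correlations[nearest]
        idx = [FEATURE_NAMES.index(s) for s in subset]
        return C[np.ix_(idx, idx)]

    def covariance(self, rho: float, subset: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        sig = self.sigma_floored(rho, subset)
        return self.correlation_at(rho, subset) * np.outer(sig, sig)

    # -- dense-grid profile cache -------------------------------------------
    def profile_grid(self, subset_label: str, rho_step: float = 0.002):
        """(rhos, mu, Sigma^-1, log|Sigma|) precomputed on the dense rho grid."""
        key = (subset_label, rho_step)
        if key not in self._cache:
            subset = subset_features(subset_label)
            k = len(subset)
            rhos = np.round(np.arange(RHO_BOUNDS[0], RHO_BOUNDS[1] + rho_step / 2,
                                      rho_step), 9)
            mu = np.stack([self.mu(r, subset) for r in rhos])
            sinv = np.empty((len(rhos), k, k))
            logdet = np.empty(len(rhos))
            for i, r in enumerate(rhos):
                cov = self.covariance(r, subset)
                cov = _ensure_pd(cov)
                sign, ld = np.linalg.slogdet(cov)
                if sign <= 0:
                    raise ModelError(f"covariance not positive definite at rho={r}")
                logdet[i] = ld
                sinv[i] = np.linalg.inv(cov)
            self._cache[key] = (rhos, mu, sinv, logdet)
        return self._cache[key]

    # -- serialisation -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "schema_version": self.SCHEMA_VERSION,
            "feature_order": list(FEATURE_NAMES),
            "mean_curves": {s: c.as_dict() for s, c in self.mean_curves.items()},
            "sd_curves": {s: c.as_dict() for s, c in self.sd_curves.items()},
            "rho_grid": [float(r) for r in self.rho_grid],
            "correlations": {f"{r:.6f}": C.tolist() for r, C in self.correlations.items()},
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema_version") != cls.SCHEMA_VERSION:
            raise ModelError(f"unsupported model schema in {path}")
        return cls(
            mean_curves={s: _curve_from_dict(d) for s, d in payload["mean_curves"].items()},
            sd_curves={s: _curve_from_dict(d) for s, d in payload["sd_curves"].items()},
            rho_grid=np.array(payload["rho_grid"], dtype=float),
            correlations={float(r): np.array(C) for r, C in payload["correlations"].items()},
            training_meta=payload.get("training_meta", {}),
        )


def _ensure_pd(cov: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Eigenvalue-floor repair for near-singular covariance matrices."""
    w, v = np.linalg.eigh(cov)
    if w.min() > floor * max(w.max(), 1.0):
        return cov
    w = np.maximum(w, floor * max(w.max(), 1.0))
    return (v * w) @ v.T


def fit_feature_curves(features: pd.DataFrame,
                       rho_grid: Sequence[float] | None = None,
                       min_obs_warn: int = 30) -> FeatureModel:
    """Fit exponential mean and SD curves per feature from a training table.

    ``features`` must have columns rho, g_max, F_max, J_min.  If the
    exponential SD fit fails, a piecewise-linear interpolation of the
    empirical SDs is used instead (with a warning).
    """
    required = ["rho", *FEATURE_NAMES]
    missing = [c for c in required if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    grouped = features.groupby("rho")
    grid = np.array(sorted(grouped.groups), dtype=float)
    if rho_grid is not None:
        grid = np.asarray(sorted(rho_grid), dtype=float)
    if len(grid) < 2:
        raise ValueError("need at least 2 distinct rho values to fit curves")
    counts = grouped.size()
    if (counts < min_obs_warn).any():
        warnings.warn(
            f"fewer than {min_obs_warn} observations at some rho grid points; "
            "fitted curves may be noisy", stacklevel=2)

    means = grouped[list(FEATURE_NAMES)].mean().loc[grid]
    sds = grouped[list(FEATURE_NAMES)].std(ddof=1).loc[grid]

    mean_curves, sd_curves = {}, {}
    for s in FEATURE_NAMES:
        try:
            mean_curves[s] = fit_exponential(grid, means[s].to_numpy())
        except ModelError as exc:
            raise ModelError(f"mean-curve fit failed for {s}") from exc
        try:
            sd_curves[s] = fit_exponential(grid, sds[s].to_numpy())
        except ModelError:
            warnings.warn(f"SD exponential fit failed for {s}; "
                          "falling back to interpolated SDs", stacklevel=2)
            sd_curves[s] = InterpolatedCurve(tuple(grid), tuple(sds[s].to_numpy()))

    correlations = estimate_correlation(features, grid, on_degenerate="nearest")
    meta = {"n_observations": int(len(features)),
            "reps_per_rho": {f"{r:.6f}": int(counts.get(r, 0)) for r in grid}}
    return FeatureModel(mean_curves=mean_curves, sd_curves=sd_curves,
                        rho_grid=grid, correlations=correlations,
                        training_meta=meta)


def estimate_correlation(features: pd.DataFrame,
                         rho_grid: Sequence[float] | None = None,
                         on_degenerate: str = "error"
                         ) -> dict[float, np.ndarray]:
    """Empirical Pearson correlation of (g_max, F_max, J_min) at each training rho.

    Near-singular matrices are repaired by an eigenvalue floor (with a
    warning).  A constant feature column makes the correlation undefined:
    by default that raises :class:`ModelError`; with
    ``on_degenerate="nearest"`` the matrix from the nearest
    non-degenerate grid point is substituted (warning logged), which
    keeps training usable when e.g. J_min is identically 0 at rho = 0.
    """
    grouped = features.groupby("rho")
    grid = sorted(grouped.groups) if rho_grid is None else sorted(rho_grid)
    out: dict[float, np.ndarray] = {}
    degenerate: list[float] = []
    for r in grid:
        block = grouped.get_group(r)[list(FEATURE_NAMES)].to_numpy()
        if block.shape[0] < 3:
            raise ModelError(f"need >= 3 observations at rho={r} to estimate correlation")
        if np.any(block.std(axis=0) == 0):
            if on_degenerate != "nearest":
                raise ModelError(f"constant feature column at rho={r}; "
                                 "correlation undefined")
            degenerate.append(float(r))
            continue
        C = np.corrcoef(block, rowvar=False)
        w = np.linalg.eigvalsh(C)
        if w.min() < 1e-8:
            warnings.warn(f"near-singular correlation at rho={r}; applying "
                          "eigenvalue floor", stacklevel=2)
            C = _ensure_pd(C, floor=1e-8)
            dd = np.sqrt(np.diag(C))
            C = C / np.outer(dd, dd)
        out[float(r)] = C
    if degenerate:
        if not out:
            raise ModelError("every rho grid point has a constant feature column")
        avail = np.array(sorted(out))
        warnings.warn(f"constant feature column at rho={degenerate}; "
                      "substituting nearest non-degenerate correlation",
                      stacklevel=2)
        for r in degenerate:
            out[r] = out[float(avail[np.argmin(np.abs(avail - r))])]
    return out


def log_likelihood_single(x: float, rho: float, model: FeatureModel,
                          statistic: str) -> float:
    """Univariate Gaussian log-likelihood of one feature value at the given rho."""
    if statistic in _LABEL_TO_FEATURE:
        statistic = _LABEL_TO_FEATURE[statistic]
    mu = float(model.mean_curves[statistic](rho))
    sig = float(model.sd_curves[statistic](rho))
    if sig <= 0:
        raise ModelError(f"non-positive SD for {statistic} at rho={rho}")
    return float(-0.5 * (np.log(2 * np.pi * sig ** 2) + (x - mu) ** 2 / sig ** 2))


def log_likelihood_multi(x: Sequence[float], rho: float, model: FeatureModel,
                         subset: str | Sequence[str] = "gFJ") -> float:
    """Multivariate Gaussian log-likelihood for a feature subset at the given rho."""
    names = subset_features(subset) if isinstance(subset, str) else tuple(subset)
    k = len(names)
    x = np.asarray(x, dtype=float).reshape(k)
    mu = model.mu(rho, names)
    cov = _ensure_pd(model.covariance(rho, names))
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ModelError(f"singular covariance at rho={rho}")
    resid = x - mu
    quad = float(resid @ np.linalg.solve(cov, resid))
    return float(-0.5 * (logdet + quad + k * np.log(2 * np.pi)))


@dataclass
class RhoEstimate:
    """MLE of rho with a 95% profile-likelihood confidence interval."""

    eta: float
    ci_lower: float
    ci_upper: float
    profile_rho: np.ndarray
    profile_loglik: np.ndarray
    statistics_used: str

    @property
    def ci_width(self) -> float:
        return self.ci_upper - self.ci_lower


def estimate_rho(features: SummaryFeatures | dict | Sequence[float],
                 model: FeatureModel, subset: str = "gFJ",
                 rho_step: float = 0.002) -> RhoEstimate:
    """Profile the log-likelihood over a dense rho grid and extract eta + 95% CI.

    Ties at the maximum resolve to the smallest rho.  The CI is the set of
    grid rhos whose log-likelihood is within 0.5*chi2_{0.95,1} of the
    maximum, reported as its min/max and truncated to [0, 0.5].
    """
    names = subset_features(subset)
    if isinstance(features, SummaryFeatures):
        x = features.vector(names)
    elif isinstance(features, dict):
        x = np.array([features[s] for s in names], dtype=float)
    else:
        x = np.asarray(features, dtype=float).reshape(len(names))

    rhos, mu, sinv, logdet = model.profile_grid(subset, rho_step)
    k = len(names)
    resid = x[np.newaxis, :] - mu
    quad = np.einsum("gi,gij,gj->g", resid, sinv, resid)
    loglik = -0.5 * (logdet + quad + k * np.log(2 * np.pi))
    if not np.any(np.isfinite(loglik)):
        raise ModelError("log-likelihood is non-finite over the whole rho grid")
    imax = int(np.nanargmax(loglik))  # first occurrence -> smallest rho on ties
    eta = float(rhos[imax])
    inside = loglik >= loglik[imax] - CI_DROP
    ci_lo = float(np.clip(rhos[inside].min(), *RHO_BOUNDS))
    ci_hi = float(np.clip(rhos[inside].max(), *RHO_BOUNDS))
    return RhoEstimate(eta=eta, ci_lower=ci_lo, ci_upper=ci_hi,
                       profile_rho=rhos, profile_loglik=loglik,
                       statistics_used=subset)


def predict_batch(features: pd.DataFrame, model: FeatureModel,
                  subsets: Sequence[str] = SUBSET_LABELS,
                  rho_step: float = 0.002) -> pd.DataFrame:
    """Estimate rho for every pattern x subset; skips rows with bad features.

    ``features`` needs columns g_max, F_max, J_min and optionally
    pattern_id and rho (the generating truth, if known).
    """
    rows = []
    skipped = 0
    for i, rec in features.iterrows():
        pid = rec.get("pattern_id", i)
        truth = rec.get("rho", np.nan)
        vals = {s: rec[s] for s in FEATURE_NAMES}
        if not all(np.isfinite(v) for v in vals.values()):
            skipped += 1
            continue
        for label in subsets:
            est = estimate_rho(vals, model, label, rho_step)
            rows.append({"pattern_id": pid, "rho": truth, "subset": label,
                         "eta": est.eta, "ci_lower": est.ci_lower,
                         "ci_upper": est.ci_upper, "ci_width": est.ci_width})
    out = pd.DataFrame(rows, columns=["pattern_id", "rho", "subset", "eta",
                                      "ci_lower", "ci_upper", "ci_width"])
    out.attrs["skipped"] = skipped
    if skipped:
        warnings.warn(f"predict_batch skipped {skipped} patterns with "
                      "non-finite features", stacklevel=2)
    return out
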