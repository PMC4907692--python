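"""Saturation radioligand-binding analysis.

Total binding of a radioligand to a receptor preparation is modeled as a
Hill isotherm plus a linear nonspecific component:

    B_total(L) = Bmax * L^nH / (Kd^nH + L^nH) + ns_slope * L

Nonspecific binding is measured either paired at each concentration
(excess cold ligand, heat-inactivated protein, or a non-expressing
control) and subtracted directly, or taken from a reference dataset to
which a line through the origin is fit.  The corrected specific binding
is then fit with the Hill equation; affinity changes between conditions
are summarized as Kd ratios with delta-method standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "BindingDataset",
    "HillFit",
    "FoldChange",
    "read_binding_table",
    "write_binding_table",
    "correct_nonspecific",
    "fit_hill",
    "predict",
    "fold_change",
    "format_fold",
]

_POINT_COLUMNS = ["concentration_nM", "counts", "replicate"]


@dataclass
class BindingDataset:
    """Binding measurements for one construct/condition.

    ``points`` holds total binding (columns ``concentration_nM``,
    ``counts``, ``replicate``); ``nonspecific`` holds either paired
    nonspecific measurements in the same layout, or a reference
    dataset's points when the nonspecific signal was characterized on a
    separate non-binding preparation.
    """

    points: pd.DataFrame
    nonspecific: pd.DataFrame | None = None
    label: str = ""

    def __post_init__(self) -> None:
        for df in (self.points, self.nonspecific):
            if df is None:
                continue
            missing = [c for c in _POINT_COLUMNS if c not in df.columns]
            if missing:
                raise ValueError(f"binding table missing columns {missing}")
            if (df["concentration_nM"] <= 0).any():
                raise ValueError("concentrations must be positive")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.points["concentration_nM"].unique())


@dataclass
class HillFit:
    """Fitted Hill parameters with standard errors.

    ``Kd`` (nM) is the half-saturating concentration, ``nH`` the Hill
    slope and ``Bmax`` the saturating signal.  Standard errors are from
    the Jacobian at the optimum (NaN when not estimable); construct with
    ``se_* = nan`` to wrap published parameter values.
    """

    Kd: float
    nH: float
    Bmax: float
    se_Kd: float = float("nan")
    se_nH: float = float("nan")
    se_Bmax: float = float("nan")
    rss: float = float("nan")
    converged: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if self.converged and (self.Kd <= 0 or self.nH <= 0 or self.Bmax <= 0):
            raise ValueError("Kd, nH and Bmax must be positive at convergence")


@dataclass(frozen=True)
class FoldChange:
    """Kd ratio between two conditions with a delta-method SE."""

    ratio: float
    se: float
    label_a: str = ""
    label_b: str = ""


# --------------------------------------------------------------------------
# Table I/O
# --------------------------------------------------------------------------

def read_binding_table(path: str | Path, condition: str | None = None) -> BindingDataset:
    """Read a delimited binding table.

    Expected columns: ``concentration_nM, counts, replicate, condition,
    is_nonspecific``.  With several conditions present, ``condition``
    selects one.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "condition" in df.columns:
        if condition is not None:
            df = df[df["condition"] == condition]
        elif df["condition"].nunique() > 1:
            raise ValueError("table holds several conditions; pass condition=")
    if df.empty:
        raise ValueError("no binding points selected")
    ns_flag = df.get("is_nonspecific", pd.Series(False, index=df.index)).astype(bool)
    keep = _POINT_COLUMNS
    total = df[~ns_flag][keep].reset_index(drop=True)
    nonspec = df[ns_flag][keep].reset_index(drop=True)
    return BindingDataset(points=total,
                          nonspecific=nonspec if len(nonspec) else None,
                          label=condition or str(df.get("condition", pd.Series([""])).iloc[0]))


def write_binding_table(ds: BindingDataset, path: str | Path) -> None:
    frames = [ds.points.assign(condition=ds.label, is_nonspecific=False)]
    if ds.nonspecific is not None:
        frames.append(ds.nonspecific.assign(condition=ds.label, is_nonspecific=True))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Nonspecific correction
# --------------------------------------------------------------------------

def correct_nonspecific(
    ds: BindingDataset, mode: str = "paired", reference: BindingDataset | None = None
) -> pd.DataFrame:
    """Specific binding after nonspecific subtraction.

    ``paired`` mode subtracts the mean paired nonspecific signal at each
    concentration; ``reference`` mode fits ``ns = slope * L`` by least
    squares to a reference dataset (or ``ds.nonspecific``) and subtracts
    the fitted line.  Negative corrected values are retained — clipping
    would bias low-signal points upward.
    """
    pts = ds.points.copy()
    if mode == "paired":
        if ds.nonspecific is None:
            raise ValueError("paired correction requires paired nonspecific data")
        ns_mean = ds.nonspecific.groupby("concentration_nM")["counts"].mean()
        missing = set(pts["concentration_nM"].unique()) - set(ns_mean.index)
        if missing:
            raise ValueError(f"no nonspecific measurement at {sorted(missing)} nM")
        pts["counts"] = pts["counts"] - pts["concentration_nM"].map(ns_mean)
    elif mode == "reference":
        ref = reference.points if reference is not None else ds.nonspecific
        if ref is None:
            raise ValueError("reference correction requires a reference dataset")
        L = ref["concentration_nM"].to_numpy(float)
        y = ref["counts"].to_numpy(float)
        slope = float(L @ y / (L @ L))  # least-squares line through the origin
        pts["counts"] = pts["counts"] - slope * pts["concentration_nM"]
    else:
        raise ValueError(f"unknown correction mode {mode!r}")
    return pts


# --------------------------------------------------------------------------
# Hill fitting
# --------------------------------------------------------------------------

def _hill(L: np.ndarray, Kd: float, nH: float, Bmax: float) -> np.ndarray:
    Ln = L**nH
    return Bmax * Ln / (Kd**nH + Ln)


def fit_hill(points, label: str = "") -> HillFit:
    """Least-squares Hill fit of specific binding vs concentration.

    Accepts a DataFrame with ``concentration_nM``/``counts`` columns (a
    ``replicate`` column is averaged per concentration) or a pair of
    arrays ``(L, B)``.  Parameters are fit on a log scale, which keeps
    them positive without hard bounds; initialization is a deterministic
    multi-start — Kd from half-maximum interpolation, Bmax from the
    plateau, and Hill slopes 0.5, 1 and 2 — keeping the best solution.
    Unweighted residuals on replicate means.
    """
    if isinstance(points, pd.DataFrame):
        means = points.groupby("concentration_nM")["counts"].mean()
        L = means.index.to_numpy(float)
        y = means.to_numpy(float)
    else:
        L, y = (np.asarray(a, dtype=float) for a in points)
        order = np.argsort(L)
        L, y = L[order], y[order]
    if np.unique(L).size < 3:
        raise ValueError("Hill fitting requires at least 3 distinct concentrations")

    bmax0 = max(y.max(), 1e-12)
    # half-maximum crossing by interpolation on the measured curve
    half = bmax0 / 2.0
    above = np.nonzero(y >= half)[0]
    if above.size and above[0] > 0:
        j = above[0]
        x0, x1, y0, y1 = L[j - 1], L[j], y[j - 1], y[j]
        kd0 = x0 + (half - y0) * (x1 - x0) / max(y1 - y0, 1e-12)
    else:
        kd0 = float(np.median(L))
    kd0 = min(max(kd0, L.min() / 10), L.max() * 10)

    def residuals(theta: np.ndarray) -> np.ndarray:
        Kd, nH, Bmax = np.exp(theta)
        return _hill(L, Kd, nH, Bmax) - y

    best = None
    for nh0 in (0.5, 1.0, 2.0):
        theta0 = np.log([kd0, nh0, bmax0])
        res = least_squares(residuals, theta0, method="lm", max_nfev=10_000)
        if best is None or res.cost < best.cost:
            best = res
    Kd, nH, Bmax = np.exp(best.x)
    rss = float(2 * best.cost)
    dof = L.size - 3
    se_log = np.full(3, np.nan)
    if best.success and dof > 0:
        JtJ = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(JtJ) * rss / dof
            se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass
    # delta method back to the linear scale: se(p) = p * se(log p)
    return HillFit(
        Kd=float(Kd), nH=float(nH), Bmax=float(Bmax),
        se_Kd=float(Kd * se_log[0]), se_nH=float(nH * se_log[1]),
        se_Bmax=float(Bmax * se_log[2]),
        rss=rss, converged=bool(best.success), label=label,
    )


def predict(fit: HillFit, L) -> np.ndarray | float:
    """Evaluate the fitted Hill curve at concentration(s) ``L`` (nM)."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    L_arr = np.asarray(L, dtype=float)
    if np.any(L_arr < 0):
        raise ValueError("concentrations must be nonnegative")
    out = np.where(L_arr > 0, _hill(np.maximum(L_arr, 1e-300), fit.Kd, fit.nH, fit.Bmax), 0.0)
    return float(out) if np.isscalar(L) or L_arr.ndim == 0 else out


def fold_change(fit_a: HillFit, fit_b: HillFit) -> FoldChange:
    """Affinity fold difference ``Kd_a / Kd_b``.

    A ratio above 1 means condition ``a`` binds more weakly (larger Kd).
    The standard error combines the two fits' relative Kd errors by the
    delta method; it is NaN when either SE is unavailable (e.g. fits
    wrapping published values).
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("fold change requires two converged fits")
    ratio = fit_a.Kd / fit_b.Kd
    rel = np.hypot(fit_a.se_Kd / fit_a.Kd, fit_b.se_Kd / fit_b.Kd)
    return FoldChange(ratio=float(ratio), se=float(ratio * rel),
                      label_a=fit_a.label, label_b=fit_b.label)


def format_fold(ratio: float) -> str:
    """Round a Kd ratio to one significant figure: ``about 3-fold``."""
    if ratio <= 0 or not np.isfinite(ratio):
        raise ValueError("ratio must be positive and finite")
    exponent = np.floor(np.log10(ratio))
    rounded = round(ratio / 10**exponent) * 10**exponent
    value = f"{int(rounded)}" if rounded >= 1 else f"{rounded:.1g}"
    return f"about {value}-fold"
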