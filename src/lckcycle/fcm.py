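"""Flow-cytometry event pipeline.

Turns per-event two-colour tables (total stain vs active-state stain,
plus an optional barcode-dye channel) into background-subtracted binned
dose curves and fitted dose-response relationships:

1. read events (CSV canonical; FCS 3.0/3.1 read-only with log->linear
   conversion from keyword metadata),
2. demultiplex barcoded subpopulations on the dye channel,
3. equal-count binning on the total-stain axis (default 73 bins),
4. per-bin geometric medians, scalar background subtraction from a
   control sample, gating to a reference expression range,
5. nonlinear regression of the crossover form ``y = a*x^2/(x + k)``
   (quadratic at low x, linear at high x).

"Geometric median" is implemented as the one-dimensional median on the
log scale per channel, i.e. ``exp(median(log(x)))`` over positive
values; for 1-D data the geometric median coincides with the median, and
the log-scale reading matches flow-cytometry convention.  A geometric
*mean* variant is selectable (``method="mean"``) since the source term
is ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, DemultiplexError, EmptyInputError, FitError

__all__ = [
    "GateBox",
    "RegressionFit",
    "read_events",
    "demultiplex_barcodes",
    "bin_lckT",
    "geometric_median",
    "geometric_mean",
    "binned_curve",
    "subtract_background",
    "restrict_range",
    "fit_dose_response",
    "normalize_curve",
    "percent_inhibition",
    "fold_change",
]

CHANNELS = ("lckT", "lckA", "violet")


@dataclass(frozen=True)
class GateBox:
    """Reference expression range on the background-subtracted x axis."""

    lckT_min: float
    lckT_max: float
    lckA_min: float = -np.inf
    lckA_max: float = np.inf

    def __post_init__(self):
        if not (self.lckT_min < self.lckT_max and self.lckA_min < self.lckA_max):
            raise ConfigError("gate box bounds must satisfy min < max")


@dataclass(frozen=True)
class RegressionFit:
    model_form: str
    coefficients: dict
    r_squared: float
    f_test_p: float

    def __post_init__(self):
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise FitError(f"r_squared {self.r_squared} outside [0, 1]")

    def predict(self, x):
        x = np.asarray(x, float)
        if self.model_form == "crossover":
            a, k = self.coefficients["alpha"], self.coefficients["kappa"]
            return a * x**2 / (x + k)
        if self.model_form == "quadlin":
            a, b = self.coefficients["a"], self.coefficients["b"]
            return a * x**2 + b * x
        raise FitError(f"unknown model form {self.model_form!r}")


def read_events(path, format: str | None = None,
                channels: dict[str, str] | None = None) -> pd.DataFrame:
    """Load an event table with canonical columns ``lckT, lckA, violet``.

    ``channels`` maps canonical names to file column/parameter names
    (e.g. ``{"lckT": "FL2-H"}``).  FCS log-amplified parameters are
    converted to linear scale from $PnE/$PnR metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format == "fcs":
        from .fcs import read_fcs
        table = read_fcs(path, linearize=True)
    elif format == "csv":
        if path.stat().st_size == 0:
            raise EmptyInputError(f"{path} is empty")
        table = pd.read_csv(path)
    else:
        raise ConfigError(f"unknown format {format!r}")
    if len(table) == 0:
        raise EmptyInputError(f"{path} contains no events")
    channels = channels or {}
    out = pd.DataFrame(index=table.index)
    for canon in CHANNELS:
        source = channels.get(canon, canon)
        if source in table.columns:
            out[canon] = table[source].astype(float)
        elif canon in ("lckT", "lckA"):
            raise ConfigError(f"channel {canon!r} (column {source!r}) missing")
    for extra in table.columns.difference(out.columns):
        if extra not in channels.values():
            out[extra] = table[extra]
    if (out[[c for c in ("lckT", "lckA") if c in out]] < 0).any().any():
        warnings.warn("negative fluorescence values present after linearisation")
    return out


def _gmm_1d(logv: np.ndarray, k: int, seed: int = 0):
    """k-component 1-D Gaussian mixture with quantile initialisation."""
    from sklearn.mixture import GaussianMixture

    x = logv.reshape(-1, 1)
    q = np.quantile(logv, (np.arange(k) + 0.5) / k).reshape(-1, 1)
    gm = GaussianMixture(n_components=k, means_init=q, n_init=1,
                         random_state=seed, covariance_type="full")
    gm.fit(x)
    return gm


def demultiplex_barcodes(events: pd.DataFrame, k: int = 3,
                         min_separation: float = 1.0,
                         seed: int = 0) -> pd.DataFrame:
    """Assign each event to one of ``k`` barcode populations.

    A 1-D Gaussian mixture on log10 dye intensity, components relabelled
    in order of increasing mean so label 0 is the dimmest population.
    Raises :class:`DemultiplexError` when fitted modes are closer than
    ``min_separation`` combined standard deviations (undetectable modes),
    rather than mislabeling silently.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    if "violet" not in events.columns:
        raise ConfigError("violet barcode channel missing")
    out = events.copy()
    if k == 1:
        out["label"] = 0
        return out
    v = events["violet"].to_numpy(float)
    if (v <= 0).any():
        raise ConfigError("barcode intensities must be positive")
    logv = np.log10(v)
    gm = _gmm_1d(logv, k, seed=seed)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(means)
    mu, sd = means[order], sds[order]
    gaps = np.diff(mu) / (sd[:-1] + sd[1:])
    if np.any(gaps < min_separation):
        raise DemultiplexError(
            f"fewer than {k} separable barcode modes",
            diagnostics={"means": mu.tolist(), "sds": sd.tolist(),
                         "separation": gaps.tolist()})
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    out["label"] = relabel[gm.predict(logv.reshape(-1, 1))]
    return out


def bin_lckT(events: pd.DataFrame, n_bins: int = 73) -> list[pd.DataFrame]:
    """Partition events into ``n_bins`` equal-count bins on ``lckT``.

    Events are rank-ordered on ``lckT`` (stable on ties) and split into
    contiguous chunks whose sizes differ by at most one, so 7300 events
    give exactly 100 per bin.  A degenerate axis (a single distinct
    value) is returned as one bin with a warning.
    """
    if n_bins < 1:
        raise ConfigError("n_bins must be >= 1")
    n = len(events)
    if n < n_bins:
        raise EmptyInputError(f"{n} events < {n_bins} bins")
    if events["lckT"].nunique() == 1:
        warnings.warn("all lckT values identical; single degenerate bin")
        return [events]
    order = np.argsort(events["lckT"].to_numpy(), kind="stable")
    edges = np.linspace(0, n, n_bins + 1).round().astype(int)
    return [events.iloc[order[a:b]] for a, b in zip(edges[:-1], edges[1:])]


def _positive(values) -> tuple[np.ndarray, int]:
    x = np.asarray(values, float)
    keep = x > 0
    return x[keep], int((~keep).sum())


def geometric_median(values) -> float:
    """``exp(median(log x))`` over positive values (see module docstring)."""
    pos, n_dropped = _positive(values)
    if pos.size == 0:
        raise EmptyInputError("no positive values for geometric median")
    if n_dropped:
        warnings.warn(f"geometric_median dropped {n_dropped} non-positive values")
    return float(np.exp(np.median(np.log(pos))))


def geometric_mean(values) -> float:
    """``exp(mean(log x))`` over positive values."""
    pos, n_dropped = _positive(values)
    if pos.size == 0:
        raise EmptyInputError("no positive values for geometric mean")
    if n_dropped:
        warnings.warn(f"geometric_mean dropped {n_dropped} non-positive values")
    return float(np.exp(np.mean(np.log(pos))))


def _center(values, method: str) -> float:
    if method == "median":
        return geometric_median(values)
    if method == "mean":
        return geometric_mean(values)
    raise ConfigError(f"unknown center method {method!r}")


def binned_curve(events: pd.DataFrame, n_bins: int = 73,
                 method: str = "median") -> pd.DataFrame:
    """Per-bin centers of both channels (no background subtraction yet).

    A bin whose channel holds no positive values (e.g. zero active
    signal at the bottom of the expression range) gets center 0.
    """
    groups = bin_lckT(events, n_bins=n_bins)

    def center(values):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return _center(values, method)
        except EmptyInputError:
            return 0.0

    curve = pd.DataFrame([{
        "bin_id": i,
        "lckT_med": center(g["lckT"]),
        "lckA_med": center(g["lckA"]),
        "n_events": len(g),
    } for i, g in enumerate(groups)])
    return curve.sort_values("lckT_med", ignore_index=True)


def subtract_background(curve: pd.DataFrame, control: pd.DataFrame,
                        method: str = "median") -> pd.DataFrame:
    """Subtract the control sample's scalar center from every bin.

    Negative nets are retained (not clamped) and flagged, to avoid
    biasing the low-expression regime.
    """
    if control is None or len(control) == 0:
        raise EmptyInputError("control sample is empty")
    bkg_t = _center(control["lckT"], method)
    bkg_a = _center(control["lckA"], method)
    out = curve.copy()
    out["lckT_bkg"] = bkg_t
    out["lckA_bkg"] = bkg_a
    out["lckT_net"] = out["lckT_med"] - bkg_t
    out["lckA_net"] = out["lckA_med"] - bkg_a
    out["negative_net"] = (out["lckT_net"] < 0) | (out["lckA_net"] < 0)
    return out


def restrict_range(curve: pd.DataFrame, box: GateBox) -> pd.DataFrame:
    """Keep bins whose net values fall inside the gate box."""
    x = curve["lckT_net"] if "lckT_net" in curve.columns else curve["lckT_med"]
    y = curve["lckA_net"] if "lckA_net" in curve.columns else curve["lckA_med"]
    keep = (x >= box.lckT_min) & (x <= box.lckT_max) \
        & (y >= box.lckA_min) & (y <= box.lckA_max)
    if not keep.any():
        raise EmptyInputError("gate box excludes every bin")
    return curve[keep].reset_index(drop=True)


def _curve_xy(curve: pd.DataFrame):
    x = (curve["lckT_net"] if "lckT_net" in curve.columns
         else curve["lckT_med"]).to_numpy(float)
    y = (curve["lckA_net"] if "lckA_net" in curve.columns
         else curve["lckA_med"]).to_numpy(float)
    return x, y


def fit_dose_response(curve: pd.DataFrame, form: str = "crossover") -> RegressionFit:
    """Nonlinear least squares of the dose curve.

    Default form ``y = alpha * x^2 / (x + kappa)``: quadratic with
    curvature ``alpha/kappa`` as x -> 0 and linear with slope ``alpha``
    as x -> infinity.  ``form="quadlin"`` fits ``a*x^2 + b*x`` instead.
    """
    x, y = _curve_xy(curve)
    if x.size < 5:
        raise FitError("need at least 5 bins to fit")
    scale_x = max(abs(x).max(), 1e-12)
    scale_y = max(abs(y).max(), 1e-12)
    if form == "crossover":
        def f(x, alpha, kappa):
            return alpha * x**2 / (x + kappa)
        p0 = (scale_y / scale_x, 0.3 * scale_x)
        bounds = ((0, 1e-9 * scale_x), (np.inf, np.inf))
        names = ("alpha", "kappa")
        n_par = 2
    elif form == "quadlin":
        def f(x, a, b):
            return a * x**2 + b * x
        p0 = (scale_y / scale_x**2, scale_y / scale_x)
        bounds = ((0, 0), (np.inf, np.inf))
        names = ("a", "b")
        n_par = 2
    else:
        raise ConfigError(f"unknown model form {form!r}")
    try:
        popt, _ = optimize.curve_fit(f, x, y, p0=p0, bounds=bounds,
                                     maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - non-convergence path
        raise FitError(f"regression did not converge: {exc}") from exc
    resid = y - f(x, *popt)
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 0:
        raise FitError("degenerate curve: zero variance in response")
    r2 = max(0.0, 1.0 - sse / sst)
    df_model, df_resid = n_par - 1 + 1, x.size - (n_par + 1)
    if df_resid <= 0 or sse <= 0:
        p_val = 0.0
    else:
        f_stat = ((sst - sse) / df_model) / (sse / df_resid)
        p_val = float(stats.f.sf(max(f_stat, 0.0), df_model, df_resid))
    return RegressionFit(model_form=form,
                         coefficients=dict(zip(names, map(float, popt))),
                         r_squared=min(r2, 1.0), f_test_p=p_val)


def normalize_curve(curve: pd.DataFrame) -> pd.DataFrame:
    """Pointwise ``lckA_net / lckT_net`` versus ``lckT_net``.

    Bins with non-positive ``lckT_net`` are dropped with a warning.
    """
    x, y = _curve_xy(curve)
    keep = x > 0
    if not keep.any():
        raise EmptyInputError("no bins with positive lckT_net to normalise")
    if (~keep).sum():
        warnings.warn(f"normalize_curve dropped {(~keep).sum()} bins with "
                      "non-positive lckT_net")
    out = curve[keep].reset_index(drop=True).copy()
    out["ratio"] = y[keep] / x[keep]
    return out


def percent_inhibition(treated_median: float, control_median: float) -> float:
    """``100 * (1 - treated/control)``; negative means an increase."""
    if control_median <= 0:
        raise ConfigError("control median must be positive")
    return 100.0 * (1.0 - treated_median / control_median)


def fold_change(treated_median: float, control_median: float) -> float:
    """Percent increase of treated over control (+50 for 150 vs 100)."""
    if control_median <= 0:
        raise ConfigError("control median must be positive")
    return 100.0 * (treated_median / control_median - 1.0)
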