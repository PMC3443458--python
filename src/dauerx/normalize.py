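"""Background correction and spike-anchored within-array normalization.

Each channel is background-corrected under the Normal-background +
Exponential-signal convolution model (corrected value = E[signal |
observed]), M/A values are computed with the dye-orientation sign
convention, and a weighted robust loess of M on A — spikes up-weighted
and offset by their expected log-ratios — removes intensity-dependent
dye bias.  A final affine anchor pins the weighted median of spike M to
the weighted median of the expected spike log-ratios, so a genuine
global shift of the mRNA population (dauer repression) survives
normalization instead of being regressed away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_ndtr
from scipy.stats import norm

from .arrayio import ProbeAnnotation, TwoColorScan
from .errors import EstimationError, NormalizationError, ValidationError

_MIN_OK_SPOTS = 30
_LOG_CLAMP = 2.0 ** -20   # defensive; corrected intensities are positive by contract


@dataclass
class NormexpParams:
    """Background-correction parameters: background mean/sd and signal mean."""

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and self.alpha > 0):
            raise ValidationError("normexp parameters require sigma > 0 and alpha > 0")


@dataclass
class NormalizedArray:
    """Per-probe M/A values with weights for one array.

    ``data`` columns: probe_id, M, A, weight, is_spike.
    """

    array_id: str
    species: str
    condition: str
    data: pd.DataFrame
    spike_anchor_offset: float | None = None   # achieved |median spike M - expected|


def estimate_normexp(scan: TwoColorScan, channel: str) -> NormexpParams:
    """Robust background parameters and signal mean for one channel.

    mu/sigma are the median and MAD·1.4826 of the local background of
    ok-flagged spots; alpha is the mean foreground-minus-background
    excess, floored at a small positive value.
    """
    if channel not in ("red", "green"):
        raise ValidationError(f"unknown channel {channel!r}")
    ok = scan.spots[scan.spots["flag"] == "ok"]
    if len(ok) < _MIN_OK_SPOTS:
        raise EstimationError(
            f"array {scan.array_id}: {len(ok)} ok spots < {_MIN_OK_SPOTS} required")
    bg = ok[f"bg_{channel}"].to_numpy(float)
    fg = ok[f"fg_{channel}"].to_numpy(float)
    mu = float(np.median(bg))
    sigma = float(np.median(np.abs(bg - mu)) * 1.4826)
    sigma = max(sigma, 1e-6 * max(mu, 1.0))
    alpha = max(float(np.mean(fg - bg)), 1e-6)
    return NormexpParams(mu=mu, sigma=sigma, alpha=alpha)


def normexp_correct(x, params: NormexpParams):
    """E[signal | observed = x] under X = Normal(mu, sigma^2) + Exp(alpha).

    Computed in log space so the Mills-ratio term stays finite far below
    background; strictly positive and monotone increasing in x.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValidationError("non-finite intensity passed to normexp_correct")
    mu_s = x - params.mu - params.sigma**2 / params.alpha
    z = mu_s / params.sigma
    # E[S|X] = mu_s + sigma * phi(z) / Phi(z); log-space ratio is stable for z << 0
    log_ratio = norm.logpdf(z) - log_ndtr(z)
    out = mu_s + params.sigma * np.exp(log_ratio)
    out = np.maximum(out, np.finfo(float).tiny)
    if out.ndim == 0:
        return float(out)
    return out


def compute_ma(scan: TwoColorScan, params_red: NormexpParams,
               params_green: NormexpParams) -> NormalizedArray:
    """Background-correct both channels and compute orientation-adjusted M, A."""
    spots = scan.spots
    r = np.maximum(normexp_correct(spots["fg_red"].to_numpy(float), params_red),
                   _LOG_CLAMP)
    g = np.maximum(normexp_correct(spots["fg_green"].to_numpy(float), params_green),
                   _LOG_CLAMP)
    m_raw = np.log2(r) - np.log2(g)
    a = 0.5 * (np.log2(r) + np.log2(g))
    m = m_raw if scan.dye_orientation == "sample_in_red" else -m_raw
    weight = np.where(spots["flag"].to_numpy() == "ok", 1.0, 0.0)
    data = pd.DataFrame({
        "probe_id": spots["probe_id"].to_numpy(object),
        "M": m,
        "A": a,
        "weight": weight,
        "is_spike": False,
    })
    return NormalizedArray(array_id=scan.array_id, species=scan.species,
                           condition=scan.condition, data=data)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def weighted_loess(x: np.ndarray, y: np.ndarray, w: np.ndarray, *,
                   span: float = 0.4, iterations: int = 4,
                   n_grid: int = 80) -> np.ndarray:
    """Robust weighted local-linear loess, evaluated at every x.

    Fit on a quantile grid with tricube distance weights times prior
    weights times Tukey-biweight robustness weights, then interpolated.
    """
    m = w > 0
    xs, ys, ws = x[m], y[m], w[m]
    if xs.size < 10:
        raise EstimationError("too few weighted points for loess")
    grid = np.unique(np.quantile(xs, np.linspace(0.0, 1.0, min(n_grid, xs.size))))
    k = max(int(np.ceil(span * xs.size)), 8)
    k = min(k, xs.size)
    rob = np.ones_like(ys)
    fit_grid = np.zeros_like(grid)
    for _ in range(iterations + 1):
        for j, x0 in enumerate(grid):
            d = np.abs(xs - x0)
            h = max(np.partition(d, k - 1)[k - 1], 1e-9)
            tri = np.clip(1.0 - (d / h) ** 3, 0.0, 1.0) ** 3
            wt = tri * ws * rob
            sw = wt.sum()
            if sw <= 0:
                fit_grid[j] = 0.0
                continue
            xm = float((wt * xs).sum() / sw)
            ym = float((wt * ys).sum() / sw)
            sxx = float((wt * (xs - xm) ** 2).sum())
            slope = float((wt * (xs - xm) * (ys - ym)).sum() / sxx) if sxx > 1e-12 else 0.0
            fit_grid[j] = ym + slope * (x0 - xm)
        resid = ys - np.interp(xs, grid, fit_grid)
        s = float(np.median(np.abs(resid)))
        if s <= 0:
            break
        rob = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, 1.0) ** 2
    return np.interp(x, grid, fit_grid)


def spike_weighted_loess(
    arr: NormalizedArray,
    probes: ProbeAnnotation,
    spike_weight: float = 50.0,
    span: float = 0.4,
    iterations: int = 4,
    anchor: bool = True,
) -> NormalizedArray:
    """Spike-aware loess normalization of one array.

    1. loess of (M - expected_spike_logratio·1{spike}) on A with weights
       (regular 1, spike ``spike_weight``, bad 0), robust iterations;
    2. subtract the fitted curve from every M;
    3. affine anchor: shift so the weighted median of spike M equals the
       weighted median of the expected spike log-ratios.

    ``spike_weight=1, anchor=False`` reproduces the naive equal-weight
    loess that regresses a genuine global shift away.
    """
    data = arr.data.copy()
    ptab = probes.table.set_index("probe_id")
    known = data["probe_id"].isin(ptab.index)
    is_spike = np.zeros(len(data), dtype=bool)
    expected = np.zeros(len(data))
    idx = data.loc[known, "probe_id"]
    is_spike[known.to_numpy()] = ptab.loc[idx, "is_spike"].to_numpy(bool)
    exp_vals = ptab.loc[idx, "expected_spike_logratio"].to_numpy(float)
    expected[known.to_numpy()] = np.where(np.isfinite(exp_vals), exp_vals, 0.0)
    data["is_spike"] = is_spike

    m = data["M"].to_numpy(float)
    a = data["A"].to_numpy(float)
    base_w = data["weight"].to_numpy(float)
    spike_mask = is_spike & (base_w > 0)
    if spike_mask.sum() < 10:
        raise NormalizationError(
            f"array {arr.array_id}: {int(spike_mask.sum())} usable spikes < 10")

    usable = base_w > 0
    lo, hi = np.quantile(a[usable], [0.1, 0.9])
    covers = a[spike_mask].min() <= lo and a[spike_mask].max() >= hi
    fit = np.zeros_like(m)
    if covers:
        # Align the spike population onto the gene cloud before fitting:
        # genes sit at (global shift + bias(A)), spikes at (expected +
        # bias(A)).  Fitting one curve through the raw mixture would bend
        # wherever the spike/gene weight mix changes along A; removing the
        # robust between-population offset first makes the mixture
        # homogeneous so the loess estimates only the A-dependent trend.
        # The affine anchor below restores the absolute spike level.
        gene_mask = usable & ~is_spike
        delta0 = (_weighted_median(m[spike_mask] - expected[spike_mask],
                                   base_w[spike_mask])
                  - _weighted_median(m[gene_mask], base_w[gene_mask]))
        y = m - (expected + delta0) * is_spike
        w = base_w * np.where(is_spike, spike_weight, 1.0)
        fit = weighted_loess(a, y, w, span=span, iterations=iterations)
    else:
        warnings.warn(
            f"array {arr.array_id}: spikes do not span the central 80% of the "
            "A range; falling back to anchor-only normalization",
            stacklevel=2)
        if not anchor:
            raise NormalizationError(
                f"array {arr.array_id}: spikes span too little of the A range "
                "and anchoring is disabled")

    m_new = m - fit
    offset = None
    if anchor:
        w_spike = base_w[spike_mask] * spike_weight
        delta = (_weighted_median(m_new[spike_mask], w_spike)
                 - _weighted_median(expected[spike_mask], w_spike))
        m_new = m_new - delta
        offset = abs(_weighted_median(m_new[spike_mask], w_spike)
                     - _weighted_median(expected[spike_mask], w_spike))

    data["M"] = m_new
    return NormalizedArray(array_id=arr.array_id, species=arr.species,
                           condition=arr.condition, data=data,
                           spike_anchor_offset=offset)


def normalize_scan(scan: TwoColorScan, probes: ProbeAnnotation, *,
                   spike_weight: float = 50.0, span: float = 0.4,
                   iterations: int = 4, anchor: bool = True) -> NormalizedArray:
    """Full per-array path: estimate params, correct, compute MA, loess."""
    params_red = estimate_normexp(scan, "red")
    params_green = estimate_normexp(scan, "green")
    arr = compute_ma(scan, params_red, params_green)
    return spike_weighted_loess(arr, probes, spike_weight=spike_weight,
                                span=span, iterations=iterations, anchor=anchor)
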