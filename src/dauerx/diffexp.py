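"""Gene-level differential expression on the common-reference design.

Probes are summarized to genes by weighted median, a per-gene two-group
linear model is fit on the log-ratios to the mix-stage reference
(dauer-vs-exit contrast = difference of condition means; dauer-vs-mix =
the dauer mean itself), gene-wise variances are shrunk toward an
empirically estimated prior (moments method on log variances), and
calls are made at a Benjamini-Hochberg FDR threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .arrayio import ProbeAnnotation
from .errors import EstimationError, ValidationError
from .normalize import NormalizedArray

log = logging.getLogger(__name__)


@dataclass
class GeneExpressionSet:
    """genes x arrays matrix of M values with per-cell weights."""

    M: pd.DataFrame          # index gene_id, columns array_id
    weights: pd.DataFrame    # same shape; number of contributing probes
    arrays: pd.DataFrame     # array_id, species, condition


@dataclass
class EBayesHyper:
    d0: float       # prior degrees of freedom, may be +inf
    s0_sq: float    # prior variance

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.s0_sq > 0):
            raise ValidationError("EBayes hyperparameters must be positive")


@dataclass
class DEResult:
    """Per-gene table plus the per-species summary counts.

    ``table`` columns: gene_id, logFC_dauer_vs_exit, logFC_dauer_vs_mix,
    s_g_sq, d_g, t_mod, p, fdr, call.
    """

    species: str
    table: pd.DataFrame
    hyper: EBayesHyper | None = None
    fdr_threshold: float = 0.05

    @property
    def summary(self) -> dict:
        calls = self.table["call"]
        n_up = int((calls == "up").sum())
        n_down = int((calls == "down").sum())
        return {
            "species": self.species,
            "n_up": n_up,
            "n_down": n_down,
            "n_total": n_up + n_down,
            "n_on_array": int(len(self.table)),
        }

    def calls(self) -> pd.Series:
        return pd.Series(self.table["call"].values, index=self.table["gene_id"].values)

    def logfc(self) -> pd.Series:
        return pd.Series(self.table["logFC_dauer_vs_exit"].values,
                         index=self.table["gene_id"].values)


# ---------------------------------------------------------------------------
# probe -> gene summarization
# ---------------------------------------------------------------------------

def summarize_probes(arrays: list[NormalizedArray],
                     probes: ProbeAnnotation) -> GeneExpressionSet:
    """Per gene per array: median M over usable probes; weight = probe count."""
    gene_map = probes.gene_map()
    frames_m = {}
    frames_w = {}
    meta = []
    for arr in arrays:
        d = arr.data
        d = d[(~d["is_spike"]) & d["probe_id"].isin(gene_map.index)]
        usable = d[d["weight"] > 0].copy()
        usable["gene_id"] = gene_map.loc[usable["probe_id"]].to_numpy()
        grouped = usable.groupby("gene_id")["M"]
        frames_m[arr.array_id] = grouped.median()
        frames_w[arr.array_id] = grouped.size().astype(float)
        meta.append((arr.array_id, arr.species, arr.condition))
    M = pd.DataFrame(frames_m)
    W = pd.DataFrame(frames_w).reindex(M.index).fillna(0.0)
    dropped = M.index[W.sum(axis=1) == 0]
    if len(dropped):
        log.warning("summarize_probes: %d genes with no usable probe on any array "
                    "excluded", len(dropped))
        M = M.drop(index=dropped)
        W = W.drop(index=dropped)
    M = M.fillna(0.0)   # cells with weight 0 are ignored downstream
    arrays_df = pd.DataFrame(meta, columns=["array_id", "species", "condition"])
    return GeneExpressionSet(M=M, weights=W, arrays=arrays_df)


# ---------------------------------------------------------------------------
# per-gene linear model
# ---------------------------------------------------------------------------

def fit_gene_model(ges: GeneExpressionSet) -> pd.DataFrame:
    """Weighted two-group fit per gene.

    Returns a DataFrame indexed by gene with beta_dauer, beta_exit,
    logFC_dauer_vs_exit, logFC_dauer_vs_mix, s_g_sq, d_g, v_contrast and
    an ``estimable`` flag (>= 2 usable arrays per condition).
    """
    conds = ges.arrays.set_index("array_id")["condition"]
    cols = list(ges.M.columns)
    cond_vec = conds.loc[cols].to_numpy()
    M = ges.M.to_numpy(float)
    W = ges.weights.to_numpy(float)

    out = {}
    masks = {c: (cond_vec == c) for c in ("dauer", "exit")}
    betas = {}
    counts = {}
    for c, cmask in masks.items():
        Wc = W[:, cmask]
        Mc = M[:, cmask]
        sw = Wc.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            betas[c] = np.where(sw > 0, (Wc * Mc).sum(axis=1) / np.where(sw > 0, sw, 1.0),
                                np.nan)
        counts[c] = (Wc > 0).sum(axis=1)

    n_d, n_e = counts["dauer"], counts["exit"]
    d_g = n_d + n_e - 2
    rss = np.zeros(M.shape[0])
    for c, cmask in masks.items():
        resid = M[:, cmask] - betas[c][:, None]
        rss += (W[:, cmask] * resid**2).sum(axis=1)
    estimable = (n_d >= 2) & (n_e >= 2) & (d_g > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s_g_sq = np.where(estimable, rss / np.where(d_g > 0, d_g, 1), np.nan)
        v = np.where(estimable, 1.0 / np.maximum(n_d, 1) + 1.0 / np.maximum(n_e, 1),
                     np.nan)
    out = pd.DataFrame({
        "beta_dauer": betas["dauer"],
        "beta_exit": betas["exit"],
        "logFC_dauer_vs_exit": betas["dauer"] - betas["exit"],
        "logFC_dauer_vs_mix": betas["dauer"],
        "s_g_sq": s_g_sq,
        "d_g": d_g.astype(float),
        "v_contrast": v,
        "estimable": estimable,
    }, index=ges.M.index)
    n_bad = int((~estimable).sum())
    if n_bad:
        log.warning("fit_gene_model: %d genes unestimable (fewer than 2 usable "
                    "arrays in a condition)", n_bad)
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_hyperparameters(s_g_sq: np.ndarray, d_g: np.ndarray) -> EBayesHyper:
    """Moments-method fit of the scaled-F model for gene variances.

    Works on e_g = log s_g^2 - psi(d_g/2) + log(d_g/2): the excess of the
    empirical variance of e over the expected digamma noise identifies the
    prior degrees of freedom via the inverse trigamma.
    """
    ok = np.isfinite(s_g_sq) & (s_g_sq > 0) & np.isfinite(d_g) & (d_g > 0)
    if ok.sum() < 50:
        raise EstimationError(
            f"only {int(ok.sum())} genes with positive variance; >= 50 required")
    s2 = s_g_sq[ok]
    d = d_g[ok]
    e = np.log(s2) - digamma(d / 2.0) + np.log(d / 2.0)
    ebar = float(e.mean())
    n = e.size
    evar = float(((e - ebar) ** 2).sum() / (n - 1))
    rhs = evar - float(np.mean(polygamma(1, d / 2.0)))
    if rhs <= 0:
        d0 = math.inf
        s0_sq = math.exp(ebar)
    else:
        d0 = 2.0 * _trigamma_inverse(rhs)
        s0_sq = math.exp(ebar + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return EBayesHyper(d0=d0, s0_sq=s0_sq)


def ebayes_moderate(fits: pd.DataFrame,
                    hyper: EBayesHyper | None = None) -> tuple[EBayesHyper, pd.DataFrame]:
    """Moderated t-statistics and p-values for the dauer-vs-exit contrast.

    Genes with zero sample variance are excluded from hyperparameter
    estimation but still moderated with the fitted prior.
    """
    est = fits[fits["estimable"]]
    s2 = est["s_g_sq"].to_numpy(float)
    d = est["d_g"].to_numpy(float)
    if hyper is None:
        if not (np.nanmax(s2, initial=0.0) > 0):
            raise EstimationError("all gene variances are zero; degenerate input")
        hyper = estimate_hyperparameters(s2, d)

    d0, s0_sq = hyper.d0, hyper.s0_sq
    if math.isinf(d0):
        s_tilde_sq = np.full_like(s2, s0_sq)
        df_total = np.full_like(d, np.inf)
    elif d0 == 0:
        s_tilde_sq = s2.copy()
        df_total = d.copy()
    else:
        s_tilde_sq = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    v = est["v_contrast"].to_numpy(float)
    logfc = est["logFC_dauer_vs_exit"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mod = logfc / np.sqrt(s_tilde_sq * v)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    out = fits.copy()
    out["s_tilde_sq"] = np.nan
    out["t_mod"] = np.nan
    out["p"] = np.nan
    out.loc[est.index, "s_tilde_sq"] = s_tilde_sq
    out.loc[est.index, "t_mod"] = t_mod
    out.loc[est.index, "p"] = p
    return hyper, out


def adjust_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def call_de(moderated: pd.DataFrame, species: str,
            fdr_threshold: float = 0.05,
            hyper: EBayesHyper | None = None) -> DEResult:
    """Attach BH-FDR values and up/down/ns calls; build the summary row."""
    table = moderated.copy()
    table["fdr"] = np.nan
    has_p = table["p"].notna()
    table.loc[has_p, "fdr"] = adjust_fdr(table.loc[has_p, "p"].to_numpy())
    logfc = table["logFC_dauer_vs_exit"]
    sig = table["fdr"] <= fdr_threshold
    call = np.where(sig & (logfc > 0), "up",
                    np.where(sig & (logfc < 0), "down", "ns"))
    zero_sig = int((sig & (logfc == 0)).sum())
    if zero_sig:
        log.warning("call_de: %d significant genes with logFC exactly 0 called ns",
                    zero_sig)
    table["call"] = call
    table = table.reset_index().rename(columns={"index": "gene_id"})
    return DEResult(species=species, table=table, hyper=hyper,
                    fdr_threshold=fdr_threshold)


def run_diffexp(arrays: list[NormalizedArray], probes: ProbeAnnotation,
                species: str, fdr_threshold: float = 0.05) -> DEResult:
    """summarize -> fit -> moderate -> call for one species."""
    species_arrays = [a for a in arrays if a.species == species]
    ges = summarize_probes(species_arrays, probes)
    fits = fit_gene_model(ges)
    hyper, moderated = ebayes_moderate(fits)
    return call_de(moderated, species, fdr_threshold=fdr_threshold, hyper=hyper)
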