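"""Cross-species comparison of differential expression over 1:1 orthologs.

Joins the two species' DE results on ortholog pairs, labels each pair
with a conservation class (1 concordant-significant, 2 discordant-
significant, 3 species-A-only, 4 species-B-only), tests the overlap of
the significant sets with a one-sided Fisher exact test, and reports
Pearson correlations of the fold changes on the relevant subsets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import DEResult

log = logging.getLogger(__name__)

_QUADRANTS = {(1, 1): "I", (-1, 1): "II", (-1, -1): "III", (1, -1): "IV"}


@dataclass
class OrthologComparison:
    """Per-pair join: gene_a, gene_b, logFC_a, logFC_b, sig_a, sig_b,
    class_label in {1,2,3,4,none}, quadrant in {I..IV,none}."""

    table: pd.DataFrame

    def class_counts(self) -> dict[str, int]:
        counts = self.table["class_label"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in ("1", "2", "3", "4", "none")}

    def quadrant_counts(self) -> dict[str, int]:
        counts = self.table["quadrant"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in ("I", "II", "III", "IV")}


@dataclass
class OverlapTest:
    a: int            # significant in both
    b: int            # species A only
    c: int            # species B only
    d: int            # neither
    odds_ratio: float
    p: float


@dataclass
class CorrelationReport:
    r_all: float | None
    n_all: int
    r_both_sig: float | None
    n_both_sig: int
    r_class1: float | None
    n_class1: int
    r_class2: float | None
    n_class2: int

    def as_dict(self) -> dict:
        return {
            "r_all": self.r_all, "n_all": self.n_all,
            "r_both_sig": self.r_both_sig, "n_both_sig": self.n_both_sig,
            "r_class1": self.r_class1, "n_class1": self.n_class1,
            "r_class2": self.r_class2, "n_class2": self.n_class2,
        }


def classify_orthologs(de_a: DEResult, de_b: DEResult,
                       pairs: list[tuple[str, str]],
                       fdr_threshold: float = 0.05) -> OrthologComparison:
    """Join DE results over the pairs and assign class and quadrant labels."""
    ta = de_a.table.set_index("gene_id")
    tb = de_b.table.set_index("gene_id")
    rows = []
    dropped = 0
    for a, b in pairs:
        if a not in ta.index or b not in tb.index:
            dropped += 1
            continue
        fa = float(ta.at[a, "logFC_dauer_vs_exit"])
        fb = float(tb.at[b, "logFC_dauer_vs_exit"])
        qa = ta.at[a, "fdr"]
        qb = tb.at[b, "fdr"]
        sig_a = bool(pd.notna(qa) and qa <= fdr_threshold)
        sig_b = bool(pd.notna(qb) and qb <= fdr_threshold)
        label, quadrant = "none", "none"
        if sig_a and sig_b:
            sa, sb = int(np.sign(fa)), int(np.sign(fb))
            if sa == 0 or sb == 0:
                log.warning("pair (%s, %s): significant gene with logFC exactly 0; "
                            "class none", a, b)
            else:
                label = "1" if sa == sb else "2"
                quadrant = _QUADRANTS[(sa, sb)]
        elif sig_a:
            label = "3"
        elif sig_b:
            label = "4"
        rows.append((a, b, fa, fb, sig_a, sig_b, label, quadrant))
    if dropped:
        log.warning("classify_orthologs: %d pairs dropped (gene missing from a "
                    "DE result)", dropped)
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "logFC_a", "logFC_b",
                                        "sig_a", "sig_b", "class_label", "quadrant"])
    return OrthologComparison(table=table)


def fisher_from_counts(a: int, b: int, c: int, d: int,
                       alternative: str = "greater") -> OverlapTest:
    """One-sided (enrichment) Fisher exact test on a 2x2 table.

    The upper-tail hypergeometric probability P[X >= a] with margins
    (a+b, a+c) over a+b+c+d; ``alternative='two-sided'`` available.
    """
    n = a + b + c + d
    if min(a + b, a + c) == 0 or min(c + d, b + d) == 0:
        warnings.warn("degenerate 2x2 margin; Fisher p set to 1", stacklevel=2)
        p = 1.0
    elif alternative == "greater":
        p = float(stats.hypergeom.sf(a - 1, n, a + b, a + c))
    else:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        p = float(p)
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = float("inf") if a * d > 0 else float("nan")
    return OverlapTest(a=a, b=b, c=c, d=d, odds_ratio=odds, p=p)


def overlap_fisher(cmp: OrthologComparison,
                   alternative: str = "greater") -> OverlapTest:
    """2x2 overlap test (sig_a x sig_b) over the joined pairs."""
    t = cmp.table
    a = int((t["sig_a"] & t["sig_b"]).sum())
    b = int((t["sig_a"] & ~t["sig_b"]).sum())
    c = int((~t["sig_a"] & t["sig_b"]).sum())
    d = int((~t["sig_a"] & ~t["sig_b"]).sum())
    return fisher_from_counts(a, b, c, d, alternative=alternative)


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def correlation_report(cmp: OrthologComparison) -> CorrelationReport:
    t = cmp.table
    subsets = {
        "all": t,
        "both_sig": t[t["sig_a"] & t["sig_b"]],
        "class1": t[t["class_label"] == "1"],
        "class2": t[t["class_label"] == "2"],
    }
    r = {}
    n = {}
    for name, sub in subsets.items():
        x = sub["logFC_a"].to_numpy(float)
        y = sub["logFC_b"].to_numpy(float)
        r[name] = _pearson(x, y)
        n[name] = int(len(sub))
    return CorrelationReport(
        r_all=r["all"], n_all=n["all"],
        r_both_sig=r["both_sig"], n_both_sig=n["both_sig"],
        r_class1=r["class1"], n_class1=n["class1"],
        r_class2=r["class2"], n_class2=n["class2"],
    )
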