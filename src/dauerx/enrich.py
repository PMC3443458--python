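"""Annotation-layer analyses on top of the cross-species DE results.

Four layers: ontology-term enrichment with DAG propagation and 1:1
annotation transfer, expression-cluster enrichment (per-column BH,
-log10 score matrix), protein-family median fold-change profiles, and
pathway up/down/no-change tabulation — plus a two-sample
Kolmogorov-Smirnov shift test for an arbitrary gene subset (pioneer
genes).  Term and cluster tests are one-sided hypergeometric (Fisher)
tests; term enrichment deliberately applies no multiple-testing
correction, cluster enrichment applies BH within each column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .arrayio import AnnotationBundle
from .diffexp import DEResult, adjust_fdr
from .errors import ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# annotation transfer and propagation
# ---------------------------------------------------------------------------

def transfer_annotations(bundle: AnnotationBundle,
                         pairs: list[tuple[str, str]]) -> AnnotationBundle:
    """Species-B bundle: each B gene inherits exactly the term/cluster/pathway
    sets of its 1:1 ortholog; unpaired B genes stay unannotated."""
    a2b = dict(pairs)
    gene2term = {a2b[a]: set(terms) for a, terms in bundle.gene2term.items()
                 if a in a2b}
    clusters = {cid: {a2b[g] for g in members if g in a2b}
                for cid, members in bundle.clusters.items()}
    pathway2gene = {pid: {a2b[g] for g in members if g in a2b}
                    for pid, members in bundle.pathway2gene.items()}
    return AnnotationBundle(
        ontology=bundle.ontology,
        gene2term=gene2term,
        clusters=clusters,
        gene2domain={},           # domains are species-specific, not transferred
        pathway2gene=pathway2gene,
        pioneer_genes=set(bundle.pioneer_genes),
    )


def propagate_to_ancestors(bundle: AnnotationBundle) -> dict[str, set[str]]:
    """Close gene→term over is_a/part_of ancestors (true-path rule)."""
    graph = bundle.ontology
    ancestors: dict[str, set[str]] = {}

    def anc(term: str) -> set[str]:
        if term not in ancestors:
            ancestors[term] = nx.descendants(graph, term)  # child->parent edges
        return ancestors[term]

    closed: dict[str, set[str]] = {}
    for gene, terms in bundle.gene2term.items():
        full = set(terms)
        for t in terms:
            full |= anc(t)
        closed[gene] = full
    return closed


# ---------------------------------------------------------------------------
# term enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    annotated: int
    significant: int
    expected: float
    p: float


def term_enrichment(study: set[str], background: set[str],
                    closed_map: dict[str, set[str]],
                    term_names: dict[str, str] | None = None,
                    min_term_size: int = 1,
                    max_p: float = 0.05) -> list[EnrichmentRow]:
    """One-sided hypergeometric enrichment per term, no multiplicity correction.

    The background is restricted to genes carrying at least one
    annotation; rows with p <= ``max_p`` are returned sorted by p.
    """
    if not study <= background:
        raise ValidationError("study set must be a subset of the background")
    bg = {g for g in background if closed_map.get(g)}
    st = study & bg
    if not st:
        warnings.warn("empty (annotated) study set; no enrichment computed",
                      stacklevel=2)
        return []
    term2bg: dict[str, int] = {}
    term2sig: dict[str, int] = {}
    for g in bg:
        in_study = g in st
        for t in closed_map[g]:
            term2bg[t] = term2bg.get(t, 0) + 1
            if in_study:
                term2sig[t] = term2sig.get(t, 0) + 1
    n_bg, n_st = len(bg), len(st)
    rows = []
    for term, annotated in term2bg.items():
        if annotated < min_term_size:
            continue
        k = term2sig.get(term, 0)
        p = float(stats.hypergeom.sf(k - 1, n_bg, annotated, n_st))
        if p <= max_p:
            rows.append(EnrichmentRow(
                term_id=term,
                term_name=(term_names or {}).get(term, term),
                annotated=annotated,
                significant=k,
                expected=annotated * n_st / n_bg,
                p=p,
            ))
    rows.sort(key=lambda r: (r.p, r.term_id))
    return rows


def enrichment_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.term_id, r.term_name, r.annotated, r.significant, r.expected, r.p)
         for r in rows],
        columns=["term_id", "term_name", "annotated", "significant",
                 "expected", "p"])


# ---------------------------------------------------------------------------
# expression-cluster enrichment
# ---------------------------------------------------------------------------

def cluster_enrichment(
    direction_sets: dict[str, set[str]],
    clusters_for_column: dict[str, dict[str, set[str]]],
    background_for_column: dict[str, set[str]],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Score matrix: clusters x direction columns; -log10 BH-adjusted
    one-sided Fisher p, zeroed where the adjusted p exceeds the threshold.

    BH is applied within each column (each column is its own test family).
    """
    all_clusters = sorted({cid for cmap in clusters_for_column.values()
                           for cid in cmap})
    columns = sorted(direction_sets)
    scores = pd.DataFrame(0.0, index=all_clusters, columns=columns)
    for col in columns:
        bg = background_for_column[col]
        study = direction_sets[col] & bg
        cmap = clusters_for_column[col]
        tested = []
        pvals = []
        for cid in all_clusters:
            members = cmap.get(cid, set()) & bg
            if not members:
                log.warning("cluster %s has no background members in column %s; "
                            "skipped", cid, col)
                continue
            k = len(members & study)
            p = float(stats.hypergeom.sf(k - 1, len(bg), len(members), len(study)))
            tested.append(cid)
            pvals.append(p)
        if not tested:
            continue
        adj = adjust_fdr(np.array(pvals))
        for cid, q in zip(tested, adj):
            if q <= fdr_threshold:
                scores.at[cid, col] = float(-np.log10(max(q, 1e-300)))
    scores.index.name = "cluster_id"
    return scores


# ---------------------------------------------------------------------------
# protein-family fold-change profiles
# ---------------------------------------------------------------------------

def pfam_family_profile(
    de_a: DEResult, de_b: DEResult,
    gene2domain_a: dict[str, set[str]],
    gene2domain_b: dict[str, set[str]],
    min_members: int = 5,
) -> tuple[pd.DataFrame, float | None]:
    """Median dauer-vs-exit log2FC per domain family in each species.

    A family qualifies with >= ``min_members`` members on each array
    (genes present in the DE results); a gene contributes to every
    domain it carries.  Returns the family table and the Pearson r of
    the two median columns (None if < 3 qualifying families).
    """
    lf_a = de_a.logfc()
    lf_b = de_b.logfc()

    def family_values(g2d: dict[str, set[str]], lf: pd.Series) -> dict[str, list[float]]:
        fams: dict[str, list[float]] = {}
        for gene, domains in g2d.items():
            if gene not in lf.index:
                continue
            val = float(lf[gene])
            for dom in domains:
                fams.setdefault(dom, []).append(val)
        return fams

    fams_a = family_values(gene2domain_a, lf_a)
    fams_b = family_values(gene2domain_b, lf_b)
    rows = []
    for dom in sorted(set(fams_a) & set(fams_b)):
        va, vb = fams_a[dom], fams_b[dom]
        if len(va) >= min_members and len(vb) >= min_members:
            rows.append((dom, len(va), len(vb),
                         float(np.median(va)), float(np.median(vb))))
    table = pd.DataFrame(rows, columns=["domain_id", "n_a", "n_b",
                                        "median_logfc_a", "median_logfc_b"])
    if len(table) < 3:
        return table, None
    x = table["median_logfc_a"].to_numpy()
    y = table["median_logfc_b"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return table, None
    return table, float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# pathway tabulation
# ---------------------------------------------------------------------------

def kegg_tabulate(de_a: DEResult, de_b: DEResult,
                  pathway2gene: dict[str, set[str]],
                  pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Per pathway and species: up / down / no-change counts among the
    member 1:1 orthologs (membership defined on species-A genes)."""
    a2b = dict(pairs)
    calls_a = de_a.calls()
    calls_b = de_b.calls()
    rows = []
    for pid in sorted(pathway2gene):
        members = [a for a in pathway2gene[pid] if a in a2b]
        counts = {"cel": {"up": 0, "down": 0, "no_change": 0},
                  "ppa": {"up": 0, "down": 0, "no_change": 0}}
        for a in members:
            b = a2b[a]
            ca = calls_a.get(a)
            cb = calls_b.get(b)
            if ca is None or cb is None:
                continue
            counts["cel"][ca if ca in ("up", "down") else "no_change"] += 1
            counts["ppa"][cb if cb in ("up", "down") else "no_change"] += 1
        rows.append((pid,
                     counts["cel"]["up"], counts["cel"]["down"], counts["cel"]["no_change"],
                     counts["ppa"]["up"], counts["ppa"]["down"], counts["ppa"]["no_change"]))
    return pd.DataFrame(rows, columns=["pathway_id", "cel_up", "cel_down",
                                       "cel_no_change", "ppa_up", "ppa_down",
                                       "ppa_no_change"])


# ---------------------------------------------------------------------------
# subset distribution-shift test
# ---------------------------------------------------------------------------

@dataclass
class KSReport:
    D: float
    p: float
    direction: str            # subset_higher / subset_lower / none
    n_subset: int
    n_complement: int


def subset_shift_test(logfc: dict[str, float] | pd.Series,
                      subset: set[str],
                      min_size: int = 20) -> tuple[KSReport, pd.DataFrame]:
    """Two-sample KS test of subset vs complement fold-change distributions.

    Also returns the two empirical CDFs evaluated on the pooled sorted
    values (columns: value, cdf_subset, cdf_complement).
    """
    if isinstance(logfc, dict):
        logfc = pd.Series(logfc)
    in_sub = logfc.index.isin(subset)
    sub = logfc[in_sub].to_numpy(float)
    comp = logfc[~in_sub].to_numpy(float)
    if sub.size < min_size or comp.size < min_size:
        raise ValidationError(
            f"subset ({sub.size}) and complement ({comp.size}) must each have "
            f">= {min_size} genes")
    res = stats.ks_2samp(sub, comp, alternative="two-sided", method="auto")
    med_s, med_c = float(np.median(sub)), float(np.median(comp))
    if med_s > med_c:
        direction = "subset_higher"
    elif med_s < med_c:
        direction = "subset_lower"
    else:
        direction = "none"
    pooled = np.sort(np.concatenate([sub, comp]))
    cdf_sub = np.searchsorted(np.sort(sub), pooled, side="right") / sub.size
    cdf_comp = np.searchsorted(np.sort(comp), pooled, side="right") / comp.size
    table = pd.DataFrame({"value": pooled, "cdf_subset": cdf_sub,
                          "cdf_complement": cdf_comp})
    report = KSReport(D=float(res.statistic), p=float(res.pvalue),
                      direction=direction, n_subset=int(sub.size),
                      n_complement=int(comp.size))
    return report, table
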