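"""Synthetic two-species study generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
common-reference two-color design with dye swaps, a global mRNA-fraction
repression ``f`` in the dauer samples (spike-ins deliberately NOT scaled
by ``f``, so they anchor the normalization), intensity-dependent dye
bias, additive-Normal background plus multiplicative-lognormal signal
noise (the exact background-correction model), correlated cross-species
effect structure on 1:1 orthologs, and planted enrichments in every
annotation layer.

Intensity model per spot and channel::

    X = B + S
    B ~ Normal(bg_mu, bg_sigma^2) truncated at 0
    S = a * 2^(+-dye_bias(A0)/2) * exp(Normal(0, signal_log_sd))

where ``a`` is the true abundance (reference: gene base; sample:
base * 2^effect * f for dauer mRNA; spikes identical in both channels)
and ``A0`` the noise-free mean log2 abundance.  The red channel gets
``+bias/2`` and green ``-bias/2`` regardless of which sample is in which
channel, so the bias is a dye artifact that flips under dye swap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .arrayio import (
    AnnotationBundle,
    HitTable,
    ProbeAnnotation,
    TwoColorScan,
)
from .errors import ConfigError

SPECIES_A = "cel"
SPECIES_B = "ppa"


@dataclass
class ClassCounts:
    """Planted 1:1-ortholog effect classes (cross-species quadrant design)."""

    n_class1_up: int = 40       # significant in both, both up
    n_class1_down: int = 40     # significant in both, both down
    n_class2: int = 40          # significant in both, opposite signs
    n_cel_only: int = 60        # significant in species A only
    n_ppa_only: int = 120       # significant in species B only

    @property
    def total(self) -> int:
        return (self.n_class1_up + self.n_class1_down + self.n_class2
                + self.n_cel_only + self.n_ppa_only)


@dataclass
class PlantedEnrichments:
    """Sizes and fold-enrichments of the planted annotation-layer signals."""

    term_id: str = "GO:9000001"
    term_size: int = 25
    term_fold: float = 10.0
    n_background_terms: int = 60
    background_term_size: int = 25
    cluster_id: str = "CL:planted_cel_dauer"
    cluster_size: int = 25
    cluster_fold: float = 10.0
    n_background_clusters: int = 20
    pathway_id: str = "path:planted_repressed"
    pathway_n_down: int = 10
    pathway_n_null: int = 10
    n_background_pathways: int = 10


@dataclass
class SyntheticStudyConfig:
    n_genes_per_species: int = 2000
    n_orthologs: int = 600
    probes_per_gene: int = 2
    n_spikes: int = 40
    replicates_per_contrast: int = 4      # two per dye orientation
    repression_factor: float = 0.5        # dauer mRNA fraction vs reference
    class_counts: ClassCounts = field(default_factory=ClassCounts)
    effect_size: float = 1.5              # log2 units
    effect_jitter_sd: float = 0.3
    cross_species_fc_correlation: float = 0.5   # copula rho for class-1 magnitudes
    dye_bias_coefficients: tuple[float, ...] = (0.0,)  # polynomial in A, low->high order
    bg_mu: float = 100.0
    bg_sigma: float = 10.0
    signal_mean_alpha: float = 3000.0     # exponential mean of gene base abundance
    signal_log_sd: float = 0.18           # natural-log sd of multiplicative noise
    bad_spot_rate: float = 0.01
    weak_pair_fraction: float = 0.05      # orthologs scored below the bit cutoff
    decoy_fraction: float = 0.3
    n_effect_domains: int = 40            # PFAM-style families with planted effects
    domain_members: int = 8
    domain_effect_sd: float = 1.0
    domain_effect_correlation: float = 0.5
    n_pioneers: int = 200
    pioneer_shift: float = 1.0            # added to species-B pioneer effects
    planted: PlantedEnrichments = field(default_factory=PlantedEnrichments)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.repression_factor <= 1.0):
            raise ConfigError("repression_factor must be in (0, 1]")
        for name in ("n_genes_per_species", "n_orthologs", "probes_per_gene",
                     "n_spikes", "replicates_per_contrast"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.class_counts.total > self.n_orthologs:
            raise ConfigError("class counts exceed n_orthologs")
        if self.n_orthologs > self.n_genes_per_species:
            raise ConfigError("n_orthologs exceeds n_genes_per_species")
        if self.replicates_per_contrast % 2:
            raise ConfigError("replicates_per_contrast must be even (paired dye flips)")


@dataclass
class GroundTruth:
    """Per-gene and per-pair simulation truth.

    ``genes[species]`` columns: gene_id, effect (biological log2 dauer-vs-exit
    effect), true_log2fc_dauer_vs_exit, true_log2fc_dauer_vs_mix (both on the
    measured, repression-inclusive scale), de_label in {up, down, null}.
    ``pairs`` columns: gene_a, gene_b, class_label in {1,2,3,4,none},
    rbh_recoverable (bool; False for pairs scored below the bit cutoff).
    """

    genes: dict[str, pd.DataFrame]
    pairs: pd.DataFrame
    planted_term: str
    planted_cluster: str
    planted_pathway: str
    repression_factor: float

    def de_genes(self, species: str, direction: str | None = None) -> set[str]:
        df = self.genes[species]
        if direction is None:
            mask = df["de_label"] != "null"
        else:
            mask = df["de_label"] == direction
        return set(df.loc[mask, "gene_id"])

    def recoverable_pairs(self) -> set[tuple[str, str]]:
        df = self.pairs[self.pairs["rbh_recoverable"]]
        return set(zip(df["gene_a"], df["gene_b"]))


@dataclass
class SyntheticStudy:
    config: SyntheticStudyConfig
    scans: list[TwoColorScan]
    probes: dict[str, ProbeAnnotation]
    hits_ab: HitTable
    hits_ba: HitTable
    bundle: AnnotationBundle
    truth: GroundTruth
    #: species-B PFAM-style domain assignments (species A's live in bundle)
    gene2domain_b: dict[str, set[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# effect layout
# ---------------------------------------------------------------------------

def _gene_ids(species: str, n: int) -> list[str]:
    return [f"{species}_g{i:05d}" for i in range(n)]


def _draw_effects(config: SyntheticStudyConfig, rng: np.random.Generator
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Lay out per-gene biological effects and ortholog class labels."""
    n = config.n_genes_per_species
    genes_a = _gene_ids(SPECIES_A, n)
    genes_b = _gene_ids(SPECIES_B, n)
    eff_a = np.zeros(n)
    eff_b = np.zeros(n)
    cc = config.class_counts
    n_orth = config.n_orthologs
    labels = np.array(["none"] * n_orth, dtype=object)

    idx = 0
    mu, sd, rho = config.effect_size, config.effect_jitter_sd, config.cross_species_fc_correlation
    cov = np.array([[sd**2, rho * sd**2], [rho * sd**2, sd**2]])

    def correlated_magnitudes(k: int) -> np.ndarray:
        m = rng.multivariate_normal([mu, mu], cov, size=k)
        return np.maximum(np.abs(m), 0.25)   # keep effects well off zero

    for sign, count, label in ((1.0, cc.n_class1_up, "1"), (-1.0, cc.n_class1_down, "1")):
        mags = correlated_magnitudes(count)
        eff_a[idx:idx + count] = sign * mags[:, 0]
        eff_b[idx:idx + count] = sign * mags[:, 1]
        labels[idx:idx + count] = label
        idx += count

    # class 2: equal magnitude, opposite sign; sign of species A random
    mags = np.maximum(np.abs(rng.normal(mu, sd, size=cc.n_class2)), 0.25)
    signs = rng.choice([-1.0, 1.0], size=cc.n_class2)
    eff_a[idx:idx + cc.n_class2] = signs * mags
    eff_b[idx:idx + cc.n_class2] = -signs * mags
    labels[idx:idx + cc.n_class2] = "2"
    idx += cc.n_class2

    for count, label, target in ((cc.n_cel_only, "3", "a"), (cc.n_ppa_only, "4", "b")):
        mags = np.maximum(np.abs(rng.normal(mu, sd, size=count)), 0.25)
        signs = rng.choice([-1.0, 1.0], size=count)
        if target == "a":
            eff_a[idx:idx + count] = signs * mags
        else:
            eff_b[idx:idx + count] = signs * mags
        labels[idx:idx + count] = label
        idx += count

    pairs = pd.DataFrame({
        "gene_a": genes_a[:n_orth],
        "gene_b": genes_b[:n_orth],
        "class_label": labels,
    })
    return (pd.DataFrame({"gene_id": genes_a, "effect": eff_a}),
            pd.DataFrame({"gene_id": genes_b, "effect": eff_b}),
            pairs)


def _apply_domain_and_pioneer_effects(
    config: SyntheticStudyConfig,
    rng: np.random.Generator,
    truth_a: pd.DataFrame,
    truth_b: pd.DataFrame,
) -> tuple[dict[str, set[str]], dict[str, set[str]], set[str]]:
    """Plant correlated family-level effects on non-ortholog genes and the
    species-B pioneer shift.  Returns (gene2domain A, gene2domain B, pioneers).
    """
    n = config.n_genes_per_species
    n_orth = config.n_orthologs
    free_a = list(range(n_orth, n))
    free_b = list(range(n_orth, n))
    g2d_a: dict[str, set[str]] = {}
    g2d_b: dict[str, set[str]] = {}
    rho = config.domain_effect_correlation
    sd = config.domain_effect_sd
    cov = np.array([[sd**2, rho * sd**2], [rho * sd**2, sd**2]])
    k = config.domain_members
    needed = config.n_effect_domains * k
    if needed > len(free_a):
        raise ConfigError("not enough non-ortholog genes for the requested effect domains")
    pick_a = rng.choice(free_a, size=needed, replace=False).reshape(config.n_effect_domains, k)
    pick_b = rng.choice(free_b, size=needed, replace=False).reshape(config.n_effect_domains, k)
    dom_eff = rng.multivariate_normal([0.0, 0.0], cov, size=config.n_effect_domains)
    for d in range(config.n_effect_domains):
        dom = f"PF{d:05d}"
        for i in pick_a[d]:
            gid = truth_a.at[i, "gene_id"]
            truth_a.at[i, "effect"] += dom_eff[d, 0]
            g2d_a.setdefault(gid, set()).add(dom)
        for i in pick_b[d]:
            gid = truth_b.at[i, "gene_id"]
            truth_b.at[i, "effect"] += dom_eff[d, 1]
            g2d_b.setdefault(gid, set()).add(dom)

    # pioneers: species-B genes without orthologs, shifted up in dauer
    remaining_b = [i for i in range(n_orth, n)]
    n_pio = min(config.n_pioneers, len(remaining_b))
    pio_idx = rng.choice(remaining_b, size=n_pio, replace=False)
    pioneers = set()
    for i in pio_idx:
        truth_b.at[i, "effect"] += config.pioneer_shift
        pioneers.add(truth_b.at[i, "gene_id"])
    return g2d_a, g2d_b, pioneers


_DE_CALL_MIN_EFFECT = 1e-9


def _finalize_truth(config: SyntheticStudyConfig, truth_df: pd.DataFrame) -> pd.DataFrame:
    f = config.repression_factor
    eff = truth_df["effect"].to_numpy()
    truth_df["true_log2fc_dauer_vs_exit"] = eff + math.log2(f)
    truth_df["true_log2fc_dauer_vs_mix"] = eff + math.log2(f)
    label = np.where(eff > _DE_CALL_MIN_EFFECT, "up",
                     np.where(eff < -_DE_CALL_MIN_EFFECT, "down", "null"))
    truth_df["de_label"] = label
    return truth_df


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def _dye_bias(coefficients: Iterable[float], a: np.ndarray) -> np.ndarray:
    out = np.zeros_like(a)
    for power, coef in enumerate(coefficients):
        out = out + coef * a**power
    return out


def _simulate_array(
    config: SyntheticStudyConfig,
    rng: np.random.Generator,
    species: str,
    condition: str,
    array_id: str,
    orientation: str,
    probe_table: pd.DataFrame,
    gene_effect: dict[str, float],
) -> TwoColorScan:
    f = config.repression_factor
    n = len(probe_table)
    is_spike = probe_table["is_spike"].to_numpy(bool)
    base = probe_table["base_abundance"].to_numpy(float)
    gene_ids = probe_table["gene_id"].to_numpy(object)

    effect = np.array([0.0 if s else gene_effect[g] for s, g in zip(is_spike, gene_ids)])
    a_ref = base.copy()
    a_smp = base.copy()
    gene_mask = ~is_spike
    if condition == "dauer":
        a_smp[gene_mask] = base[gene_mask] * 2.0 ** effect[gene_mask] * f
    # exit: biological exit effect is 0 relative to the mix reference
    # spikes: identical abundance in both channels, never scaled by f

    a0 = 0.5 * (np.log2(a_smp) + np.log2(a_ref))
    bias = _dye_bias(config.dye_bias_coefficients, a0)

    if orientation == "sample_in_red":
        a_red, a_green = a_smp, a_ref
    else:
        a_red, a_green = a_ref, a_smp

    def channel(abund: np.ndarray, half_bias: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        noise = np.exp(rng.normal(0.0, config.signal_log_sd, size=n))
        signal = abund * 2.0 ** half_bias * noise
        bg_true = np.maximum(rng.normal(config.bg_mu, config.bg_sigma, size=n), 0.0)
        fg = bg_true + signal
        bg_local = np.maximum(rng.normal(config.bg_mu, config.bg_sigma, size=n), 0.0)
        return fg, bg_local

    fg_red, bg_red = channel(a_red, +bias / 2.0)
    fg_green, bg_green = channel(a_green, -bias / 2.0)
    flags = np.where(rng.random(n) < config.bad_spot_rate, "bad", "ok")
    if (flags == "bad").all():       # degenerate tiny fixtures
        flags[0] = "ok"

    spots = pd.DataFrame({
        "probe_id": probe_table["probe_id"].to_numpy(object),
        "fg_red": fg_red,
        "bg_red": bg_red,
        "fg_green": fg_green,
        "bg_green": bg_green,
        "flag": flags,
    })
    return TwoColorScan(array_id=array_id, species=species, condition=condition,
                        dye_orientation=orientation, spots=spots)


def _build_probe_table(config: SyntheticStudyConfig, rng: np.random.Generator,
                       species: str, gene_df: pd.DataFrame) -> pd.DataFrame:
    """Probe-level layout with per-probe base abundances.

    Gene base abundances are Exponential(alpha) (matching the
    background-correction signal model); spike bases are log-uniform
    across the abundance range so the loess curve is constrained at
    every intensity.
    """
    rows = []
    bases = rng.exponential(config.signal_mean_alpha, size=len(gene_df))
    bases = np.maximum(bases, 20.0)   # keep genes detectable above background
    for gid, base in zip(gene_df["gene_id"], bases):
        for k in range(config.probes_per_gene):
            rows.append((f"{gid}_p{k}", gid, False, np.nan, base))
    lo, hi = np.log2(50.0), np.log2(bases.max() * 2.0)
    spike_bases = 2.0 ** np.linspace(lo, hi, config.n_spikes)
    for s, base in enumerate(spike_bases):
        rows.append((f"{species}_spike{s:03d}", "", True, 0.0, base))
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "is_spike",
                                       "expected_spike_logratio", "base_abundance"])


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def generate_hit_tables(truth: GroundTruth, config: SyntheticStudyConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[HitTable, HitTable]:
    """Directional hit tables whose reciprocal-best-hit set equals the
    truth's recoverable pair set.

    Every intended pair is a mutual best hit; a configured fraction is
    scored below the 50-bit cutoff (not recoverable); decoy paralog hits
    with strictly lower scores and sub-threshold noise hits are injected.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    pairs = truth.pairs
    n_pairs = len(pairs)
    strong = rng.uniform(120.0, 400.0, size=n_pairs)
    weak_mask = rng.random(n_pairs) < config.weak_pair_fraction
    scores = np.where(weak_mask, rng.uniform(20.0, 49.9, size=n_pairs), strong)
    evalues = 10.0 ** (-scores / 10.0)

    rows_ab: list[tuple[str, str, float, float]] = []
    rows_ba: list[tuple[str, str, float, float]] = []
    all_b = list(truth.genes[SPECIES_B]["gene_id"])
    all_a = list(truth.genes[SPECIES_A]["gene_id"])
    for i, row in enumerate(pairs.itertuples(index=False)):
        s, e = float(scores[i]), float(evalues[i])
        rows_ab.append((row.gene_a, row.gene_b, s, e))
        rows_ba.append((row.gene_b, row.gene_a, s, e))
        if rng.random() < config.decoy_fraction:
            decoy_b = all_b[int(rng.integers(len(all_b)))]
            if decoy_b != row.gene_b:
                d = s * float(rng.uniform(0.5, 0.95))
                rows_ab.append((row.gene_a, decoy_b, d, 10.0 ** (-d / 10.0)))
        if rng.random() < config.decoy_fraction:
            decoy_a = all_a[int(rng.integers(len(all_a)))]
            if decoy_a != row.gene_a:
                d = s * float(rng.uniform(0.5, 0.95))
                rows_ba.append((row.gene_b, decoy_a, d, 10.0 ** (-d / 10.0)))
    # sub-threshold noise hits between random non-ortholog genes
    n_noise = max(10, n_pairs // 10)
    for _ in range(n_noise):
        qa = all_a[int(rng.integers(len(all_a)))]
        sb = all_b[int(rng.integers(len(all_b)))]
        s = float(rng.uniform(20.0, 49.5))
        rows_ab.append((qa, sb, s, 10.0 ** (-s / 10.0)))
        rows_ba.append((sb, qa, s, 10.0 ** (-s / 10.0)))

    truth.pairs["rbh_recoverable"] = ~weak_mask
    ht_ab = HitTable(pd.DataFrame(rows_ab, columns=["query_id", "subject_id", "bit_score", "e_value"]))
    ht_ba = HitTable(pd.DataFrame(rows_ba, columns=["query_id", "subject_id", "bit_score", "e_value"]))
    return ht_ab, ht_ba


# ---------------------------------------------------------------------------
# annotation bundle
# ---------------------------------------------------------------------------

def _biased_sample(rng: np.random.Generator, candidates: list[str],
                   favored: set[str], size: int, fold: float) -> set[str]:
    """Sample without replacement with `fold`-times higher weight on `favored`."""
    weights = np.array([fold if g in favored else 1.0 for g in candidates])
    weights = weights / weights.sum()
    size = min(size, len(candidates))
    picked = rng.choice(len(candidates), size=size, replace=False, p=weights)
    return {candidates[i] for i in picked}


def generate_annotation_bundle(
    truth: GroundTruth,
    config: SyntheticStudyConfig,
    gene2domain_a: dict[str, set[str]] | None = None,
    gene2domain_b: dict[str, set[str]] | None = None,
    pioneers: set[str] | None = None,
    rng: np.random.Generator | None = None,
) -> AnnotationBundle:
    """Ontology, associations, clusters, domains, pathways and pioneer list
    with the configured planted enrichments among DE genes."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    pe = config.planted
    ortho_a = list(truth.pairs["gene_a"])
    de_a = truth.de_genes(SPECIES_A)

    # --- ontology: one namespace, root <- mid layer <- leaf terms ----------
    graph = nx.DiGraph()
    root = "GO:0000001"
    graph.add_node(root, name="root", namespace="biological_process")
    n_mid = 6
    mids = [f"GO:00001{m:02d}" for m in range(n_mid)]
    for m, mid in enumerate(mids):
        graph.add_node(mid, name=f"mid_{m}", namespace="biological_process")
        graph.add_edge(mid, root)
    leaf_terms = [pe.term_id] + [f"GO:8{t:06d}" for t in range(pe.n_background_terms)]
    for t, term in enumerate(leaf_terms):
        graph.add_node(term, name=f"leaf_{t}", namespace="biological_process")
        graph.add_edge(term, mids[t % n_mid])

    # --- associations: planted term biased toward DE ortholog genes --------
    gene2term: dict[str, set[str]] = {}

    def annotate(term: str, members: set[str]) -> None:
        for g in members:
            gene2term.setdefault(g, set()).add(term)

    annotate(pe.term_id, _biased_sample(rng, ortho_a, de_a, pe.term_size, pe.term_fold))
    for term in leaf_terms[1:]:
        annotate(term, _biased_sample(rng, ortho_a, set(), pe.background_term_size, 1.0))

    # --- expression clusters: planted cluster tracks species-A up genes ----
    clusters: dict[str, set[str]] = {}
    up_a = truth.de_genes(SPECIES_A, "up") & set(ortho_a)
    clusters[pe.cluster_id] = _biased_sample(rng, ortho_a, up_a, pe.cluster_size,
                                             pe.cluster_fold)
    for c in range(pe.n_background_clusters):
        clusters[f"CL:bg{c:03d}"] = _biased_sample(rng, ortho_a, set(),
                                                   pe.cluster_size, 1.0)

    # --- pathways: planted pathway dominated by species-B-only down genes --
    pathway2gene: dict[str, set[str]] = {}
    pairs = truth.pairs
    genes_b_label = truth.genes[SPECIES_B].set_index("gene_id")["de_label"]
    b_down_pairs = pairs[
        (pairs["class_label"] == "4")
        & (pairs["gene_b"].map(genes_b_label) == "down")
    ]
    null_pairs = pairs[pairs["class_label"] == "none"]
    planted_members = set(b_down_pairs["gene_a"].head(pe.pathway_n_down))
    planted_members |= set(null_pairs["gene_a"].head(pe.pathway_n_null))
    pathway2gene[pe.pathway_id] = planted_members
    for p in range(pe.n_background_pathways):
        pathway2gene[f"path:bg{p:03d}"] = _biased_sample(rng, ortho_a, set(), 20, 1.0)

    return AnnotationBundle(
        ontology=graph,
        gene2term=gene2term,
        clusters=clusters,
        gene2domain=dict(gene2domain_a or {}),
        pathway2gene=pathway2gene,
        pioneer_genes=set(pioneers or set()),
    )


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def generate_study(config: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate the complete study.  Same config (incl. seed) → identical output."""
    root_ss = np.random.SeedSequence(config.seed)
    rng_layout, rng_arrays, rng_hits, rng_bundle = (
        np.random.default_rng(s) for s in root_ss.spawn(4))

    truth_a, truth_b, pairs = _draw_effects(config, rng_layout)
    g2d_a, g2d_b, pioneers = _apply_domain_and_pioneer_effects(
        config, rng_layout, truth_a, truth_b)
    truth_a = _finalize_truth(config, truth_a)
    truth_b = _finalize_truth(config, truth_b)
    truth = GroundTruth(
        genes={SPECIES_A: truth_a, SPECIES_B: truth_b},
        pairs=pairs,
        planted_term=config.planted.term_id,
        planted_cluster=config.planted.cluster_id,
        planted_pathway=config.planted.pathway_id,
        repression_factor=config.repression_factor,
    )

    scans: list[TwoColorScan] = []
    probes: dict[str, ProbeAnnotation] = {}
    half = config.replicates_per_contrast // 2
    for species, truth_df in ((SPECIES_A, truth_a), (SPECIES_B, truth_b)):
        probe_table = _build_probe_table(config, rng_arrays, species, truth_df)
        probes[species] = ProbeAnnotation(
            table=probe_table.drop(columns=["base_abundance"]).copy())
        gene_effect = dict(zip(truth_df["gene_id"], truth_df["effect"]))
        for condition in ("dauer", "exit"):
            for r in range(config.replicates_per_contrast):
                orientation = "sample_in_red" if r < half else "sample_in_green"
                array_id = f"{species}_{condition}_r{r + 1}"
                scans.append(_simulate_array(
                    config, rng_arrays, species, condition, array_id,
                    orientation, probe_table, gene_effect))

    hits_ab, hits_ba = generate_hit_tables(truth, config, rng_hits)
    bundle = generate_annotation_bundle(truth, config, g2d_a, g2d_b, pioneers,
                                        rng_bundle)
    return SyntheticStudy(config=config, scans=scans, probes=probes,
                          hits_ab=hits_ab, hits_ba=hits_ba, bundle=bundle,
                          truth=truth, gene2domain_b=g2d_b)


def truth_to_json_dict(truth: GroundTruth) -> dict:
    """JSON-serializable ground-truth sidecar."""
    return {
        "repression_factor": truth.repression_factor,
        "planted_term": truth.planted_term,
        "planted_cluster": truth.planted_cluster,
        "planted_pathway": truth.planted_pathway,
        "genes": {sp: df.to_dict(orient="list") for sp, df in truth.genes.items()},
        "pairs": truth.pairs.to_dict(orient="list"),
    }
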