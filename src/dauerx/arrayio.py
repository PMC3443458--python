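"""Readers and writers for every external table the pipeline touches.

All files are tab-separated UTF-8 text; lines starting with ``#`` are
comments.  Scan tables carry a header; 12-column hit tables do not (the
usual tabular search-output convention).  Parsers either return fully
validated objects or raise :class:`~dauerx.errors.FormatError` /
:class:`~dauerx.errors.ValidationError` — rows are never silently dropped.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

SPECIES = ("cel", "ppa")
CONDITIONS = ("dauer", "exit", "mix_reference")
ORIENTATIONS = ("sample_in_red", "sample_in_green")

SCAN_COLUMNS = ["probe_id", "fg_red", "bg_red", "fg_green", "bg_green", "flag"]
_INTENSITY_COLUMNS = ["fg_red", "bg_red", "fg_green", "bg_green"]

#: flag values mapped to "ok"; anything else means the spot is unusable
_OK_FLAGS = {"ok", "0"}


# ---------------------------------------------------------------------------
# two-color scans
# ---------------------------------------------------------------------------

@dataclass
class TwoColorScan:
    """Spot-level red/green intensities of one hybridization.

    ``spots`` columns: probe_id (str), fg_red, bg_red, fg_green, bg_green
    (float, linear fluorescence units) and flag ("ok"/"bad").
    """

    array_id: str
    species: str
    condition: str
    dye_orientation: str
    spots: pd.DataFrame

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species {self.species!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.dye_orientation not in ORIENTATIONS:
            raise ValidationError(f"unknown dye orientation {self.dye_orientation!r}")
        missing = [c for c in SCAN_COLUMNS if c not in self.spots.columns]
        if missing:
            raise FormatError(f"scan table missing column(s): {', '.join(missing)}")
        if self.spots["probe_id"].duplicated().any():
            dup = self.spots.loc[self.spots["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe_id {dup!r} in array {self.array_id}")
        vals = self.spots[_INTENSITY_COLUMNS].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            row = int(np.argwhere(~np.isfinite(vals))[0, 0])
            raise ValidationError(f"non-finite intensity at row {row} of array {self.array_id}")
        if (vals < 0).any():
            row = int(np.argwhere(vals < 0)[0, 0])
            raise ValidationError(f"negative intensity at row {row} of array {self.array_id}")
        if not (self.spots["flag"] == "ok").any():
            raise ValidationError(f"array {self.array_id} has no ok-flagged spot")

    @property
    def n_spots(self) -> int:
        return len(self.spots)


def _read_table(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_scan_table(
    path: str | os.PathLike,
    *,
    array_id: str,
    species: str,
    condition: str,
    dye_orientation: str,
) -> TwoColorScan:
    """Read one GPR-like scan table and attach array metadata."""
    try:
        df = _read_table(path, dtype={"probe_id": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty scan table") from exc
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    df = df[SCAN_COLUMNS].copy()
    for col in _INTENSITY_COLUMNS:
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric {col}") from exc
    df["flag"] = [
        "ok" if str(v).strip() in _OK_FLAGS else "bad" for v in df["flag"]
    ]
    df = df.reset_index(drop=True)
    return TwoColorScan(
        array_id=array_id,
        species=species,
        condition=condition,
        dye_orientation=dye_orientation,
        spots=df,
    )


def write_scan_table(scan: TwoColorScan, path: str | os.PathLike) -> None:
    df = scan.spots[SCAN_COLUMNS].copy()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# array_id={scan.array_id} species={scan.species} "
                 f"condition={scan.condition} orientation={scan.dye_orientation}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

@dataclass
class ProbeAnnotation:
    """probe → gene map with spike-in flags and expected spike log-ratios.

    ``table`` columns: probe_id, gene_id ("" for controls), is_spike (bool),
    expected_spike_logratio (float; NaN for non-spikes).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["probe_id", "gene_id", "is_spike", "expected_spike_logratio"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"probe annotation missing column(s): {', '.join(missing)}")
        t = self.table
        if t["probe_id"].duplicated().any():
            raise ValidationError("duplicate probe_id in probe annotation")
        spikes = t[t["is_spike"]]
        if not np.isfinite(spikes["expected_spike_logratio"].to_numpy(float)).all():
            raise ValidationError("spike probe without finite expected_spike_logratio")
        nonspike = t[~t["is_spike"]]
        if (nonspike["gene_id"].astype(str).str.len() == 0).any():
            raise ValidationError("non-spike probe without gene_id")

    @property
    def spike_ids(self) -> set[str]:
        return set(self.table.loc[self.table["is_spike"], "probe_id"])

    def gene_map(self) -> pd.Series:
        """probe_id → gene_id for non-spike probes."""
        t = self.table[~self.table["is_spike"]]
        return pd.Series(t["gene_id"].values, index=t["probe_id"].values)


def read_probe_annotation(path: str | os.PathLike) -> ProbeAnnotation:
    df = _read_table(path, dtype={"probe_id": str})
    if "gene_id" in df.columns:
        df["gene_id"] = df["gene_id"].fillna("").astype(str)
    if "is_spike" in df.columns:
        df["is_spike"] = df["is_spike"].astype(str).str.lower().isin({"true", "1", "yes"})
    return ProbeAnnotation(table=df.reset_index(drop=True))


def write_probe_annotation(probes: ProbeAnnotation, path: str | os.PathLike) -> None:
    df = probes.table.copy()
    df["is_spike"] = df["is_spike"].map({True: "1", False: "0"})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

@dataclass
class HitTable:
    """Pairwise sequence-search hits: query_id, subject_id, bit_score, e_value.

    (query, subject) pairs may repeat — one row per HSP.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["query_id", "subject_id", "bit_score", "e_value"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise FormatError(f"hit table missing column(s): {', '.join(missing)}")
        scores = self.rows["bit_score"].to_numpy(dtype=float)
        if len(scores) and (not np.isfinite(scores).all() or (scores < 0).any()):
            raise ValidationError("bit scores must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.rows)


def read_hit_table(path: str | os.PathLike) -> HitTable:
    """Parse a 12-column tabular hit file (columns 1,2,11,12 used)."""
    rows: list[tuple[str, str, float, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                evalue = float(parts[10])
                bits = float(parts[11])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-numeric e-value/bit score") from exc
            rows.append((parts[0], parts[1], bits, evalue))
    df = pd.DataFrame(rows, columns=["query_id", "subject_id", "bit_score", "e_value"])
    return HitTable(rows=df)


def write_hit_table(hits: HitTable, path: str | os.PathLike) -> None:
    """Write hits in the 12-column dialect (unused columns zero-filled)."""
    with open(path, "w", encoding="utf-8") as fh:
        for row in hits.rows.itertuples(index=False):
            cols = [row.query_id, row.subject_id, "100.0", "100", "0", "0",
                    "1", "100", "1", "100", repr(float(row.e_value)),
                    repr(float(row.bit_score))]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# annotation bundle (OBO ontology + flat gene-set tables)
# ---------------------------------------------------------------------------

@dataclass
class AnnotationBundle:
    """Ontology DAG plus the flat annotation layers.

    ``ontology`` is a DiGraph with child→parent edges (is_a / part_of only)
    and per-node ``name`` / ``namespace`` attributes.
    """

    ontology: nx.DiGraph
    gene2term: dict[str, set[str]]
    clusters: dict[str, set[str]]
    gene2domain: dict[str, set[str]]
    pathway2gene: dict[str, set[str]]
    pioneer_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.ontology):
            cycle = nx.find_cycle(self.ontology)
            raise ValidationError(f"ontology contains a cycle: {cycle}")
        known = set(self.ontology.nodes)
        for gene, terms in self.gene2term.items():
            unknown = terms - known
            if unknown:
                raise ValidationError(
                    f"gene {gene} annotated to unknown term(s): {sorted(unknown)[:3]}")

    def term_name(self, term_id: str) -> str:
        return self.ontology.nodes[term_id].get("name", term_id)


def parse_obo(path: str | os.PathLike) -> nx.DiGraph:
    """Minimal OBO 1.2 parser: [Term] stanzas, is_a and part_of edges only.

    Obsolete terms are dropped; other relationship types are ignored.
    """
    graph = nx.DiGraph()
    term: dict | None = None

    def flush(t: dict | None) -> None:
        if not t or t.get("obsolete") or "id" not in t:
            return
        graph.add_node(t["id"], name=t.get("name", t["id"]),
                       namespace=t.get("namespace", ""))
        for parent in t.get("parents", []):
            graph.add_edge(t["id"], parent)

    with open(path, encoding="utf-8") as fh:
        in_term = False
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                flush(term if in_term else None)
                in_term = line == "[Term]"
                term = {"parents": []} if in_term else None
                continue
            if not in_term or not line or ":" not in line:
                continue
            key, _, value = line.partition(":")
            value = value.strip()
            if key == "id":
                term["id"] = value
            elif key == "name":
                term["name"] = value
            elif key == "namespace":
                term["namespace"] = value
            elif key == "is_obsolete" and value.lower().startswith("true"):
                term["obsolete"] = True
            elif key == "is_a":
                term["parents"].append(value.split("!")[0].strip())
            elif key == "relationship" and value.startswith("part_of"):
                term["parents"].append(value.split()[1].strip())
        flush(term if in_term else None)

    # parents referenced but never declared still need nodes
    for node in list(graph.nodes):
        graph.nodes[node].setdefault("name", node)
        graph.nodes[node].setdefault("namespace", "")
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValidationError(f"ontology contains a cycle: {cycle}")
    return graph


def write_obo(graph: nx.DiGraph, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for node in sorted(graph.nodes):
            data = graph.nodes[node]
            fh.write(f"\n[Term]\nid: {node}\nname: {data.get('name', node)}\n")
            if data.get("namespace"):
                fh.write(f"namespace: {data['namespace']}\n")
            for parent in sorted(graph.successors(node)):
                fh.write(f"is_a: {parent}\n")


def _read_pair_table(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Two-column TSV: (entity_id, gene_id)."""
    out: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            out.append((parts[0], parts[1]))
    return out


def _write_pair_table(mapping: Mapping[str, set[str]], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for entity in sorted(mapping):
            for gene in sorted(mapping[entity]):
                fh.write(f"{entity}\t{gene}\n")


def _invert(pairs: Iterable[tuple[str, str]]) -> dict[str, set[str]]:
    """(entity, gene) rows → gene → {entities}."""
    out: dict[str, set[str]] = {}
    for entity, gene in pairs:
        out.setdefault(gene, set()).add(entity)
    return out


def _group(pairs: Iterable[tuple[str, str]]) -> dict[str, set[str]]:
    """(entity, gene) rows → entity → {genes}."""
    out: dict[str, set[str]] = {}
    for entity, gene in pairs:
        out.setdefault(entity, set()).add(gene)
    return out


def read_annotation_bundle(
    ontology_path: str | os.PathLike,
    associations_path: str | os.PathLike,
    clusters_path: str | os.PathLike,
    domains_path: str | os.PathLike,
    pathways_path: str | os.PathLike,
    pioneers_path: str | os.PathLike,
) -> AnnotationBundle:
    graph = parse_obo(ontology_path)
    gene2term = _invert(_read_pair_table(associations_path))
    clusters = _group(_read_pair_table(clusters_path))
    gene2domain = _invert(_read_pair_table(domains_path))
    pathway2gene = _group(_read_pair_table(pathways_path))
    pioneers: set[str] = set()
    with open(pioneers_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                pioneers.add(line)
    return AnnotationBundle(
        ontology=graph,
        gene2term=gene2term,
        clusters=clusters,
        gene2domain=gene2domain,
        pathway2gene=pathway2gene,
        pioneer_genes=pioneers,
    )


def write_annotation_bundle(bundle: AnnotationBundle, outdir: str | os.PathLike) -> dict[str, str]:
    """Write every bundle layer under ``outdir``; returns path map."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "ontology": os.path.join(outdir, "ontology.obo"),
        "associations": os.path.join(outdir, "gene2term.tsv"),
        "clusters": os.path.join(outdir, "clusters.tsv"),
        "domains": os.path.join(outdir, "gene2domain.tsv"),
        "pathways": os.path.join(outdir, "pathway2gene.tsv"),
        "pioneers": os.path.join(outdir, "pioneer_genes.txt"),
    }
    write_obo(bundle.ontology, paths["ontology"])
    term2gene: dict[str, set[str]] = {}
    for gene, terms in bundle.gene2term.items():
        for term in terms:
            term2gene.setdefault(term, set()).add(gene)
    _write_pair_table(term2gene, paths["associations"])
    _write_pair_table(bundle.clusters, paths["clusters"])
    domain2gene: dict[str, set[str]] = {}
    for gene, domains in bundle.gene2domain.items():
        for dom in domains:
            domain2gene.setdefault(dom, set()).add(gene)
    _write_pair_table(domain2gene, paths["domains"])
    _write_pair_table(bundle.pathway2gene, paths["pathways"])
    with open(paths["pioneers"], "w", encoding="utf-8") as fh:
        for gene in sorted(bundle.pioneer_genes):
            fh.write(gene + "\n")
    return paths
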