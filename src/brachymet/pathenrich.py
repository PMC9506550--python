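"""m/z annotation against the bundled compound/pathway database and
pathway over-representation analysis.

The approach mirrors mummichog-style functional analysis of untargeted
m/z lists: each query m/z is tentatively annotated against database
ions within a ppm tolerance, annotated compounds from a "significant"
list are tested per pathway with the hypergeometric tail against the
annotated reference universe, a seeded permutation null is computed
alongside, p-values are Benjamini-Hochberg adjusted across pathways,
and pathway impact is scored from relative betweenness centrality of
hit nodes (normalized so a fully hit pathway scores 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .chemmass import ion_mz, parse_formula, ppm_error
from .library import CompoundRecord, load_compound_library  # re-exported surface

__all__ = [
    "CompoundRecord", "load_compound_library",
    "PathwayGraph", "EnrichmentRow", "load_pathway_graph",
    "annotate_mz_list", "enrich_pathways", "pathway_impact", "bh_fdr",
]

DEFAULT_TOL_PPM = 5.0
#: Reporting defaults for "significantly enriched" pathways.
FDR_MAX = 0.03
IMPACT_MIN = 0.3


@dataclass(frozen=True)
class EnrichmentRow:
    pathway: str
    total: int
    hits: int
    p_raw: float
    p_perm: float
    fdr: float
    impact: float


class PathwayGraph:
    """Named pathways over compound nodes with within-pathway adjacency."""

    def __init__(self, nodes: pd.DataFrame, pathways: dict[str, set],
                 graph: nx.Graph):
        for name, members in pathways.items():
            if not members:
                raise ValueError(f"pathway {name!r} is empty")
        self.nodes = nodes              # node_id, name, formula, mz_pos, mz_neg
        self.pathways = pathways        # pathway name -> set of node ids
        self.graph = graph              # undirected compound adjacency

    @property
    def compound_ids(self) -> set:
        return set(self.nodes["node_id"])

    def subgraph(self, pathway: str) -> nx.Graph:
        return self.graph.subgraph(self.pathways[pathway])


def load_pathway_graph() -> PathwayGraph:
    """The bundled miniature pathway database."""
    path = resources.files("brachymet.data").joinpath("pathway_db.tsv")
    with resources.as_file(path) as p:
        raw = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    mz_pos, mz_neg = [], []
    for f in raw["formula"]:
        formula = parse_formula(f)
        mz_pos.append(ion_mz(formula, "[M+H]+"))
        mz_neg.append(ion_mz(formula, "[M-H]-"))
    nodes = raw[["node_id", "name", "formula"]].copy()
    nodes["mz_pos"] = mz_pos
    nodes["mz_neg"] = mz_neg
    pathways: dict[str, set] = {}
    graph = nx.Graph()
    graph.add_nodes_from(nodes["node_id"])
    for row in raw.itertuples(index=False):
        for pw in row.pathways.split(";"):
            pathways.setdefault(pw.strip(), set()).add(row.node_id)
        if row.neighbors:
            for nb in row.neighbors.split(";"):
                graph.add_edge(row.node_id, nb.strip())
    unknown = set(graph.nodes) - set(nodes["node_id"])
    if unknown:
        raise ValueError(f"neighbor ids not defined as nodes: {sorted(unknown)}")
    return PathwayGraph(nodes, pathways, graph)


def annotate_mz_list(mzs, graph_or_db, tol_ppm: float = DEFAULT_TOL_PPM) -> dict:
    """Tentative annotation of (m/z, polarity) queries.

    ``graph_or_db`` is a PathwayGraph (annotates against its node masses)
    or a list of CompoundRecord.  Returns {(mz, polarity): set of ids};
    a compound matched by several queries is still counted once when the
    values of the mapping are unioned for enrichment.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if isinstance(graph_or_db, PathwayGraph):
        entries = [(r.node_id, r.mz_pos, "positive") for r in graph_or_db.nodes.itertuples(index=False)]
        entries += [(r.node_id, r.mz_neg, "negative") for r in graph_or_db.nodes.itertuples(index=False)]
    else:
        entries = [(r.compound_id, r.theoretical_mz, r.polarity)
                   for r in graph_or_db if r.formula is not None]
    out = {}
    for mz, polarity in mzs:
        hits = {ident for ident, theo, pol in entries
                if pol == polarity and abs(ppm_error(mz, theo)) <= tol_ppm}
        out[(mz, polarity)] = hits
    return out


def bh_fdr(pvals) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out.tolist()


def pathway_impact(graph: PathwayGraph, hit_compounds: set) -> dict[str, float]:
    """Relative-betweenness impact per pathway, in [0, 1].

    impact = sum of betweenness centralities of hit nodes over the sum
    across all pathway nodes, computed on the pathway's own subgraph
    (endpoint-inclusive so isolated and chain-end nodes carry weight);
    0 when the denominator is 0.
    """
    impact = {}
    for name, members in graph.pathways.items():
        sub = graph.subgraph(name)
        bc = nx.betweenness_centrality(sub, normalized=True, endpoints=True)
        denom = sum(bc.values())
        num = sum(bc[n] for n in members if n in hit_compounds)
        impact[name] = num / denom if denom > 0 else 0.0
    return impact


def enrich_pathways(significant: set, reference: set, graph: PathwayGraph,
                    permutations: int = 2000, seed: int = 0) -> list[EnrichmentRow]:
    """Hypergeometric pathway over-representation with a permutation null.

    ``significant`` (annotated compounds from the selected m/z list) must
    be a subset of ``reference`` (all annotated compounds).  For each
    pathway, p_raw = P(X >= hits) drawing |significant| compounds from
    the reference universe; p_perm resamples significant-sized sets;
    BH-FDR is computed over the hypergeometric p-values.
    """
    significant, reference = set(significant), set(reference)
    offenders = significant - reference
    if offenders:
        raise ValueError(f"significant compounds outside reference: {sorted(offenders)}")
    rng = np.random.default_rng(seed)
    universe = sorted(reference)
    n_universe, n_sig = len(universe), len(significant)
    impact = pathway_impact(graph, significant)

    names, totals, hit_counts, p_raws = [], [], [], []
    members_in_ref = {}
    for name, members in sorted(graph.pathways.items()):
        in_ref = members & reference
        k = len(members & significant)
        names.append(name)
        totals.append(len(members))
        hit_counts.append(k)
        members_in_ref[name] = in_ref
        if k == 0 or not in_ref:
            p_raws.append(1.0)
        else:
            p_raws.append(float(stats.hypergeom.sf(k - 1, n_universe,
                                                   len(in_ref), n_sig)))
    # permutation null: resample significant-sized sets from the universe
    perm_ge = np.zeros(len(names))
    if permutations > 0 and n_sig > 0:
        arr = np.array(universe, dtype=object)
        member_masks = {
            name: np.isin(arr, sorted(members_in_ref[name]))
            for name in names}
        for _ in range(permutations):
            pick = rng.choice(n_universe, size=n_sig, replace=False)
            mask = np.zeros(n_universe, dtype=bool)
            mask[pick] = True
            for j, name in enumerate(names):
                if (mask & member_masks[name]).sum() >= hit_counts[j]:
                    perm_ge[j] += 1
        p_perm = (perm_ge + 1) / (permutations + 1)
    else:
        p_perm = np.ones(len(names))
    fdr = bh_fdr(p_raws)
    return [EnrichmentRow(names[j], totals[j], hit_counts[j], p_raws[j],
                          float(p_perm[j]), fdr[j], impact[names[j]])
            for j in range(len(names))]


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.sort_values(["fdr", "p_raw", "pathway"]).reset_index(drop=True)
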