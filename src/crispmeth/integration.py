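"""Methylation-expression integration and downstream gene-level analysis.

DEG filtering (|log2FC| > 1, FDR <= 0.001), DMG/DEG set overlap,
promoter-methylation vs expression concordance, candidate-gene selection
against supplied pathway sets and a curated literature list, hypergeometric
gene-set enrichment with Benjamini-Hochberg correction, confidence filtering
of protein-protein interaction edges, and the muscle-fiber diameter helper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def filter_degs(
    expression: pd.DataFrame,
    min_abs_log2fc: float = 1.0,
    max_fdr: float = 0.001,
) -> set[str]:
    """Differentially expressed genes: |log2FC| strictly above the fold
    threshold AND FDR at or below the FDR threshold."""
    for col in ("gene_id", "log2_fc", "fdr"):
        if col not in expression.columns:
            raise ValueError(f"expression table missing column {col!r}")
    keep = (expression["log2_fc"].abs() > min_abs_log2fc) & (
        expression["fdr"] <= max_fdr
    )
    return set(expression.loc[keep, "gene_id"])


def overlap_sets(dmgs: set[str], degs: set[str]):
    """Venn decomposition of the DMG and DEG sets.

    Returns (intersection, dmg_only, deg_only, counts) where counts is the
    (n_both, n_dmg_only, n_deg_only) triple.
    """
    inter = dmgs & degs
    dmg_only = dmgs - degs
    deg_only = degs - dmgs
    return inter, dmg_only, deg_only, (len(inter), len(dmg_only), len(deg_only))


def concordance(promoter_dmr_direction: str, log2_fc: float) -> str:
    """Classify a promoter-DMR / expression pair.

    ``promoter_dmr_direction`` is the methylation direction in group A
    ('hyper_in_A' / 'hypo_in_A'); ``log2_fc`` is expression of group A over
    group B.  Promoter hypomethylation with higher expression (or hyper
    with lower) is the canonical inhibitory relationship.
    """
    if promoter_dmr_direction not in ("hyper_in_A", "hypo_in_A"):
        raise ValueError(f"bad direction {promoter_dmr_direction!r}")
    meth_up = promoter_dmr_direction == "hyper_in_A"
    expr_up = log2_fc > 0
    return "non_canonical" if meth_up == expr_up else "canonical"


def concordance_table(
    dmr_directions: dict[str, str], expression: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene concordance for genes with both a promoter DMR direction and
    an expression record; genes missing either side are excluded."""
    expr = expression.set_index("gene_id")
    rows = []
    for gid, direction in sorted(dmr_directions.items()):
        if gid not in expr.index:
            continue
        fc = float(expr.loc[gid, "log2_fc"])
        rows.append(
            {
                "gene_id": gid, "direction": direction, "log2_fc": fc,
                "concordance": concordance(direction, fc),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "direction", "log2_fc",
                                       "concordance"])


# ---------------------------------------------------------------------------
# candidate selection


@dataclass
class CandidateGene:
    """A DMG-and-DEG gene scored against the selection criteria."""

    gene_id: str
    in_overlap: bool
    pathways: list = field(default_factory=list)
    in_curated: bool = False
    meth_direction: str | None = None
    expr_direction: str | None = None
    concordance: str | None = None

    @property
    def selected(self) -> bool:
        return self.in_overlap and bool(self.pathways) and self.in_curated


def load_curated_gene_list() -> set[str]:
    """The packaged curated list of muscle structure/development genes."""
    text = (
        resources.files("crispmeth.data")
        .joinpath("curated_muscle_genes.txt")
        .read_text()
    )
    return {ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")}


def select_candidates(
    overlap_genes: set[str],
    pathway_sets: dict[str, set[str]],
    curated_list: set[str],
    dmr_directions: dict[str, str] | None = None,
    expression: pd.DataFrame | None = None,
) -> list[CandidateGene]:
    """Candidate genes: in the DMG-and-DEG overlap, members of at least one
    supplied pathway set, and present in the curated literature list.

    All flags are recorded on every overlap gene; ``selected`` marks those
    satisfying every criterion.
    """
    import warnings

    if not curated_list:
        warnings.warn("empty curated list: the literature criteria cannot be "
                      "satisfied by any gene")
    expr = expression.set_index("gene_id") if expression is not None else None
    out = []
    for gid in sorted(overlap_genes):
        cand = CandidateGene(
            gene_id=gid,
            in_overlap=True,
            pathways=sorted(n for n, s in pathway_sets.items() if gid in s),
            in_curated=gid in curated_list,
        )
        if dmr_directions and gid in dmr_directions:
            cand.meth_direction = dmr_directions[gid]
            if expr is not None and gid in expr.index:
                fc = float(expr.loc[gid, "log2_fc"])
                cand.expr_direction = "up" if fc > 0 else "down"
                cand.concordance = concordance(cand.meth_direction, fc)
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# gene-set enrichment


@dataclass
class EnrichmentResult:
    set_name: str
    k: int          # overlap of query with the set
    K: int          # set size within the universe
    n: int          # query size
    N: int          # universe size
    p_value: float
    q_value: float = math.nan
    significant: bool = False


def enrich(
    query_genes: set[str],
    universe: set[str],
    gene_sets: dict[str, set[str]],
    q_max: float = 0.05,
    method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation test per gene set.

    Sets are intersected with the universe; the query must be a subset of
    the universe.  p values are corrected across the tested sets
    (Benjamini-Hochberg by default, ``method='bonferroni'`` available) and
    results return sorted by q then p.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query_genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(query_genes)
    results = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        K = len(members)
        k = len(query_genes & members)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        results.append(EnrichmentResult(set_name=name, k=k, K=K, n=n, N=N,
                                        p_value=min(p, 1.0)))
    if results:
        pvals = np.array([r.p_value for r in results])
        rej, qvals, *_ = multipletests(pvals, alpha=q_max, method=method)
        for r, q, rj in zip(results, qvals, rej):
            r.q_value = float(q)
            r.significant = bool(rj)
    results.sort(key=lambda r: (r.q_value, r.p_value, r.set_name))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name, "overlap": r.k, "set_size": r.K,
                "query_size": r.n, "universe_size": r.N,
                "p_value": r.p_value, "q_value": r.q_value,
                "significant": r.significant,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# PPI network


@dataclass
class PPINetwork:
    edges: pd.DataFrame            # protein_a, protein_b, score (rescaled)
    n_nodes: int
    n_edges: int
    components: list               # list of sorted node lists, largest first
    degrees: dict
    n_self_loops_dropped: int = 0


def filter_ppi_edges(
    edge_table: pd.DataFrame, min_score: float = 0.400
) -> PPINetwork:
    """Keep interaction edges at or above the confidence cutoff.

    Scores on the STRING integer scale (any value > 1) are rescaled into
    [0, 1] by dividing by 1000.  Self-loops are dropped (counted), and the
    connected components and node degrees of the retained graph are
    computed.
    """
    import networkx as nx

    for col in ("protein_a", "protein_b", "score"):
        if col not in edge_table.columns:
            raise ValueError(f"edge table missing column {col!r}")
    df = edge_table.copy()
    score = pd.to_numeric(df["score"], errors="raise").astype(float)
    if (score > 1.0).any():
        score = score / 1000.0
    df["score"] = score
    self_loops = df["protein_a"] == df["protein_b"]
    n_loops = int(self_loops.sum())
    df = df[~self_loops]
    df = df[df["score"] >= min_score].reset_index(drop=True)

    g = nx.Graph()
    g.add_weighted_edges_from(
        zip(df["protein_a"], df["protein_b"], df["score"])
    )
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c),
    )
    return PPINetwork(
        edges=df,
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        components=comps,
        degrees=dict(g.degree()),
        n_self_loops_dropped=n_loops,
    )


# ---------------------------------------------------------------------------
# fiber geometry


def fiber_diameter_from_area(area: float) -> float:
    """Muscle-fiber diameter from its cross-sectional area, s = pi r^2."""
    if area <= 0:
        raise ValueError("fiber area must be positive")
    return 2.0 * math.sqrt(area / math.pi)


def fiber_area_from_diameter(diameter: float) -> float:
    if diameter <= 0:
        raise ValueError("fiber diameter must be positive")
    return math.pi * (diameter / 2.0) ** 2
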