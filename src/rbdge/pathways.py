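"""Pathway state overlay and over-representation analysis.

Maps gene-level differential-expression calls onto curated pathway node
definitions (MAPK, PI3K-AKT and cell-cycle diagrams) and assigns each node a
ternary state: +1 when more of its member genes are significantly up in URB
than down, -1 for the reverse, 0 for ties or no significant members.
Enrichment of a node's membership among the significant genes is scored by
the upper-tail hypergeometric test (classical over-representation analysis).

The bundled gene-set JSON is a curated, user-overridable best effort: the
published diagrams label nodes ("NT3/4", "CDK4/6", ...) without listing
probe-level membership, so the mapping here expands each label to the usual
HGNC symbols.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from scipy import stats


class GeneSetError(ValueError):
    """Raised for malformed gene-set files."""


@dataclass
class GeneSetCollection:
    pathways: dict[str, dict[str, list[str]]]   # pathway -> node -> genes
    universe: set[str] | None = None
    warnings: list[str] = field(default_factory=list)

    def all_genes(self) -> set[str]:
        return {
            g for nodes in self.pathways.values() for genes in nodes.values() for g in genes
        }


def bundled_gene_sets_path() -> Path:
    return Path(resources.files("rbdge").joinpath("data/gene_sets.json"))


def load_gene_sets(
    file: str | Path | None = None, universe: set[str] | None = None
) -> GeneSetCollection:
    """Load and validate a pathway->node->genes JSON collection.

    Member genes absent from ``universe`` (when given) produce warnings, not
    errors, since panel content varies.
    """
    path = Path(file) if file is not None else bundled_gene_sets_path()
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise GeneSetError(f"{path}: invalid JSON ({exc})") from None
    if not isinstance(payload, dict) or "pathways" not in payload:
        raise GeneSetError(f"{path}: top-level object must carry a 'pathways' key")

    pathways: dict[str, dict[str, list[str]]] = {}
    warnings: list[str] = []
    for pw_name, pw in payload["pathways"].items():
        nodes = pw.get("nodes")
        if not isinstance(nodes, dict):
            raise GeneSetError(f"pathway {pw_name!r}: missing 'nodes' mapping")
        pathways[pw_name] = {}
        for node, genes in nodes.items():
            if not isinstance(genes, list) or not all(isinstance(g, str) for g in genes):
                raise GeneSetError(f"node {pw_name}/{node}: members must be a string list")
            pathways[pw_name][node] = list(genes)
            if universe is not None:
                missing = [g for g in genes if g not in universe]
                if missing:
                    warnings.append(
                        f"{pw_name}/{node}: genes not on panel: {missing}"
                    )
    return GeneSetCollection(pathways, universe, warnings)


@dataclass
class NodeState:
    pathway: str
    node: str
    state: int       # -1, 0, +1
    n_up: int
    n_down: int
    n_ns: int


def node_states(de_results: pd.DataFrame, sets: GeneSetCollection) -> list[NodeState]:
    """Ternary node states from majority vote of significant member genes.

    Expects DE results with the URB-positive fold-change convention: a
    significant gene with log2_fc > 0 votes +1 for every node containing it.
    """
    indexed = de_results.set_index("gene")
    states = []
    for pathway, nodes in sets.pathways.items():
        for node, genes in nodes.items():
            n_up = n_down = n_ns = 0
            for gene in genes:
                if gene not in indexed.index:
                    continue
                row = indexed.loc[gene]
                if bool(row["significant"]):
                    if float(row["log2_fc"]) > 0:
                        n_up += 1
                    else:
                        n_down += 1
                else:
                    n_ns += 1
            if n_up > n_down:
                state = 1
            elif n_down > n_up:
                state = -1
            else:
                state = 0
            states.append(NodeState(pathway, node, state, n_up, n_down, n_ns))
    return states


def states_frame(states: list[NodeState]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": s.pathway, "node": s.node, "state": s.state,
                "n_up": s.n_up, "n_down": s.n_down, "n_ns": s.n_ns,
            }
            for s in states
        ]
    )


def ora_test(significant_genes: set, node_genes: set, universe: set) -> float:
    """Upper-tail hypergeometric p of seeing >= k significant node members.

    Universe size M, significant draws n, node size K, overlap k:
    p = P(X >= k), X ~ Hypergeom(M, n, K).
    """
    if not universe:
        raise GeneSetError("empty universe")
    node = set(node_genes) & set(universe)
    sig = set(significant_genes) & set(universe)
    k = len(node & sig)
    M, n, K = len(universe), len(sig), len(node)
    return float(stats.hypergeom.sf(k - 1, M, n, K))
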