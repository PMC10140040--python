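"""Assembly of validated interactions into a per-phenotype network.

Nodes are (gene, expression-state) records: the state is the side of the
median split the gene occupies in the winning configuration's target
quadrant (activating gene -> "high", deactivating -> "low").  A gene that
interacts in opposite states appears as two distinct nodes.  Edges carry
the score, the BH-adjusted significance and specificity Q-values, the
direction of phenotype change toward the target quadrant, and a
ligand-receptor flag looked up in a static interaction-pair table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .io import ExpressionMatrix, GeneListPair, LigandReceptorTable
from .validation import ValidatedInteraction

#: winning configuration -> (gene1 state, gene2 state) in the target quadrant
CONFIG_STATES = {
    "act_act": ("high", "high"),
    "deact_deact": ("low", "low"),
    "act_deact": ("high", "low"),
    "deact_act": ("low", "high"),
}


@dataclass(frozen=True)
class NetworkNode:
    gene: str
    gene_class: str  # TAP | ICP
    state: str       # high | low

    @property
    def id(self) -> str:
        return f"{self.gene}|{self.state}"


@dataclass(frozen=True)
class NetworkEdge:
    node_a: str
    node_b: str
    S: float
    Q_significance: float
    Q_specificity: float
    direction: str  # up | down
    is_ligand_receptor: bool = False
    gene_a: str = ""
    gene_b: str = ""


@dataclass(frozen=True)
class InteractionNetwork:
    iap: str
    nodes: tuple[NetworkNode, ...]
    edges: tuple[NetworkEdge, ...]


def build_network(
    validated: list[ValidatedInteraction], score_cutoff: float = 0.0
) -> InteractionNetwork:
    """Keep passing interactions with |S| >= cutoff; derive node states.

    All inputs must share one phenotype.  The TAP gene of each pair
    becomes (or reuses) a TAP node, the ICP gene an ICP node, each in the
    state given by the winning configuration.
    """
    iaps = {v.result.iap for v in validated}
    if len(iaps) > 1:
        raise ValueError(f"mixed phenotypes in network input: {sorted(iaps)}")
    iap = iaps.pop() if iaps else ""
    nodes: dict[str, NetworkNode] = {}
    edges: list[NetworkEdge] = []
    for v in validated:
        r = v.result
        if not v.passed or r.S is None or abs(r.S) < score_cutoff:
            continue
        state1, state2 = CONFIG_STATES[r.config]
        n1 = NetworkNode(r.pair[0], "TAP", state1)
        n2 = NetworkNode(r.pair[1], "ICP", state2)
        nodes.setdefault(n1.id, n1)
        nodes.setdefault(n2.id, n2)
        edges.append(
            NetworkEdge(
                node_a=n1.id,
                node_b=n2.id,
                S=r.S,
                Q_significance=v.significance.Q,
                Q_specificity=v.specificity.Q,
                direction="up" if r.sign == 1 else "down",
                gene_a=r.pair[0],
                gene_b=r.pair[1],
            )
        )
    return InteractionNetwork(
        iap=iap, nodes=tuple(nodes.values()), edges=tuple(edges)
    )


def annotate_ligand_receptor(
    network: InteractionNetwork, lr: LigandReceptorTable
) -> InteractionNetwork:
    """Flag edges whose unordered gene pair occurs in the table (idempotent)."""
    edges = tuple(
        replace(e, is_ligand_receptor=lr.contains(e.gene_a, e.gene_b))
        for e in network.edges
    )
    return InteractionNetwork(iap=network.iap, nodes=network.nodes, edges=edges)


def expand_gene_lists(
    lists: GeneListPair,
    lr: LigandReceptorTable,
    expr: ExpressionMatrix | None = None,
) -> GeneListPair:
    """Append each gene's interaction partners to its own list.

    Partners of TAP genes join the TAP list, partners of ICP genes the
    ICP list; duplicates are removed and partners absent from the
    expression matrix are dropped with a warning.
    """
    present = set(expr.genes) if expr is not None else None

    def grow(genes: tuple[str, ...]) -> tuple[str, ...]:
        out = list(genes)
        seen = set(genes)
        for g in genes:
            for partner in lr.partners(g):
                if partner in seen:
                    continue
                if present is not None and partner not in present:
                    warnings.warn(
                        f"ligand-receptor partner {partner!r} of {g!r} absent "
                        f"from expression matrix; not added"
                    )
                    continue
                out.append(partner)
                seen.add(partner)
        return tuple(out)

    return GeneListPair(grow(lists.tap_genes), grow(lists.icp_genes))
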