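"""GO-term over-representation analysis on propagated annotations.

Parses an OBO ontology restricted to the biological_process branch,
propagates gene annotations up the is_a hierarchy (a gene annotated to a
child term is annotated to every ancestor, so the root ends up annotated
to all genes), filters terms by annotation frequency, and scores gene
sets with an upper-tail hypergeometric test.

For term i the counts follow the usual over-representation convention:
m genes carry term i in the whole annotated universe, n genes carry any
term, k genes are selected, and x of the selected genes carry term i.
Then p = P(X >= x) for X ~ Hypergeometric(n, m, k).

Only is_a edges are traversed; conditional (parent-child decorrelated)
methods are deliberately out of scope — the score is the plain
hypergeometric on propagated counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy.special import gammaln, logsumexp

from .diffexpr import bh_adjust

__all__ = [
    "GoDag",
    "AnnotationSet",
    "OboFormatError",
    "GafFormatError",
    "parse_obo",
    "parse_annotations",
    "propagate",
    "filter_terms",
    "hypergeom_p",
    "enrich",
    "DEFAULT_MIN_EXCL",
    "DEFAULT_MAX_EXCL",
    "DEFAULT_ALPHA",
]

BIOLOGICAL_PROCESS = "biological_process"
DEFAULT_MIN_EXCL = 5     # term kept iff count > 5 ...
DEFAULT_MAX_EXCL = 300   # ... and count < 300 (strict bounds)
DEFAULT_ALPHA = math.exp(-3)  # reporting threshold on the adjusted p


class OboFormatError(ValueError):
    pass


class GafFormatError(ValueError):
    pass


@dataclass
class GoDag:
    """Rooted acyclic is_a hierarchy of GO terms.

    ``graph`` holds directed child -> parent edges; ``root`` is the single
    term with no parent (biological_process after restriction).
    """

    graph: nx.DiGraph
    root: str
    names: dict = field(default_factory=dict)
    _anc_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise OboFormatError("ontology graph contains a cycle")
        if self.root not in self.graph:
            raise OboFormatError("designated root is not in the graph")

    @property
    def terms(self) -> set:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> frozenset:
        """All terms reachable from ``term`` by following is_a edges upward."""
        hit = self._anc_cache.get(term)
        if hit is None:
            hit = frozenset(nx.descendants(self.graph, term))
            self._anc_cache[term] = hit
        return hit

    def name(self, term: str) -> str:
        return self.names.get(term, term)


def parse_obo(path) -> GoDag:
    """Read an OBO file into a biological_process GoDag.

    Obsolete terms are dropped (obonet's default), terms outside the
    biological_process namespace are dropped with their edges, and only
    is_a relations are retained. The restricted graph must be acyclic
    with exactly one root, otherwise an :class:`OboFormatError` is raised.
    Terms that cannot reach the root are dropped with a warning.
    """
    raw = obonet.read_obo(path)
    g = nx.DiGraph()
    names = {}
    for node, attrs in raw.nodes(data=True):
        if attrs.get("namespace", BIOLOGICAL_PROCESS) != BIOLOGICAL_PROCESS:
            continue
        g.add_node(node)
        names[node] = attrs.get("name", node)
    for child, parent, key in raw.edges(keys=True):
        if key != "is_a":
            continue
        if child in g and parent in g:
            g.add_edge(child, parent)
    if g.number_of_nodes() == 0:
        raise OboFormatError("no biological_process terms found")
    if not nx.is_directed_acyclic_graph(g):
        raise OboFormatError("is_a relations contain a cycle")
    roots = [t for t in g.nodes if g.out_degree(t) == 0]
    if len(roots) != 1:
        raise OboFormatError(
            f"expected exactly one root term, found {len(roots)}: {sorted(roots)[:5]}"
        )
    root = roots[0]
    reachable = {root} | set(nx.ancestors(g, root))
    dropped = set(g.nodes) - reachable
    if dropped:
        warnings.warn(f"dropping {len(dropped)} terms with no path to the root")
        g.remove_nodes_from(dropped)
    return GoDag(g, root, {t: names[t] for t in g.nodes})


def parse_annotations(path, format: str = "gaf") -> dict:
    """Read direct gene -> term annotations.

    ``format='gaf'`` expects GAF 1.x/2.x rows (15 or 17 tab-separated
    columns, ``!`` comment lines skipped); rows whose qualifier contains
    NOT are excluded per GAF semantics. ``format='two_column'`` expects
    plain ``gene<TAB>term`` rows. Duplicate pairs collapse to one.
    """
    direct: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if format == "gaf":
                if len(fields) not in (15, 17):
                    raise GafFormatError(
                        f"line {lineno}: expected 15 or 17 columns, got {len(fields)}"
                    )
                qualifier = fields[3]
                if "NOT" in qualifier.split("|"):
                    continue
                gene, term = fields[2], fields[4]
            elif format == "two_column":
                if len(fields) != 2:
                    raise GafFormatError(
                        f"line {lineno}: expected 2 columns, got {len(fields)}"
                    )
                gene, term = fields
            else:
                raise ValueError(f"unknown annotation format {format!r}")
            direct.setdefault(gene, set()).add(term)
    return {g: frozenset(ts) for g, ts in direct.items()}


@dataclass
class AnnotationSet:
    """Direct and ancestry-closed annotations plus the term -> genes index."""

    direct: dict
    closure: dict
    term_genes: dict

    def term_counts(self) -> dict:
        return {t: len(gs) for t, gs in self.term_genes.items()}

    @property
    def universe(self) -> frozenset:
        return frozenset(self.closure)


def propagate(dag: GoDag, direct: Mapping) -> AnnotationSet:
    """Close annotations under ancestry: closure(g) = U_t ({t} | ancestors(t)).

    Direct terms absent from the DAG are reported via a warning and dropped;
    a gene whose every direct term is unknown disappears from the closure.
    """
    unknown = set()
    closure = {}
    kept_direct = {}
    for gene, terms in direct.items():
        closed: set = set()
        kept: set = set()
        for t in terms:
            if t not in dag.graph:
                unknown.add(t)
                continue
            kept.add(t)
            closed.add(t)
            closed |= dag.ancestors(t)
        if kept:
            kept_direct[gene] = frozenset(kept)
            closure[gene] = frozenset(closed)
    if unknown:
        warnings.warn(
            f"dropped {len(unknown)} annotation terms absent from the ontology: "
            f"{sorted(unknown)[:5]}"
        )
    term_genes: dict = {}
    for gene, terms in closure.items():
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    term_genes = {t: frozenset(gs) for t, gs in term_genes.items()}
    return AnnotationSet(kept_direct, closure, term_genes)


def filter_terms(
    ann: AnnotationSet,
    min_excl: int = DEFAULT_MIN_EXCL,
    max_excl: int = DEFAULT_MAX_EXCL,
) -> set:
    """Terms whose propagated gene count c satisfies min_excl < c < max_excl.

    Both bounds are strict: a term with exactly ``min_excl`` or exactly
    ``max_excl`` genes is removed. Counts are over the entire annotated
    universe, never the selected set; the root (annotated to every gene)
    falls to the high-frequency filter in any realistically sized universe.
    """
    if min_excl >= max_excl:
        raise ValueError("min_excl must be below max_excl")
    return {t for t, gs in ann.term_genes.items() if min_excl < len(gs) < max_excl}


def hypergeom_p(x: int, k: int, m: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x), in log space.

    X counts how many of the k selected genes carry the term, drawing
    without replacement from n genes of which m carry it:

        P(X >= x) = sum_{j=x}^{min(m,k)} C(m,j) C(n-m,k-j) / C(n,k)
    """
    for name, v in (("x", x), ("k", k), ("m", m), ("n", n)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer")
    if m > n or k > n:
        raise ValueError("require m <= n and k <= n")
    if x > min(m, k):
        raise ValueError("require x <= min(m, k)")
    if x == 0:
        return 1.0
    j = np.arange(max(x, k - (n - m)), min(m, k) + 1)
    if j.size == 0:
        return 0.0
    log_pmf = (
        gammaln(m + 1) - gammaln(j + 1) - gammaln(m - j + 1)
        + gammaln(n - m + 1) - gammaln(k - j + 1) - gammaln(n - m - (k - j) + 1)
        - (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))
    )
    return float(min(1.0, math.exp(logsumexp(log_pmf))))


def _bonferroni(p: np.ndarray) -> np.ndarray:
    return np.minimum(p * len(p), 1.0)


def enrich(
    selected: Iterable,
    ann: AnnotationSet,
    dag: GoDag | None = None,
    min_excl: int = DEFAULT_MIN_EXCL,
    max_excl: int = DEFAULT_MAX_EXCL,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Score a gene set for term over-representation.

    Returns one row per retained term with columns
    term, name, m, n, k, x, p_raw, p_adjusted, sorted by adjusted then
    raw p. ``n`` is the number of genes with any annotation, ``k`` the
    selected genes inside that universe; selected genes outside the
    universe are dropped with a warning.
    """
    universe = ann.universe
    selected = set(selected)
    outside = selected - universe
    if outside:
        warnings.warn(
            f"{len(outside)} selected genes are outside the annotated universe "
            "and were dropped"
        )
    sel = selected & universe
    columns = ["term", "name", "m", "n", "k", "x", "p_raw", "p_adjusted"]
    if not sel:
        warnings.warn("empty selected gene set; no enrichment computed")
        return pd.DataFrame(columns=columns)
    n = len(universe)
    k = len(sel)
    terms = sorted(filter_terms(ann, min_excl, max_excl))
    records = []
    for t in terms:
        genes_t = ann.term_genes[t]
        m = len(genes_t)
        x = len(genes_t & sel)
        records.append((t, dag.name(t) if dag else t, m, n, k, x, hypergeom_p(x, k, m, n)))
    out = pd.DataFrame(records, columns=columns[:-1])
    p = out["p_raw"].to_numpy()
    if adjust == "bh":
        out["p_adjusted"] = bh_adjust(p) if len(p) else p
    elif adjust == "bonferroni":
        out["p_adjusted"] = _bonferroni(p)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out = out.sort_values(["p_adjusted", "p_raw", "term"], kind="stable")
    return out.reset_index(drop=True)
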