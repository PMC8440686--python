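"""HPO ontology handling and phenotype-driven on-the-fly gene panels.

A patient coded with a broad term (e.g. "Seizure") should recruit genes
annotated to any of its more specific descendants, so panel construction
expands each patient term downwards through the ontology before looking
genes up in the term-to-gene map (standard HPO practice; switchable off).
The ontology root and modifier-style branches (mode of inheritance,
clinical modifier) never participate in matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .models_io import GenePanel, HPO_PATTERN, PhenotypeRecord

logger = logging.getLogger("varprio")

ROOT_TERM = "HP:0000001"
#: branches excluded from gene matching when present in the ontology
DEFAULT_EXCLUDED_BRANCHES = ("HP:0000005", "HP:0012823")  # inheritance, clinical modifier


@dataclass
class Ontology:
    """A DAG of HPO terms; ``parents`` maps each term to its is_a parents."""

    terms: set[str]
    parents: dict[str, set[str]]
    children: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        for term, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise ValueError(f"parent {p} of {term} is not an ontology term")
        self._check_acyclic()
        self.children = {t: set() for t in self.terms}
        for term, ps in self.parents.items():
            for p in ps:
                self.children[p].add(term)

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for p in self.parents.get(node, ()):
                s = state.get(p)
                if s == 1:
                    raise ValueError(f"ontology cycle involving {node}")
                if s is None:
                    visit(p)
            state[node] = 2

        for t in self.terms:
            if state.get(t) is None:
                visit(t)

    @classmethod
    def from_obo(cls, path: str | Path) -> "Ontology":
        """Load an OBO file (is_a edges only) via obonet."""
        import obonet

        graph = obonet.read_obo(str(path))
        terms = set(graph.nodes)
        parents: dict[str, set[str]] = {t: set() for t in terms}
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                parents[child].add(parent)
        return cls(terms=terms, parents=parents)

    def descendants(self, term: str) -> set[str]:
        """All terms below ``term`` (term itself excluded)."""
        out: set[str] = set()
        stack = [term]
        while stack:
            for child in self.children.get(stack.pop(), ()):
                if child not in out:
                    out.add(child)
                    stack.append(child)
        return out

    def branch(self, term: str) -> set[str]:
        return {term} | self.descendants(term)


def ancestor_closure(terms: Iterable[str], ontology: Ontology,
                     include_root: bool = False) -> set[str]:
    """Terms plus all their ancestors, excluding the ontology root.

    Terms unknown to the ontology are dropped with a warning.
    """
    closure: set[str] = set()
    stack = []
    for t in terms:
        if t in ontology.terms:
            stack.append(t)
        else:
            logger.warning("dropping unknown HPO term %s", t)
    while stack:
        term = stack.pop()
        if term in closure:
            continue
        closure.add(term)
        stack.extend(ontology.parents.get(term, ()))
    if not include_root:
        closure.discard(ROOT_TERM)
    return closure


def load_hpo_gene_map(path: str | Path) -> dict[str, set[str]]:
    """Read a TSV term-to-gene map (columns: hpo_id, gene)."""
    mapping: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("hpo"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            continue
        term, gene = parts[0].strip(), parts[1].strip().upper()
        if HPO_PATTERN.match(term) and gene:
            mapping.setdefault(term, set()).add(gene)
    return mapping


def on_the_fly_panel(record: PhenotypeRecord,
                     hpo_gene_map: Mapping[str, set[str]],
                     ontology: Ontology,
                     mode: str = "union",
                     expand: bool = True,
                     excluded_branches: Iterable[str] = DEFAULT_EXCLUDED_BRANCHES,
                     ) -> GenePanel:
    """Build the per-patient gene panel from the patient's HPO terms.

    Each patient term recruits the genes annotated to the term or (when
    ``expand``) to any of its descendants. ``mode="union"`` returns the plain
    union; ``mode="ranked"`` additionally orders genes by the number of
    distinct patient terms that recruited them (ties broken by symbol).
    An empty result (no valid terms) yields an empty panel with a warning so
    the engine can fall back to requiring an explicit panel.
    """
    if mode not in ("union", "ranked"):
        raise ValueError(f"unknown panel mode {mode!r}")
    excluded: set[str] = {ROOT_TERM}
    for b in excluded_branches:
        if b in ontology.terms:
            excluded |= ontology.branch(b)

    valid_terms = []
    for t in record.hpo_terms:
        if t in ontology.terms and t not in excluded:
            valid_terms.append(t)
        else:
            logger.warning("experiment %s: HPO term %s not usable for panel matching",
                           record.experiment_id, t)

    counts: dict[str, int] = {}
    for term in valid_terms:
        expansion = (ontology.branch(term) if expand else {term}) - excluded
        recruited: set[str] = set()
        for t in expansion:
            recruited |= hpo_gene_map.get(t, set())
        for gene in recruited:
            counts[gene] = counts.get(gene, 0) + 1

    if not counts:
        logger.warning("experiment %s: on-the-fly panel is empty", record.experiment_id)
    ranked = sorted(counts, key=lambda g: (-counts[g], g))
    panel = GenePanel(panel_id=f"otf:{record.experiment_id}", source="on-the-fly",
                      genes=set(counts))
    if mode == "ranked":
        panel.ranked = ranked
    return panel
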