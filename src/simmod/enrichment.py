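"""Functional enrichment of modules: hypergeometric tests with the
parent-child correction, Holm adjustment and fold-enrichment scores.

For a module of ``n_m`` genes and a term annotating ``K`` of the ``N``
population genes, ``k`` of them in the module, the classic test is the upper
tail of a hypergeometric distribution (one-tailed Fisher's exact test),
``P(X >= k)``. Because a gene annotated to a term is implicitly annotated to
all of the term's ancestors, classic testing inherits significance up the
ontology; the parent-child method conditions on the parents instead,
replacing the population by the genes annotated to the union of the term's
direct parents. Per-module p-value families are adjusted with the
Bonferroni-Holm step-down correction, and each tested term receives a fold
enrichment score (k/n_m)/(K/N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from scipy.stats import hypergeom

from simmod.errors import InputError, SimModError
from simmod.multiplex import Partition

logger = logging.getLogger(__name__)

_RELATIONS = ("is_a", "part_of")


@dataclass(frozen=True)
class OntologyDAG:
    """Term hierarchy: acyclic is_a/part_of parent links.

    ``parents`` maps each term to its set of direct parents; roots have an
    empty set. Every term reachable as a parent must itself be a key.
    """

    parents: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        norm = {t: frozenset(p) for t, p in self.parents.items()}
        for term, ps in norm.items():
            for p in ps:
                if p not in norm:
                    raise InputError(f"term {term!r} has unknown parent {p!r}")
        object.__setattr__(self, "parents", norm)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 1 = on stack, 2 = done

        def visit(t: str) -> None:
            state[t] = 1
            for p in self.parents[t]:
                mark = state.get(p)
                if mark == 1:
                    raise InputError(f"ontology contains a cycle through {t!r}")
                if mark is None:
                    visit(p)
            state[t] = 2

        for term in self.parents:
            if term not in state:
                visit(term)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t, p in self.parents.items() if not p)

    def ancestors(self, term: str) -> frozenset[str]:
        """All strict ancestors of ``term`` over is_a/part_of."""
        if term not in self.parents:
            raise InputError(f"unknown term {term!r}")
        seen: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.parents[t])
        return frozenset(seen)

    @classmethod
    def from_obo(cls, path: str | Path) -> "OntologyDAG":
        """Load an OBO 1.2 ontology, keeping is_a and part_of links."""
        import obonet

        graph = obonet.read_obo(str(path))
        parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
        for child, parent, rel in graph.edges(keys=True):
            if rel in _RELATIONS:
                parents[child].add(parent)
        return cls({t: frozenset(p) for t, p in parents.items()})


@dataclass(frozen=True)
class AnnotationSet:
    """Gene-to-term annotations propagated to ontology ancestors.

    ``population`` is the gene universe N against which enrichment is
    measured (typically the network's node set); every annotated gene must
    belong to it.
    """

    gene_to_terms: dict[str, frozenset[str]]
    population: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "population", frozenset(self.population))
        norm = {g: frozenset(ts) for g, ts in self.gene_to_terms.items() if ts}
        outside = set(norm) - self.population
        if outside:
            raise InputError(
                f"{len(outside)} annotated gene(s) not in population, "
                f"e.g. {sorted(outside)[:3]}"
            )
        object.__setattr__(self, "gene_to_terms", norm)

    def genes_annotated(self, term: str) -> frozenset[str]:
        return frozenset(g for g, ts in self.gene_to_terms.items() if term in ts)

    def term_to_genes(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for g, ts in self.gene_to_terms.items():
            for t in ts:
                out.setdefault(t, set()).add(g)
        return {t: frozenset(gs) for t, gs in out.items()}

    @classmethod
    def from_direct(
        cls,
        direct: Mapping[str, Iterable[str]],
        dag: OntologyDAG,
        population: Iterable[str] | None = None,
    ) -> "AnnotationSet":
        """Build from direct annotations, propagating each term to its ancestors."""
        gene_to_terms: dict[str, frozenset[str]] = {}
        for gene, terms in direct.items():
            closed: set[str] = set()
            for t in terms:
                if t not in dag.parents:
                    raise InputError(f"gene {gene!r} annotated to unknown term {t!r}")
                closed.add(t)
                closed |= dag.ancestors(t)
            gene_to_terms[gene] = frozenset(closed)
        pop = frozenset(population) if population is not None else frozenset(gene_to_terms)
        return cls(gene_to_terms=gene_to_terms, population=pop)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        dag: OntologyDAG,
        population: Iterable[str] | None = None,
    ) -> "AnnotationSet":
        """Plain two-column TSV: gene <TAB> term; '#' comments skipped."""
        direct: dict[str, set[str]] = {}
        path = Path(path)
        if not path.exists():
            raise InputError(f"annotation file not found: {path}")
        with path.open(encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise InputError(f"{path}:{lineno}: expected 2 tab-separated columns")
                direct.setdefault(fields[0].strip(), set()).add(fields[1].strip())
        return cls.from_direct(direct, dag, population)

    @classmethod
    def from_gaf(
        cls,
        path: str | Path,
        dag: OntologyDAG,
        population: Iterable[str] | None = None,
        exclude_evidence: Iterable[str] = (),
    ) -> "AnnotationSet":
        """GAF 2.x: DB object id (col 2) and GO id (col 5); NOT-qualified rows
        and rows whose evidence code (col 7) is excluded are skipped, as are
        annotations to terms absent from the ontology."""
        excluded = set(exclude_evidence)
        direct: dict[str, set[str]] = {}
        path = Path(path)
        if not path.exists():
            raise InputError(f"annotation file not found: {path}")
        with path.open(encoding="utf-8") as fh:
            for raw in fh:
                if raw.startswith("!") or not raw.strip():
                    continue
                fields = raw.rstrip("\n").split("\t")
                if len(fields) < 7:
                    continue
                gene, qualifier, term, evidence = fields[1], fields[3], fields[4], fields[6]
                if "NOT" in qualifier.split("|"):
                    continue
                if evidence in excluded:
                    continue
                if term not in dag.parents:
                    logger.warning("skipping annotation to unknown term %s", term)
                    continue
                direct.setdefault(gene, set()).add(term)
        return cls.from_direct(direct, dag, population)


@dataclass(frozen=True)
class EnrichmentResult:
    """One (module, term) test."""

    module: int
    term: str
    module_size: int
    module_term_count: int
    population_size: int
    population_term_count: int
    raw_p: float
    adjusted_p: float
    score: float
    enriched: bool


def hypergeom_upper_tail(k: int, n_m: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n_m draws)."""
    if not (0 <= k <= min(n_m, K) and 0 <= n_m <= N and 0 <= K <= N):
        raise InputError(
            f"inconsistent hypergeometric counts: k={k}, n_m={n_m}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n_m)))


def enrichment_score(k: int, n_m: int, K: int, N: int) -> float:
    """Fold enrichment (k/n_m)/(K/N): >1 means over-representation."""
    if n_m <= 0:
        raise InputError("module size must be positive")
    if K <= 0:
        raise InputError("population term count must be positive for a score")
    if N <= 0:
        raise InputError("population size must be positive")
    return (k / n_m) / (K / N)


def holm_adjust(pvals: list[float]) -> list[float]:
    """Bonferroni-Holm step-down adjusted p-values, in the input order.

    Sorted ascending, the i-th adjusted value is
    ``max_{j<=i} min(1, (m-j+1) * p_(j))``; the running maximum enforces
    monotonicity.
    """
    for p in pvals:
        if not (0.0 <= p <= 1.0):
            raise InputError(f"p-value outside [0, 1]: {p!r}")
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * pvals[idx]))
        adjusted[idx] = running
    return adjusted


def parent_child_p(
    term: str,
    module_genes: Iterable[str],
    annotations: AnnotationSet,
    dag: OntologyDAG,
) -> float:
    """Parent-child (union) upper-tail p-value for a term in a module.

    The population is replaced by the genes annotated to the union of the
    term's direct parents; the term's genes are necessarily a subset of it
    because annotations are ancestor-closed. Root terms have no parents and
    are not testable: p = 1.
    """
    if term not in dag.parents:
        raise InputError(f"unknown term {term!r}")
    module = frozenset(module_genes)
    outside = module - annotations.population
    if outside:
        raise InputError(
            f"module gene(s) outside population, e.g. {sorted(outside)[:3]}"
        )
    parents = dag.parents[term]
    if not parents:
        return 1.0
    parent_pop: set[str] = set()
    for p in parents:
        parent_pop |= annotations.genes_annotated(p)
    term_genes = annotations.genes_annotated(term)
    k = len(module & term_genes)
    n_prime = len(module & parent_pop)
    K_prime = len(term_genes)
    N_prime = len(parent_pop)
    if N_prime == 0:
        return 1.0
    return hypergeom_upper_tail(k, n_prime, K_prime, N_prime)


def _classic_p(term: str, module: frozenset[str], annotations: AnnotationSet) -> float:
    term_genes = annotations.genes_annotated(term)
    return hypergeom_upper_tail(
        len(module & term_genes),
        len(module),
        len(term_genes),
        len(annotations.population),
    )


def enrich_partition(
    partition: Partition,
    annotations: AnnotationSet,
    dag: OntologyDAG,
    alpha: float = 0.05,
    method: str = "parent_child",
) -> list[EnrichmentResult]:
    """Test every (module, term) pair with at least one annotated module gene.

    Modules with fewer than two annotated genes are skipped with a warning.
    Root terms are excluded from the testing family (the parent-child test
    is undefined for them and the classic test is degenerate with p = 1).
    The Holm correction is applied within each module's family of tested
    terms; a term is *enriched* when its adjusted p-value is ≤ ``alpha``.
    """
    if method not in ("parent_child", "classic"):
        raise InputError(f"unknown method {method!r}")
    if not (partition.domain & annotations.population):
        raise SimModError("no overlap between partition domain and annotation population")
    results: list[EnrichmentResult] = []
    N = len(annotations.population)
    term_genes = annotations.term_to_genes()
    roots = dag.roots
    for label, members in partition.modules().items():
        module = frozenset(members & annotations.population)
        annotated = [g for g in module if annotations.gene_to_terms.get(g)]
        if len(annotated) < 2:
            logger.warning(
                "module %d skipped: only %d annotated gene(s)", label, len(annotated)
            )
            continue
        terms = sorted(
            {t for g in annotated for t in annotations.gene_to_terms[g]} - roots
        )
        if not terms:
            continue
        raws: list[float] = []
        rows: list[tuple[str, int, int]] = []
        for term in terms:
            tg = term_genes.get(term, frozenset())
            k = len(module & tg)
            if method == "parent_child":
                p = parent_child_p(term, module, annotations, dag)
            else:
                p = _classic_p(term, module, annotations)
            raws.append(p)
            rows.append((term, k, len(tg)))
        adjusted = holm_adjust(raws)
        for (term, k, K), raw, adj in zip(rows, raws, adjusted):
            results.append(
                EnrichmentResult(
                    module=label,
                    term=term,
                    module_size=len(module),
                    module_term_count=k,
                    population_size=N,
                    population_term_count=K,
                    raw_p=raw,
                    adjusted_p=adj,
                    score=enrichment_score(k, len(module), K, N),
                    enriched=adj <= alpha,
                )
            )
    return results


def summarize_enrichment(results: list[EnrichmentResult]) -> dict:
    """Per-module summary: best enriched score, plus the enriched-module fraction.

    Returns ``{"modules": {label: {...}}, "enriched_module_fraction": float}``
    over the modules that were testable (appear in ``results``).
    """
    per_module: dict[int, dict] = {}
    for r in results:
        entry = per_module.setdefault(
            r.module,
            {"n_tested": 0, "n_enriched": 0, "max_enriched_score": 0.0, "best_term": None},
        )
        entry["n_tested"] += 1
        if r.enriched:
            entry["n_enriched"] += 1
            if r.score > entry["max_enriched_score"]:
                entry["max_enriched_score"] = r.score
                entry["best_term"] = r.term
    n_modules = len(per_module)
    n_enriched = sum(1 for e in per_module.values() if e["n_enriched"] > 0)
    return {
        "modules": per_module,
        "enriched_module_fraction": (n_enriched / n_modules) if n_modules else 0.0,
    }
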