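"""GO over-representation of CVGs and fundamental-process classification.

Enrichment is the one-sided Fisher test — the hypergeometric upper
tail — on true-path-propagated annotations (is_a and part_of), with BH
FDR across tested terms. Group classification replaces a manual
curation step: member genes' propagated BP terms are mapped onto nine
named fundamental processes through a term->process table, decided by
majority vote; groups whose genes map to nothing are UNDEFINED.
Annotation provenance is split into experimental (IDA, IEP, IPI, IMP,
IGI by default) versus electronic evidence codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import obonet
import pandas as pd
from scipy import stats

from .calling import bh_adjust
from .config import PipelineConfig
from .orthology import CVGGroup

logger = logging.getLogger(__name__)

#: Canonical order of the nine fundamental vascular-development
#: processes; classification ties break toward the earlier entry.
PROCESS_ORDER = (
    "cell organization and biogenesis",
    "cell wall formation",
    "developmental process",
    "metabolic process",
    "response to abiotic and biotic stimulus",
    "response to hormones",
    "signal transduction pathway",
    "transcriptional regulation",
    "transport",
)

UNDEFINED = "UNDEFINED"


class EnrichmentError(ValueError):
    pass


class GeneAnnotation(NamedTuple):
    gene_id: str
    term_id: str
    evidence_code: str


@dataclass
class OntologyDag:
    """Minimal GO DAG view: per-term name, namespace and parents
    (is_a + part_of)."""

    names: dict[str, str]
    namespaces: dict[str, str]
    parents: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        unknown = {
            p for ps in self.parents.values() for p in ps if p not in self.parents
        }
        if unknown:
            raise EnrichmentError(f"parent terms missing from DAG: {sorted(unknown)[:5]}")

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable from ``term`` via parent links, inclusive."""
        if term not in self.parents:
            raise EnrichmentError(f"unknown term {term!r}")
        seen: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            stack.extend(self.parents[t])
        return frozenset(seen)


def load_ontology(path: str | Path) -> OntologyDag:
    """Read an OBO 1.2 file; obsolete terms are excluded."""
    graph = obonet.read_obo(path, ignore_obsolete=True)
    names, namespaces, parents = {}, {}, {}
    for term, data in graph.nodes(data=True):
        names[term] = data.get("name", term)
        namespaces[term] = data.get("namespace", "biological_process")
        ps = set()
        for _, parent, key in graph.out_edges(term, keys=True):
            if key in ("is_a", "part_of"):
                ps.add(parent)
        parents[term] = frozenset(ps)
    dag = OntologyDag(names=names, namespaces=namespaces, parents=parents)
    # acyclicity check: ancestors() on a cyclic input would terminate,
    # so verify with a topological argument instead
    import networkx as nx

    g = nx.DiGraph(
        (t, p) for t, ps in parents.items() for p in ps
    )
    if not nx.is_directed_acyclic_graph(g):
        raise EnrichmentError("ontology contains a cycle")
    return dag


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from GAF 2.x or a 3-column TSV.

    GAF rows use columns 2 (gene), 5 (term) and 7 (evidence); rows with
    a NOT qualifier are skipped. The TSV form needs a header with
    gene_id, term_id, evidence_code.
    """
    path = Path(path)
    annotations: list[GeneAnnotation] = []
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        is_gaf = first.startswith("!") or len(first.rstrip("\n").split("\t")) >= 15
        if is_gaf:
            for line in fh:
                if line.startswith("!") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 7:
                    continue
                if "NOT" in f[3].split("|"):
                    continue
                annotations.append(GeneAnnotation(f[1], f[4], f[6]))
            return annotations
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "term_id", "evidence_code"):
        if col not in df.columns:
            raise EnrichmentError(f"annotation file missing column {col!r}")
    return [
        GeneAnnotation(g, t, e)
        for g, t, e in zip(df["gene_id"], df["term_id"], df["evidence_code"])
    ]


def propagate_annotations(
    dag: OntologyDag, annotations: Iterable[GeneAnnotation]
) -> dict[str, frozenset[str]]:
    """True-path closure: each gene's terms plus all their ancestors."""
    dropped = 0
    direct: dict[str, set[str]] = {}
    for ann in annotations:
        if ann.term_id not in dag:
            dropped += 1
            continue
        direct.setdefault(ann.gene_id, set()).add(ann.term_id)
    if dropped:
        logger.warning(
            "propagate_annotations: dropped %d annotations to unknown terms",
            dropped,
        )
    closure_cache: dict[str, frozenset[str]] = {}
    out: dict[str, frozenset[str]] = {}
    for gene, terms in direct.items():
        full: set[str] = set()
        for t in terms:
            if t not in closure_cache:
                closure_cache[t] = dag.ancestors(t)
            full |= closure_cache[t]
        out[gene] = frozenset(full)
    return out


def hypergeom_test(
    sample_count: int,
    sample_total: int,
    background_count: int,
    background_total: int,
) -> float:
    """Upper-tail hypergeometric P(X >= sample_count).

    X counts term-annotated genes in a draw of ``sample_total`` from a
    background of ``background_total`` containing ``background_count``
    annotated genes.
    """
    if not (
        0 <= sample_count <= sample_total
        and 0 <= background_count <= background_total
        and sample_total <= background_total
        and sample_count <= background_count
    ):
        raise EnrichmentError(
            f"inconsistent counts: {sample_count}/{sample_total} vs "
            f"{background_count}/{background_total}"
        )
    return float(
        stats.hypergeom.sf(
            sample_count - 1, background_total, background_count, sample_total
        )
    )


def enrich(
    sample_genes: set[str],
    background_genes: set[str],
    dag: OntologyDag,
    annotations: Iterable[GeneAnnotation],
    config: PipelineConfig,
    namespace: str = "biological_process",
    background_mode: str = "annotated",
) -> pd.DataFrame:
    """Term over-representation of ``sample_genes`` within the background.

    ``background_mode='annotated'`` (default) restricts the universe to
    genes carrying >= 1 propagated annotation; ``'all'`` keeps every
    background gene. One row per propagated term (in ``namespace``) hit
    by >= 1 sample gene, with hypergeometric p, BH FDR across tested
    terms, and the significance flag at fdr < config.fdr_threshold.
    """
    if not background_genes:
        raise EnrichmentError("empty background")
    if not sample_genes <= background_genes:
        extra = sorted(sample_genes - background_genes)[:5]
        raise EnrichmentError(f"sample genes outside background: {extra}")
    gene_terms = propagate_annotations(dag, annotations)
    if background_mode == "annotated":
        universe = {g for g in background_genes if g in gene_terms}
        sample = {g for g in sample_genes if g in gene_terms}
    elif background_mode == "all":
        universe, sample = set(background_genes), set(sample_genes)
    else:
        raise EnrichmentError(f"unknown background_mode {background_mode!r}")
    if not universe:
        raise EnrichmentError("no annotated genes in background")

    term_bg: dict[str, int] = {}
    term_sample: dict[str, int] = {}
    for g in universe:
        for t in gene_terms.get(g, ()):
            if dag.namespaces.get(t) != namespace:
                continue
            term_bg[t] = term_bg.get(t, 0) + 1
            if g in sample:
                term_sample[t] = term_sample.get(t, 0) + 1

    tested = sorted(term_sample)
    n_s, n_b = len(sample), len(universe)
    pvals = np.array(
        [hypergeom_test(term_sample[t], n_s, term_bg[t], n_b) for t in tested]
    )
    fdr = bh_adjust(pvals, "bh")
    out = pd.DataFrame(
        {
            "term_id": tested,
            "name": [dag.names.get(t, t) for t in tested],
            "sample_count": [term_sample[t] for t in tested],
            "sample_total": n_s,
            "background_count": [term_bg[t] for t in tested],
            "background_total": n_b,
            "p_value": pvals,
            "fdr": fdr,
        }
    )
    out["significant"] = out["fdr"] < config.fdr_threshold
    return out.sort_values(["p_value", "term_id"]).reset_index(drop=True)


def read_process_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("term_id", "process"):
        if col not in df.columns:
            raise EnrichmentError(f"process map missing column {col!r}")
    bad = set(df["process"]) - set(PROCESS_ORDER)
    if bad:
        raise EnrichmentError(f"unknown process names: {sorted(bad)}")
    return dict(zip(df["term_id"], df["process"]))


def default_process_map() -> dict[str, str]:
    """Packaged GOSLIM-style mapping of BP terms onto the 9 processes."""
    ref = resources.files("cvgkit.data") / "goslim_process_map.tsv"
    with resources.as_file(ref) as path:
        return read_process_map(path)


def classify_groups(
    groups: list[CVGGroup],
    annotations: Iterable[GeneAnnotation],
    dag: OntologyDag,
    process_map: Mapping[str, str] | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Assign each CVG group a fundamental process and annotation status.

    Status is ``experimental`` when any member carries a BP annotation
    with an experimental evidence code, ``electronic`` when only other
    codes are present, ``none`` otherwise. The process is a majority
    vote over member genes' propagated BP terms mapped through
    ``process_map`` (each gene votes once per process); ties break
    toward the earlier process in the canonical order; groups with no
    mapped term are UNDEFINED.
    """
    config = config or PipelineConfig()
    if process_map is None:
        process_map = default_process_map()
    if not process_map:
        raise EnrichmentError("empty process map")
    annotations = list(annotations)
    bp_direct: dict[str, list[GeneAnnotation]] = {}
    for ann in annotations:
        if ann.term_id in dag and dag.namespaces.get(ann.term_id) == "biological_process":
            bp_direct.setdefault(ann.gene_id, []).append(ann)
    propagated = propagate_annotations(dag, annotations)

    rows = []
    for group in groups:
        genes = sorted(group.all_genes())
        codes = {a.evidence_code for g in genes for a in bp_direct.get(g, ())}
        if codes & config.experimental_codes:
            status = "experimental"
        elif codes:
            status = "electronic"
        else:
            status = "none"
        votes: dict[str, int] = {}
        for g in genes:
            gene_processes = {
                process_map[t]
                for t in propagated.get(g, ())
                if t in process_map
                and dag.namespaces.get(t) == "biological_process"
            }
            for p in gene_processes:
                votes[p] = votes.get(p, 0) + 1
        if votes:
            process = min(
                votes, key=lambda p: (-votes[p], PROCESS_ORDER.index(p))
            )
        else:
            process = UNDEFINED
        rows.append(
            {
                "group_id": group.group_id,
                "process": process,
                "annotation_status": status,
            }
        )
    return pd.DataFrame(rows, columns=["group_id", "process", "annotation_status"])


def classification_summary(assignments: pd.DataFrame) -> dict:
    """Counts per process and the rounded percentage of UNDEFINED groups."""
    total = len(assignments)
    counts = assignments["process"].value_counts().to_dict()
    n_undef = int(counts.get(UNDEFINED, 0))
    status = assignments["annotation_status"].value_counts().to_dict()
    return {
        "n_groups": total,
        "process_counts": {k: int(v) for k, v in sorted(counts.items())},
        "annotation_status_counts": {k: int(v) for k, v in sorted(status.items())},
        "n_undefined": n_undef,
        "undefined_percent": round(100.0 * n_undef / total) if total else 0,
    }
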