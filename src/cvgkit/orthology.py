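"""Conserved vascular gene (CVG) identification and cross-species grouping.

Homology evidence arrives as BLAST tabular (outfmt 6) hit tables. A
vascular gene is a CVG when the undirected hit graph — restricted to
vascular genes on both endpoints and to hits at E-value <= cutoff
(boundary included) — links it to at least one gene in *every* other
species. CVG groups are the connected components of that graph that
span all species; components missing a species are reported separately
as incomplete.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


class HomologyError(ValueError):
    pass


class HomologyHit(NamedTuple):
    query_species: str
    query_gene: str
    subject_species: str
    subject_gene: str
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class CVGGroup:
    group_id: int
    members: dict[str, tuple[str, ...]]  # species -> sorted gene ids

    @property
    def species_count(self) -> int:
        return sum(1 for g in self.members.values() if g)

    @property
    def size(self) -> int:
        return sum(len(g) for g in self.members.values())

    def all_genes(self) -> frozenset[str]:
        return frozenset(g for genes in self.members.values() for g in genes)


def read_species_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "species_id"):
        if col not in df.columns:
            raise HomologyError(f"species map missing column {col!r}")
    return dict(zip(df["gene_id"], df["species_id"]))


def load_hits(
    path: str | Path,
    cutoff: float,
    species_map: Mapping[str, str],
) -> list[HomologyHit]:
    """Parse a 12-column BLAST outfmt-6 table and filter by E-value.

    Hits at exactly the cutoff are retained (``<=``). Within-species
    hits and self hits are discarded; duplicate ordered pairs collapse
    to the best (lowest) E-value; genes missing from the species map
    are dropped with a warning.
    """
    best: dict[tuple[str, str], HomologyHit] = {}
    n_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise HomologyError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            q, s = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise HomologyError(f"{path}:{lineno}: {exc}") from exc
            if evalue < 0:
                raise HomologyError(f"{path}:{lineno}: negative E-value")
            if q not in species_map or s not in species_map:
                n_unknown += 1
                continue
            qs, ss = species_map[q], species_map[s]
            if qs == ss:
                continue
            if evalue > cutoff:
                continue
            key = (q, s)
            hit = HomologyHit(qs, q, ss, s, evalue, bitscore)
            if key not in best or evalue < best[key].evalue:
                best[key] = hit
    if n_unknown:
        logger.warning("load_hits: dropped %d hits with unknown gene ids", n_unknown)
    return list(best.values())


def _hit_graph(
    hits: Iterable[HomologyHit],
    allowed: set[str] | None = None,
    require_reciprocal: bool = False,
) -> nx.Graph:
    """Undirected cross-species graph from directed hits.

    Union of directions by default; intersection (both directions
    present) when ``require_reciprocal``.
    """
    directed: set[tuple[str, str]] = set()
    species: dict[str, str] = {}
    for h in hits:
        if allowed is not None and (
            h.query_gene not in allowed or h.subject_gene not in allowed
        ):
            continue
        directed.add((h.query_gene, h.subject_gene))
        species[h.query_gene] = h.query_species
        species[h.subject_gene] = h.subject_species
    g = nx.Graph()
    for a, b in directed:
        if require_reciprocal and (b, a) not in directed:
            continue
        g.add_edge(a, b)
    nx.set_node_attributes(g, species, "species")
    return g


def identify_cvgs(
    vascular_sets: Mapping[str, set[str]],
    hits: Iterable[HomologyHit],
    require_reciprocal: bool = False,
) -> dict[str, set[str]]:
    """Per-species CVG sets: vascular genes with a vascular homolog in
    every other species.

    Only edges whose two endpoints are both in their species' vascular
    set count as ortholog evidence.
    """
    if len(vascular_sets) < 3:
        raise HomologyError("CVG identification needs >= 3 species")
    for sp, genes in vascular_sets.items():
        if not genes:
            logger.warning("identify_cvgs: species %s has no vascular genes", sp)
    allowed = set().union(*vascular_sets.values())
    graph = _hit_graph(hits, allowed=allowed, require_reciprocal=require_reciprocal)
    species_of = {
        g: sp for sp, genes in vascular_sets.items() for g in genes
    }
    all_species = set(vascular_sets)
    cvgs: dict[str, set[str]] = {sp: set() for sp in all_species}
    for gene, sp in species_of.items():
        if gene not in graph:
            continue
        neighbor_species = {
            species_of[n] for n in graph.neighbors(gene) if n in species_of
        }
        if all_species - {sp} <= neighbor_species:
            cvgs[sp].add(gene)
    return cvgs


def build_groups(
    cvgs: Mapping[str, set[str]],
    hits: Iterable[HomologyHit],
    require_reciprocal: bool = False,
) -> tuple[list[CVGGroup], list[CVGGroup]]:
    """Connected components of the hit graph induced on CVG nodes.

    Returns (groups, incomplete): components spanning every species are
    CVG groups, numbered 1..k by decreasing size then lexicographic
    smallest member; components lacking a species are incomplete.
    """
    allowed = set().union(*cvgs.values()) if cvgs else set()
    species_of = {g: sp for sp, genes in cvgs.items() for g in genes}
    graph = _hit_graph(hits, allowed=allowed, require_reciprocal=require_reciprocal)
    graph.add_nodes_from(allowed)  # isolated CVGs still form components
    all_species = set(cvgs)

    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    groups: list[CVGGroup] = []
    incomplete: list[CVGGroup] = []
    for comp in components:
        members: dict[str, list[str]] = {sp: [] for sp in sorted(all_species)}
        for g in comp:
            members[species_of[g]].append(g)
        record = CVGGroup(
            group_id=0,
            members={sp: tuple(sorted(gs)) for sp, gs in members.items()},
        )
        if all(record.members[sp] for sp in all_species):
            groups.append(record)
        else:
            incomplete.append(record)
    groups = [
        CVGGroup(group_id=i + 1, members=g.members) for i, g in enumerate(groups)
    ]
    incomplete = [
        CVGGroup(group_id=-(i + 1), members=g.members)
        for i, g in enumerate(incomplete)
    ]
    if incomplete:
        logger.info(
            "build_groups: %d components lack a species and are not groups",
            len(incomplete),
        )
    return groups, incomplete


def group_summary(groups: list[CVGGroup]) -> dict:
    """Per-species CVG counts, group count and group-size distribution."""
    species: set[str] = set()
    for g in groups:
        species |= set(g.members)
    per_species = {
        sp: sum(len(g.members.get(sp, ())) for g in groups)
        for sp in sorted(species)
    }
    sizes = sorted((g.size for g in groups), reverse=True)
    dist: dict[str, int] = {}
    for s in sizes:
        dist[str(s)] = dist.get(str(s), 0) + 1
    return {
        "n_groups": len(groups),
        "cvg_counts": per_species,
        "group_size_distribution": dist,
    }


def write_groups(
    groups: list[CVGGroup], path: str | Path, summary_path: str | Path | None = None
) -> None:
    rows = [
        {"group_id": g.group_id, "species_id": sp, "gene_id": gene}
        for g in groups
        for sp in sorted(g.members)
        for gene in g.members[sp]
    ]
    pd.DataFrame(rows, columns=["group_id", "species_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump(group_summary(groups), fh, indent=2, sort_keys=True)
            fh.write("\n")
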