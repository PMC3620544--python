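"""Synthetic three-species datasets with planted structure.

Generates everything the pipeline consumes — multi-tissue replicate
expression matrices with stem-elevated planted genes, cross-species
homology hit tables with decoys, a shallow GO DAG with planted
enrichment, and a term->process map — together with the ground truth,
so every stage can be scored without external downloads.

The expression model is additive Gaussian on the log2 scale (RMA-like):
value = gene baseline + per-gene tissue effect + stem shift (planted
vascular genes, focal tissue only) + module tissue profile + noise.
Planted orthology is 1:1:1 per group; true cross-species hits sit well
below the E-value cutoff and decoys sit above it unless the sub-cutoff
stress mode is on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .expression import ExpressionMatrix, SampleSheet
from .orthology import CVGGroup, HomologyHit
from .enrichment import PROCESS_ORDER

logger = logging.getLogger(__name__)

SPECIES_DEFAULT = ("ath", "ptr", "osa")
TISSUE_POOL = (
    "stem", "leaf", "root", "seedling", "shoot_apex", "seed", "flower",
    "silique", "panicle", "catkin", "petiole", "internode",
)

EVIDENCE_CODES = ("IDA", "IMP", "ISS", "IEA")
EVIDENCE_PROBS = (0.15, 0.10, 0.20, 0.55)


@dataclass
class SimulationParams:
    """Study-condition knobs for the generator.

    Defaults mirror the analysed design: three species, eight tissues
    with the stem focal, triplicate arrays, a 2 log2-unit stem shift on
    planted vascular genes over noise sigma 0.5, fifty 1:1:1 conserved
    groups plus species-specific vascular genes without orthologs, and
    decoy homology hits at 5% of the true-hit count.
    """

    n_species: int = 3
    genes_per_species: int = 2000
    tissues_per_species: int = 8
    replicates_per_tissue: int = 3
    n_planted_groups: int = 50
    n_nonconserved_vascular: int = 200
    stem_shift_log2: float = 2.0
    noise_sd_log2: float = 0.5
    baseline_mean_log2: float = 7.0
    baseline_sd_log2: float = 1.5
    tissue_effect_sd_log2: float = 0.05
    decoy_hit_rate: float = 0.05
    decoy_below_cutoff: bool = False
    adversarial: bool = False
    evalue_cutoff: float = 1e-50
    n_coexpr_modules: int = 5
    module_profile_sd_log2: float = 0.1
    module_noise_sd: float = 0.3
    n_go_terms: int = 200
    enriched_term_count: int = 5
    annotations_per_gene: float = 8.0
    enrichment_relative_risk: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_species", "genes_per_species", "tissues_per_species",
            "replicates_per_tissue", "n_go_terms",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.decoy_hit_rate <= 1.0):
            raise ValueError("decoy_hit_rate must be in [0,1]")
        if self.enriched_term_count > self.n_go_terms:
            raise ValueError("enriched_term_count exceeds n_go_terms")
        if self.tissues_per_species > len(TISSUE_POOL):
            raise ValueError("too many tissues requested")
        need = self.n_planted_groups + self.n_nonconserved_vascular
        if need > self.genes_per_species:
            raise ValueError("planted genes exceed genes_per_species")

    @property
    def species(self) -> tuple[str, ...]:
        if self.n_species <= len(SPECIES_DEFAULT):
            return SPECIES_DEFAULT[: self.n_species]
        return tuple(f"sp{i}" for i in range(self.n_species))

    @property
    def tissues(self) -> tuple[str, ...]:
        return TISSUE_POOL[: self.tissues_per_species]

    @property
    def focal_tissue(self) -> str:
        return TISSUE_POOL[0]


@dataclass
class GroundTruth:
    """Planted structure serialized alongside the generated data."""

    planted_vascular: dict[str, set[str]]
    planted_groups: list[dict[str, tuple[str, ...]]]
    planted_modules: dict[str, dict[str, int]]
    planted_enriched_terms: set[str] = field(default_factory=set)

    def group_sets(self) -> list[frozenset[str]]:
        return [
            frozenset(g for genes in grp.values() for g in genes)
            for grp in self.planted_groups
        ]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_vascular": {
                sp: sorted(genes) for sp, genes in self.planted_vascular.items()
            },
            "planted_groups": [
                {sp: list(genes) for sp, genes in grp.items()}
                for grp in self.planted_groups
            ],
            "planted_modules": self.planted_modules,
            "planted_enriched_terms": sorted(self.planted_enriched_terms),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_vascular={
                sp: set(g) for sp, g in d["planted_vascular"].items()
            },
            planted_groups=[
                {sp: tuple(g) for sp, g in grp.items()}
                for grp in d["planted_groups"]
            ],
            planted_modules={
                sp: {g: int(m) for g, m in mods.items()}
                for sp, mods in d["planted_modules"].items()
            },
            planted_enriched_terms=set(d["planted_enriched_terms"]),
        )


def _gene_ids(species: str, n: int) -> list[str]:
    return [f"{species}_g{i:04d}" for i in range(n)]


def make_truth(params: SimulationParams, rng: np.random.Generator) -> GroundTruth:
    """Plant vascular genes, 1:1:1 ortholog groups and modules."""
    vascular: dict[str, set[str]] = {}
    groups: list[dict[str, tuple[str, ...]]] = []
    modules: dict[str, dict[str, int]] = {}
    for sp in params.species:
        ids = _gene_ids(sp, params.genes_per_species)
        group_members = ids[: params.n_planted_groups]
        extras = ids[
            params.n_planted_groups
            : params.n_planted_groups + params.n_nonconserved_vascular
        ]
        vascular[sp] = set(group_members) | set(extras)
        mods = {}
        if params.n_coexpr_modules > 0:
            for i, g in enumerate(group_members):
                mods[g] = i % params.n_coexpr_modules
        modules[sp] = mods
    for i in range(params.n_planted_groups):
        groups.append(
            {sp: (f"{sp}_g{i:04d}",) for sp in params.species}
        )
    return GroundTruth(
        planted_vascular=vascular,
        planted_groups=groups,
        planted_modules=modules,
    )


def simulate_expression(
    params: SimulationParams,
    truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, ExpressionMatrix], SampleSheet, GroundTruth]:
    """Per-species log2 expression matrices plus the joint sample sheet."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if truth is None:
        truth = make_truth(params, rng)
    tissues = params.tissues
    focal = params.focal_tissue
    n_rep = params.replicates_per_tissue

    matrices: dict[str, ExpressionMatrix] = {}
    sheet_rows = []
    for sp in params.species:
        genes = _gene_ids(sp, params.genes_per_species)
        samples = [
            f"{sp}_{t}_r{k + 1}" for t in tissues for k in range(n_rep)
        ]
        for t in tissues:
            for k in range(n_rep):
                sheet_rows.append(
                    {
                        "sample_id": f"{sp}_{t}_r{k + 1}",
                        "species_id": sp,
                        "tissue_id": t,
                    }
                )
        n_g, n_t = len(genes), len(tissues)
        baseline = rng.normal(
            params.baseline_mean_log2, params.baseline_sd_log2, n_g
        )
        tissue_eff = rng.normal(0.0, params.tissue_effect_sd_log2, (n_g, n_t))
        module_profile = rng.normal(
            0.0, params.module_profile_sd_log2,
            (max(params.n_coexpr_modules, 1), n_t),
        )
        mean = baseline[:, None] + tissue_eff
        vasc_idx = np.array(
            [g in truth.planted_vascular[sp] for g in genes], dtype=bool
        )
        focal_col = tissues.index(focal)
        mean[vasc_idx, focal_col] += params.stem_shift_log2
        mods = truth.planted_modules.get(sp, {})
        for gi, g in enumerate(genes):
            if g in mods:
                mean[gi] += module_profile[mods[g]]
        noise = rng.normal(
            0.0, params.noise_sd_log2, (n_g, n_t * n_rep)
        )
        values = np.repeat(mean, n_rep, axis=1) + noise
        matrices[sp] = ExpressionMatrix(
            species_id=sp,
            data=pd.DataFrame(values, index=genes, columns=samples),
        )
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    return matrices, sheet, truth


def simulate_module_matrix(
    n_modules: int = 5,
    genes_per_module: int = 40,
    n_samples: int = 30,
    loading: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Latent-factor coexpression data: gene = loading * module factor
    + noise.

    Module size defaults to 40 — above the default HRR cutoff of 30 —
    so connected components of the HRR graph are interpretable as
    modules.
    """
    rng = np.random.default_rng(seed)
    genes = [f"mod_g{i:04d}" for i in range(n_modules * genes_per_module)]
    labels = {g: i // genes_per_module for i, g in enumerate(genes)}
    factors = rng.normal(0.0, 1.0, (n_modules, n_samples))
    noise = rng.normal(0.0, noise_sd, (len(genes), n_samples))
    values = np.vstack(
        [loading * factors[labels[g]] for g in genes]
    ) + noise + 7.0
    samples = [f"s{j:03d}" for j in range(n_samples)]
    matrix = ExpressionMatrix(
        species_id="sim",
        data=pd.DataFrame(values, index=genes, columns=samples),
    )
    return matrix, labels


def _format_hit(q: str, s: str, evalue: float, rng: np.random.Generator) -> str:
    pident = 60.0 + 40.0 * rng.random()
    length = int(rng.integers(150, 600))
    mismatch = int(length * (1.0 - pident / 100.0))
    bitscore = max(50.0, -10.0 * np.log10(max(evalue, 1e-180)) + rng.normal(0, 5))
    return "\t".join(
        [
            q, s, f"{pident:.2f}", str(length), str(mismatch), "0",
            "1", str(length), "1", str(length),
            f"{evalue:.6g}", f"{bitscore:.1f}",
        ]
    )


def simulate_homology(
    params: SimulationParams,
    truth: GroundTruth,
    path: str | Path,
    rng: np.random.Generator | None = None,
) -> Path:
    """Write a BLAST outfmt-6 table: planted within-group cross-species
    hits below the E-value cutoff plus decoy hits.

    True hits get log10(E) ~ U(-180, -55), both directions. Decoys are
    uniform cross-species vascular pairs at ``decoy_hit_rate`` times
    the true-pair count, with log10(E) ~ U(-49, -5) (filtered out by
    the cutoff) or U(-180, -55) in the sub-cutoff stress mode. The
    adversarial flag plants one extra hit at exactly the cutoff.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    path = Path(path)
    lines: list[str] = []
    true_pairs: set[tuple[str, str]] = set()
    species = list(params.species)
    for grp in truth.planted_groups:
        for i, sp_a in enumerate(species):
            for sp_b in species[i + 1:]:
                for ga in grp.get(sp_a, ()):
                    for gb in grp.get(sp_b, ()):
                        ev = 10.0 ** rng.uniform(-180.0, -55.0)
                        lines.append(_format_hit(ga, gb, ev, rng))
                        lines.append(_format_hit(gb, ga, ev, rng))
                        true_pairs.add((ga, gb))

    n_decoys = int(round(params.decoy_hit_rate * len(true_pairs)))
    vascular = {
        sp: sorted(truth.planted_vascular[sp]) for sp in species
    }
    made = 0
    attempts = 0
    while made < n_decoys and attempts < 100 * max(n_decoys, 1):
        attempts += 1
        sp_a, sp_b = rng.choice(len(species), size=2, replace=False)
        sp_a, sp_b = species[sp_a], species[sp_b]
        ga = vascular[sp_a][int(rng.integers(len(vascular[sp_a])))]
        gb = vascular[sp_b][int(rng.integers(len(vascular[sp_b])))]
        key = (ga, gb) if ga < gb else (gb, ga)
        if key in true_pairs:
            continue
        true_pairs.add(key)  # avoid duplicate decoys too
        if params.decoy_below_cutoff:
            ev = 10.0 ** rng.uniform(-180.0, -55.0)
        else:
            ev = 10.0 ** rng.uniform(-49.0, -5.0)
        if params.adversarial and made == 0:
            ev = params.evalue_cutoff
        lines.append(_format_hit(ga, gb, ev, rng))
        made += 1

    with open(path, "w") as fh:
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")
    return path


def write_species_map(params: SimulationParams, path: str | Path) -> Path:
    rows = [
        {"gene_id": g, "species_id": sp}
        for sp in params.species
        for g in _gene_ids(sp, params.genes_per_species)
    ]
    pd.DataFrame(rows, columns=["gene_id", "species_id"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def simulate_annotations(
    params: SimulationParams,
    truth: GroundTruth,
    obo_path: str | Path,
    annot_path: str | Path,
    process_map_path: str | Path | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Path, Path]:
    """Write a shallow synthetic GO DAG (OBO 1.2) plus annotations.

    The DAG has one BP root, ten mid-level terms and ``n_go_terms``
    leaves with 1-2 mid-level parents (one of them via part_of now and
    then). Background genes draw ~``annotations_per_gene`` leaf terms
    uniformly; the planted-enriched leaves annotate planted vascular
    genes at ``enrichment_relative_risk`` times the base rate. Nine of
    the mid-level terms map onto the nine fundamental processes
    (written to ``process_map_path``), the tenth stays unmapped so
    poorly annotated groups land in UNDEFINED.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed + 2)
    root = "GO:1000000"
    n_mid = 10
    mids = [f"GO:10000{i + 1:02d}" for i in range(n_mid)]
    leaves = [f"GO:2{i + 1:06d}" for i in range(params.n_go_terms)]

    stanzas = [
        "format-version: 1.2",
        "ontology: synthetic-go",
        "",
        "[Term]",
        f"id: {root}",
        "name: biological_process root",
        "namespace: biological_process",
    ]
    for m in mids:
        stanzas += [
            "",
            "[Term]",
            f"id: {m}",
            f"name: process {m}",
            "namespace: biological_process",
            f"is_a: {root} ! root",
        ]
    leaf_parents: dict[str, list[str]] = {}
    for i, leaf in enumerate(leaves):
        k = 1 + int(rng.random() < 0.3)
        parents = [mids[j] for j in rng.choice(n_mid, size=k, replace=False)]
        leaf_parents[leaf] = parents
        stanzas += [
            "",
            "[Term]",
            f"id: {leaf}",
            f"name: leaf process {i + 1}",
            "namespace: biological_process",
            f"is_a: {parents[0]} ! parent",
        ]
        if len(parents) > 1:
            stanzas.append(f"relationship: part_of {parents[1]} ! parent")
    obo_path = Path(obo_path)
    with open(obo_path, "w") as fh:
        fh.write("\n".join(stanzas) + "\n")

    enriched = leaves[: params.enriched_term_count]
    truth.planted_enriched_terms = set(enriched)

    base_p = params.annotations_per_gene / params.n_go_terms
    boost_p = min(1.0, params.enrichment_relative_risk * base_p)
    rows = []
    for sp in params.species:
        genes = _gene_ids(sp, params.genes_per_species)
        planted = truth.planted_vascular[sp]
        planted_mask = np.array([g in planted for g in genes])
        enriched_mask = np.array(
            [t in truth.planted_enriched_terms for t in leaves]
        )
        p_matrix = np.full((len(genes), params.n_go_terms), base_p)
        p_matrix[np.ix_(planted_mask, enriched_mask)] = boost_p
        draw = rng.random((len(genes), params.n_go_terms))
        hit_gi, hit_ti = np.nonzero(draw < p_matrix)
        codes = rng.choice(
            len(EVIDENCE_CODES), size=len(hit_gi), p=EVIDENCE_PROBS
        )
        for gi, ti, ci in zip(hit_gi, hit_ti, codes):
            rows.append(
                {
                    "gene_id": genes[gi],
                    "term_id": leaves[ti],
                    "evidence_code": EVIDENCE_CODES[ci],
                }
            )
    annot_path = Path(annot_path)
    pd.DataFrame(rows, columns=["gene_id", "term_id", "evidence_code"]).to_csv(
        annot_path, sep="\t", index=False
    )

    if process_map_path is not None:
        pm = pd.DataFrame(
            {
                "term_id": mids[: len(PROCESS_ORDER)],
                "process": list(PROCESS_ORDER),
            }
        )
        pm.to_csv(process_map_path, sep="\t", index=False)
    return obo_path, annot_path


def simulate_all(
    params: SimulationParams, outdir: str | Path
) -> dict[str, object]:
    """Generate the complete dataset into ``outdir`` and return paths
    plus in-memory objects (matrices, sheet, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    matrices, sheet, truth = simulate_expression(params, rng=rng)
    paths: dict[str, object] = {}
    for sp, m in matrices.items():
        p = outdir / f"expression_{sp}.tsv"
        m.write(p)
        paths[f"expression_{sp}"] = p
    sheet.write(outdir / "sample_sheet.tsv")
    paths["sample_sheet"] = outdir / "sample_sheet.tsv"
    paths["hits"] = simulate_homology(
        params, truth, outdir / "homology_hits.tsv", rng=rng
    )
    paths["species_map"] = write_species_map(params, outdir / "species_map.tsv")
    obo, annot = simulate_annotations(
        params,
        truth,
        outdir / "ontology.obo",
        outdir / "annotations.tsv",
        outdir / "process_map.tsv",
        rng=rng,
    )
    paths["ontology"] = obo
    paths["annotations"] = annot
    paths["process_map"] = outdir / "process_map.tsv"
    truth.to_json(outdir / "truth.json")
    paths["truth"] = outdir / "truth.json"
    paths["matrices"] = matrices
    paths["sheet"] = sheet
    paths["truth_obj"] = truth
    return paths


# ---------------------------------------------------------------------------
# scoring


def _match_f1(
    predicted: list[frozenset[str]], planted: list[frozenset[str]]
) -> dict[str, float]:
    """Group-level precision/recall/F1 with Jaccard >= 0.5 matching.

    Empty prediction sets score precision 1.0 by convention (no false
    positives) and recall 0.
    """

    def jaccard(a: frozenset[str], b: frozenset[str]) -> float:
        return len(a & b) / len(a | b) if (a or b) else 1.0

    matched_pred = sum(
        1 for p in predicted if any(jaccard(p, q) >= 0.5 for q in planted)
    )
    matched_true = sum(
        1 for q in planted if any(jaccard(p, q) >= 0.5 for p in predicted)
    )
    precision = matched_pred / len(predicted) if predicted else 1.0
    recall = matched_true / len(planted) if planted else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1}


def score_recovery(
    predicted_groups: list[CVGGroup],
    truth: GroundTruth,
    vascular_calls: Mapping[str, set[str]] | None = None,
    module_labels_pred: Mapping[str, int] | None = None,
    module_labels_true: Mapping[str, int] | None = None,
) -> dict[str, float]:
    """Score predictions against the planted truth.

    Group-level precision/recall/F1 (Jaccard >= 0.5), optional pooled
    gene-level precision/recall of vascular calls, optional adjusted
    Rand index of module labels over their common genes.
    """
    scores: dict[str, float] = {}
    pred_sets = [g.all_genes() for g in predicted_groups]
    scores.update(
        {f"group_{k}": v for k, v in _match_f1(pred_sets, truth.group_sets()).items()}
    )
    if vascular_calls is not None:
        tp = fp = fn = 0
        for sp, planted in truth.planted_vascular.items():
            called = set(vascular_calls.get(sp, set()))
            tp += len(called & planted)
            fp += len(called - planted)
            fn += len(planted - called)
        scores["vascular_precision"] = tp / (tp + fp) if (tp + fp) else 1.0
        scores["vascular_recall"] = tp / (tp + fn) if (tp + fn) else 1.0
    if module_labels_pred is not None and module_labels_true is not None:
        common = sorted(set(module_labels_pred) & set(module_labels_true))
        if common:
            scores["module_ari"] = float(
                adjusted_rand_score(
                    [module_labels_true[g] for g in common],
                    [module_labels_pred[g] for g in common],
                )
            )
        else:
            scores["module_ari"] = 0.0
    return scores


def null_enrichment_pvalues(
    n_reps: int = 200,
    n_genes: int = 4000,
    n_terms: int = 25,
    annot_prob: float = 0.5,
    sample_size: int = 400,
    seed: int = 0,
) -> np.ndarray:
    """Hypergeometric p-values under a null where annotations are
    independent of sample membership.

    Margins default large so the discrete test's achievable levels are
    dense and the p < 0.05 rate can sit near nominal.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    pvals = np.empty(n_reps * n_terms)
    for r in range(n_reps):
        annotated = rng.random((n_terms, n_genes)) < annot_prob
        sample = rng.choice(n_genes, size=sample_size, replace=False)
        k = annotated[:, sample].sum(axis=1)
        big_k = annotated.sum(axis=1)
        pvals[r * n_terms : (r + 1) * n_terms] = stats.hypergeom.sf(
            k - 1, n_genes, big_k, sample_size
        )
    return pvals
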