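"""Expression matrix I/O, probe collapsing, tissue profiles and heatmap
standardization.

Input matrices are log2-scale (post-normalization) genes x samples TSVs;
a ``linear`` input scale triggers a floored log2 transform. Missing
values are rejected outright — there is no imputation policy here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel gene id for probes that cannot be uniquely assigned.
AMBIGUOUS = "AMBIGUOUS"


class ExpressionError(ValueError):
    """Malformed or inconsistent expression input."""


@dataclass
class SampleSheet:
    """Sample metadata: one row per sample with its species and tissue."""

    frame: pd.DataFrame  # columns: sample_id, species_id, tissue_id

    REQUIRED = ("sample_id", "species_id", "tissue_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ExpressionError(f"sample sheet missing columns: {missing}")
        dup = self.frame["sample_id"][self.frame["sample_id"].duplicated()]
        if len(dup):
            raise ExpressionError(f"duplicate sample ids: {sorted(set(dup))}")
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def species(self) -> list[str]:
        return sorted(self.frame["species_id"].unique())

    def samples_for(self, species_id: str) -> pd.DataFrame:
        return self.frame[self.frame["species_id"] == species_id]

    def tissue_of(self, species_id: str | None = None) -> dict[str, str]:
        sub = self.frame if species_id is None else self.samples_for(species_id)
        return dict(zip(sub["sample_id"], sub["tissue_id"]))

    def tissues(self, species_id: str) -> list[str]:
        return sorted(self.samples_for(species_id)["tissue_id"].unique())


@dataclass
class ExpressionMatrix:
    """Log2 expression values for one species, genes x samples."""

    species_id: str
    data: pd.DataFrame  # index: gene_id, columns: sample_id

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = sorted(set(self.data.index[self.data.index.duplicated()]))
            raise ExpressionError(f"duplicate gene ids: {dups}")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ExpressionError("expression matrix contains non-finite values")
        self.data.index.name = "gene_id"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def write(self, path: str | Path, precision: int | None = None) -> None:
        """Write as TSV; default full-repr floats so a re-read is exact."""
        fmt = None if precision is None else f"%.{precision}g"
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format=fmt)


@dataclass
class TissueProfile:
    """Per-gene, per-tissue summary of one species' expression.

    ``means``/``variances`` are genes x tissues frames; variances are
    unbiased (n-1) and reported as 0 for single-replicate tissues,
    whose names are kept in ``single_replicate_tissues``.
    """

    species_id: str
    means: pd.DataFrame
    variances: pd.DataFrame
    n_replicates: pd.Series  # tissue -> sample count
    single_replicate_tissues: frozenset[str] = field(default_factory=frozenset)

    @property
    def tissues(self) -> list[str]:
        return list(self.means.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.means.index)


def read_expression(
    matrix_path: str | Path,
    sheet: str | Path | SampleSheet,
    input_scale: str = "log2",
    epsilon: float = 1e-6,
) -> ExpressionMatrix:
    """Read a genes x samples TSV, validate it against the sample sheet.

    The first column is ``gene_id``; remaining column names are sample
    ids that must all belong to a single species in the sheet.
    ``input_scale='linear'`` applies log2 with values floored at
    ``epsilon``.
    """
    if not isinstance(sheet, SampleSheet):
        sheet = SampleSheet.read(sheet)
    raw = pd.read_csv(matrix_path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise ExpressionError(f"{matrix_path}: expected gene_id + sample columns")
    raw = raw.set_index(raw.columns[0])
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | ~np.isfinite(converted)
        if bad.any():
            gene = raw.index[bad.to_numpy()][0]
            raise ExpressionError(
                f"{matrix_path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
        values[col] = converted.to_numpy()

    species_of = dict(zip(sheet.frame["sample_id"], sheet.frame["species_id"]))
    unknown = [s for s in values.columns if s not in species_of]
    if unknown:
        raise ExpressionError(f"samples absent from sheet: {unknown}")
    species = {species_of[s] for s in values.columns}
    if len(species) != 1:
        raise ExpressionError(
            f"matrix mixes samples from several species: {sorted(species)}"
        )

    if input_scale == "linear":
        values = np.log2(values.clip(lower=epsilon))
    elif input_scale != "log2":
        raise ExpressionError(f"unknown input_scale {input_scale!r}")
    return ExpressionMatrix(species_id=species.pop(), data=values)


def read_probe_map(path: str | Path) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "gene_id"):
        if col not in pm.columns:
            raise ExpressionError(f"probe map missing column {col!r}")
    return pm


def collapse_probes(
    matrix: ExpressionMatrix, probe_map: pd.DataFrame
) -> ExpressionMatrix:
    """Re-key probe rows to gene loci, keeping only unique assignments.

    A probe mapped to >1 gene (or flagged ``AMBIGUOUS``) is dropped, and
    a gene targeted by >1 probe is excluded entirely, so the result
    contains only genes measured by a unique probe. Probes missing from
    the map are dropped with a warning.
    """
    per_probe = probe_map.groupby("probe_id")["gene_id"].agg(set)
    assignment: dict[str, str] = {}
    for probe, genes in per_probe.items():
        genes = set(genes) - {AMBIGUOUS}
        if len(genes) == 1:
            assignment[probe] = next(iter(genes))

    present = [p for p in matrix.data.index if p in assignment]
    missing = matrix.shape[0] - len(present)
    n_ambiguous = sum(
        1 for p in matrix.data.index if p in per_probe.index and p not in assignment
    )
    if missing:
        logger.warning(
            "collapse_probes: dropped %d probes (%d ambiguous, %d absent from map)",
            missing, n_ambiguous, missing - n_ambiguous,
        )

    sub = matrix.data.loc[present]
    genes = pd.Series([assignment[p] for p in present], index=sub.index)
    counts = genes.value_counts()
    multi = set(counts[counts > 1].index)
    if multi:
        logger.warning(
            "collapse_probes: excluded %d genes measured by >1 probe", len(multi)
        )
    keep = [p for p in present if assignment[p] not in multi]
    out = matrix.data.loc[keep].copy()
    out.index = pd.Index([assignment[p] for p in keep], name="gene_id")
    out = out.sort_index()
    return ExpressionMatrix(species_id=matrix.species_id, data=out)


def tissue_profile(matrix: ExpressionMatrix, sheet: SampleSheet) -> TissueProfile:
    """Per-gene, per-tissue sample mean and unbiased variance."""
    tissue_of = sheet.tissue_of(matrix.species_id)
    missing = [s for s in matrix.sample_ids if s not in tissue_of]
    if missing:
        raise ExpressionError(f"samples absent from sheet: {missing}")
    groups: dict[str, list[str]] = {}
    for s in matrix.sample_ids:
        groups.setdefault(tissue_of[s], []).append(s)
    declared = set(sheet.samples_for(matrix.species_id)["tissue_id"])
    empty = declared - set(groups)
    if empty:
        raise ExpressionError(
            f"tissues with zero samples in matrix: {sorted(empty)}"
        )

    tissues = sorted(groups)
    means = pd.DataFrame(index=matrix.data.index, columns=tissues, dtype=float)
    variances = pd.DataFrame(index=matrix.data.index, columns=tissues, dtype=float)
    n_reps = pd.Series({t: len(groups[t]) for t in tissues}, dtype=int)
    for t in tissues:
        block = matrix.data[groups[t]].to_numpy()
        means[t] = block.mean(axis=1)
        variances[t] = (
            block.var(axis=1, ddof=1) if block.shape[1] > 1 else 0.0
        )
    singles = frozenset(t for t in tissues if n_reps[t] == 1)
    if singles:
        logger.warning(
            "tissue_profile: single-replicate tissues %s contribute means only",
            sorted(singles),
        )
    means.index.name = variances.index.name = "gene_id"
    return TissueProfile(
        species_id=matrix.species_id,
        means=means,
        variances=variances,
        n_replicates=n_reps,
        single_replicate_tissues=singles,
    )


def standardize_for_heatmap(profile: TissueProfile) -> pd.DataFrame:
    """Per-gene z-score of tissue means: (x - mean) / sample sd.

    Genes constant across tissues map to an all-zero row. This is the
    standardized matrix behind the cross-tissue expression heatmaps.
    """
    if len(profile.tissues) < 2:
        raise ExpressionError("standardization requires >= 2 tissues")
    m = profile.means.to_numpy()
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (m - mu) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    z[~np.isfinite(z)] = 0.0
    return pd.DataFrame(z, index=profile.means.index, columns=profile.tissues)
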