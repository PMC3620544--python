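"""Stem-preferential ("vascular associated") gene calling.

A gene is called vascular when it passes two gates simultaneously:

1. Its focal-tissue (stem) mean is significantly higher than the mean
   of *every* other tissue — one-sided moderated-t contrasts, p-values
   adjusted across genes within each contrast, all adjusted p < alpha.
2. Its linear-scale stem expression is at least ``fold_threshold``
   times the geometric mean of all tissue means.

The moderated t shrinks each gene's variance toward an empirical-Bayes
prior (d0, s0^2) estimated by the method of moments on log sample
variances: if s_g^2 ~ s_g,true^2 * chi^2_dg / dg and the true variances
follow a scaled inverse-chi-square prior with d0 df and scale s0^2,
then log s_g^2 has moments expressible via digamma/trigamma functions;
d0 is recovered by Newton inversion of the trigamma function. The
posterior variance (d0*s0^2 + dg*sg^2)/(d0+dg) gives a t statistic with
d0+dg degrees of freedom (a normal tail when d0 is infinite).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .expression import TissueProfile

logger = logging.getLogger(__name__)


class CallingError(ValueError):
    pass


@dataclass(frozen=True)
class VariancePrior:
    """Empirical-Bayes variance prior: d0 (df, may be inf) and s0^2."""

    d0: float
    s0_sq: float

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.d0)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_variance_prior(
    residual_variances: np.ndarray,
    residual_df: np.ndarray,
    d0_max: float = 1e6,
) -> VariancePrior:
    """Method-of-moments fit of (d0, s0^2) from gene-wise variances.

    Works on log variances: e_g = log s_g^2 - digamma(dg/2) + log(dg/2)
    is an unbiased estimate of log s0^2 shifted by the prior terms; the
    excess dispersion of e_g over mean(trigamma(dg/2)) identifies
    trigamma(d0/2). Zero dispersion (or less) yields an infinite prior.
    """
    s2 = np.asarray(residual_variances, dtype=float)
    df = np.asarray(residual_df, dtype=float)
    if s2.shape != df.shape:
        raise CallingError("variances and dfs must have equal length")
    ok = (s2 > 0) & (df > 0)
    if not ok.any():
        raise CallingError("all residual variances are zero: degenerate data")
    if ok.sum() < 10:
        raise CallingError(
            f"need >= 10 genes with positive variance, got {int(ok.sum())}"
        )
    s2, df = s2[ok], df[ok]

    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = len(e)
    evar = float(((e - emean) ** 2).sum() / (n - 1))
    evar -= float(special.polygamma(1, df / 2.0).mean())

    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        if d0 > d0_max:
            d0 = math.inf
    else:
        d0 = math.inf

    if math.isinf(d0):
        # d0 = inf: E[s_g^2] = s0^2 exactly, so the arithmetic mean is
        # the unbiased estimate (no digamma correction needed)
        s0_sq = float(s2.mean())
    else:
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def residual_variances(profile: TissueProfile) -> tuple[np.ndarray, float]:
    """One-factor (tissue) model residual variance per gene and its df.

    Pooled within-tissue variance across all tissues; df = sum(n_t - 1).
    """
    n = profile.n_replicates
    df_total = float((n - 1).sum())
    if df_total <= 0:
        raise CallingError("no replicated tissue: residual variance undefined")
    weights = (n - 1).to_numpy(dtype=float)
    v = profile.variances.to_numpy()
    pooled = (v * weights).sum(axis=1) / df_total
    return pooled, df_total


def _contrast_arrays(
    profile: TissueProfile,
    prior: VariancePrior,
    tissue: str,
    focal: str,
    one_sided: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized moderated contrast focal-vs-tissue over all genes."""
    if tissue == focal:
        raise CallingError("contrast tissue equals the focal tissue")
    for t in (focal, tissue):
        if t not in profile.means.columns:
            raise CallingError(f"tissue {t!r} not in profile")
    n1 = int(profile.n_replicates[focal])
    n2 = int(profile.n_replicates[tissue])
    dg = n1 + n2 - 2
    v1 = profile.variances[focal].to_numpy()
    v2 = profile.variances[tissue].to_numpy()
    if dg > 0:
        sg_sq = ((n1 - 1) * v1 + (n2 - 1) * v2) / dg
    else:
        if prior.is_infinite and prior.s0_sq <= 0:
            raise CallingError(
                "both tissues single-replicate and prior degenerate"
            )
        sg_sq = np.zeros_like(v1)

    d0 = prior.d0
    if math.isinf(d0):
        s_tilde_sq = np.full_like(sg_sq, prior.s0_sq)
        df_total = math.inf
    elif d0 == 0 and dg == 0:
        raise CallingError("no residual df and no prior df")
    else:
        s_tilde_sq = (d0 * prior.s0_sq + dg * sg_sq) / (d0 + dg)
        df_total = d0 + dg

    delta = (profile.means[focal] - profile.means[tissue]).to_numpy()
    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
        t = np.where(
            se == 0, np.where(delta == 0, 0.0, np.sign(delta) * np.inf), t
        )
    if math.isinf(df_total):
        p = stats.norm.sf(t)
    else:
        p = stats.t.sf(t, df_total)
    if not one_sided:
        p = np.minimum(2.0 * np.minimum(p, 1.0 - p), 1.0)
    return t, p


def moderated_contrast(
    profile: TissueProfile,
    prior: VariancePrior,
    gene: str,
    tissue: str,
    focal: str = "stem",
    one_sided: bool = True,
) -> tuple[float, float]:
    """Moderated-t contrast (focal minus ``tissue``) for one gene.

    Returns (t, p) with p the upper tail on d0+dg degrees of freedom.
    """
    if gene not in profile.means.index:
        raise CallingError(f"gene {gene!r} not in profile")
    t, p = _contrast_arrays(profile, prior, tissue, focal, one_sided)
    i = profile.means.index.get_loc(gene)
    return float(t[i]), float(p[i])


def geometric_mean_fold(
    profile: TissueProfile,
    gene: str,
    focal: str = "stem",
    include_focal: bool = True,
) -> float:
    """Linear-scale fold of stem over the geometric mean of tissue means.

    On log2 data this is 2**(stem_mean - arithmetic mean of the log2
    tissue means); the focal tissue itself is included by default.
    """
    row = profile.means.loc[gene]
    tissues = list(profile.means.columns)
    if not include_focal:
        tissues = [t for t in tissues if t != focal]
    return float(2.0 ** (row[focal] - row[tissues].mean()))


def bh_adjust(p_values, method: str = "bh") -> np.ndarray:
    """Adjust p-values across genes: BH step-up (default), Bonferroni
    or passthrough."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise CallingError("p-values outside [0, 1]")
    if p.size == 0 or method == "none":
        return p.copy()
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    raise CallingError(f"unknown adjustment method {method!r}")


def call_vascular_genes(
    profile: TissueProfile, config: PipelineConfig
) -> pd.DataFrame:
    """Apply the dual vascular criterion to every gene of one species.

    Returns a frame indexed by gene with the stem mean, the fold over
    the geometric mean, per-tissue adjusted p-values (``adjp_<tissue>``),
    the worst adjusted p, and the gate flags. ``is_vascular`` is true
    iff every contrast's adjusted p < alpha AND fold >= fold_threshold.
    """
    focal = config.focal_tissue
    if focal not in profile.means.columns:
        raise CallingError(
            f"focal tissue {focal!r} absent from profile "
            f"(tissues: {list(profile.means.columns)})"
        )
    others = [t for t in profile.means.columns if t != focal]
    if not others:
        raise CallingError("need at least one non-focal tissue")

    if config.use_moderated:
        s2, df = residual_variances(profile)
        prior = fit_variance_prior(s2, np.full_like(s2, df), config.d0_max)
    else:
        prior = VariancePrior(d0=0.0, s0_sq=1.0)  # d0=0: ordinary pooled t

    genes = profile.means.index
    out = pd.DataFrame(index=genes)
    out["stem_mean_log2"] = profile.means[focal]
    log2_fold = profile.means[focal] - (
        profile.means.mean(axis=1)
        if config.geomean_include_focal
        else profile.means[others].mean(axis=1)
    )
    out["fold_over_geomean"] = 2.0 ** log2_fold
    out["geomean_criterion_met"] = out["fold_over_geomean"] >= config.fold_threshold

    all_sig = np.ones(len(genes), dtype=bool)
    worst = np.zeros(len(genes))
    for t in others:
        tstat, p = _contrast_arrays(profile, prior, t, focal, config.one_sided)
        adj = bh_adjust(p, config.p_adjust)
        out[f"t_{t}"] = tstat
        out[f"adjp_{t}"] = adj
        all_sig &= adj < config.alpha
        worst = np.maximum(worst, adj)
    out["worst_adj_p"] = worst
    out["all_contrasts_significant"] = all_sig
    out["is_vascular"] = all_sig & out["geomean_criterion_met"].to_numpy()

    n = len(genes)
    called = int(out["is_vascular"].sum())
    logger.info(
        "%s: %d of %d genes (%.1f%%) called vascular",
        profile.species_id, called, n, 100.0 * called / max(n, 1),
    )
    return out


def write_vascular_calls(calls: pd.DataFrame, path) -> None:
    cols = [
        "stem_mean_log2", "fold_over_geomean", "worst_adj_p", "is_vascular"
    ]
    out = calls[cols].copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
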