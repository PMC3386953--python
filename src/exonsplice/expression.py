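"""Transcript-level summarization, empirical-Bayes moderated-t differential
expression with fold-change filtering, and Venn partitioning of call sets.

The moderated t shrinks each feature's residual variance toward a pooled
prior:  with per-feature variance s_g^2 on d_g degrees of freedom and
hyperparameters (d0, s0^2) fitted by moment-matching the distribution of
log s_g^2 (digamma/trigamma moment equations, trigamma inverted by Newton
iteration),

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t~_g   = (mean_b - mean_a) / (s~_g * sqrt(1/n_a + 1/n_b))

with a two-sided p from Student's t on d0 + d_g degrees of freedom
(standard normal when d0 is infinite).  Forcing d0 = 0 recovers the
ordinary two-sample t; d0 = inf pools every variance to s0^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .enrichment import bh_adjust
from .errors import ConfigError
from .model_io import IntensityMatrix, ProbeAnnotation, SampleDesign
from .preprocess import _LOG_FLOOR

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# summarization
# ---------------------------------------------------------------------------


def summarize_transcripts(
    m: IntensityMatrix, annotation: ProbeAnnotation
) -> pd.DataFrame:
    """Transcript x sample log2 expression: mean log2 over surviving probes.

    Only genomic probes present in the matrix contribute; transcripts with
    no surviving probe are excluded and logged.
    """
    if not m.is_background_corrected:
        raise ConfigError("summarize_transcripts needs a corrected matrix")
    genomic = annotation.genomic
    surviving = genomic[genomic["probe_id"].isin(m.values.index)]
    lost = set(genomic["transcript_id"]) - set(surviving["transcript_id"])
    if lost:
        logger.warning(
            "summarize_transcripts: %d transcript(s) have no surviving "
            "probes and are excluded", len(lost),
        )
    log2m = np.log2(m.values.clip(lower=_LOG_FLOOR))
    expr = (
        log2m.loc[surviving["probe_id"]]
        .groupby(surviving.set_index("probe_id")["transcript_id"])
        .mean()
    )
    expr.index.name = "transcript_id"
    return expr


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float, max_iter: int = 50, tol: float = 1e-10) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return y


@dataclass
class VariancePrior:
    """Moment-matched scaled-inverse-chi-square prior for residual variances."""

    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance


def fit_variance_prior(s2: np.ndarray, df: float) -> VariancePrior:
    """Fit (d0, s0^2) from observed variances ``s2`` on ``df`` df each.

    Moment-matches mean and variance of log s^2; when the empirical spread
    of log variances does not exceed what ``df`` alone explains, d0 is
    infinite and s0^2 is the (log-scale) pooled variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        logger.warning("fit_variance_prior: all variances are zero")
        return VariancePrior(d0=math.inf, s0_sq=0.0)
    if (~ok).any():
        logger.warning(
            "fit_variance_prior: %d zero variance(s) excluded from the fit",
            int((~ok).sum()),
        )
    z = np.log(s2[ok])
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(np.mean(e))
    if e.size < 2:
        return VariancePrior(d0=math.inf, s0_sq=math.exp(emean))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return VariancePrior(d0=math.inf, s0_sq=math.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = math.exp(
        emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return VariancePrior(d0=d0, s0_sq=s0_sq)


@dataclass
class ModeratedTResult:
    """Row-wise two-group moderated-t table plus the fitted prior."""

    table: pd.DataFrame
    prior: VariancePrior
    group_a: str = "a"
    group_b: str = "b"


def moderated_t(
    data: pd.DataFrame,
    cols_a: Sequence[str],
    cols_b: Sequence[str],
    d0: float | None = None,
    labels: tuple[str, str] = ("a", "b"),
) -> ModeratedTResult:
    """Two-group moderated t across the rows of ``data``.

    Parameters
    ----------
    data
        feature x sample values (log2 scale).
    cols_a, cols_b
        column names of the two groups; each needs >= 2 members.
    d0
        Override the prior degrees of freedom: ``0`` disables shrinkage
        (ordinary t), ``inf`` forces full pooling, ``None`` (default) fits
        the prior from the data.
    """
    cols_a, cols_b = list(cols_a), list(cols_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ConfigError("each group needs >= 2 replicates")
    a = data[cols_a].to_numpy(dtype=float)
    b = data[cols_b].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    dg = n_a + n_b - 2

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    rss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = rss / dg

    if d0 is None:
        prior = fit_variance_prior(s2, dg)
    else:
        if d0 < 0:
            raise ConfigError("d0 must be >= 0")
        if math.isinf(d0):
            prior = VariancePrior(d0=math.inf, s0_sq=float(np.mean(s2)))
        else:
            fitted = fit_variance_prior(s2, dg)
            prior = VariancePrior(d0=float(d0), s0_sq=fitted.s0_sq)

    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + dg * s2) / (prior.d0 + dg)
        df_total = prior.d0 + dg

    delta = mean_b - mean_a
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, np.where(delta == 0, 0.0, np.inf))
        t = np.where((se == 0) & (delta != 0), np.sign(delta) * np.inf, t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.minimum(p, 1.0)

    table = pd.DataFrame(
        {
            "log2_fc": delta,
            f"mean_{labels[0]}": mean_a,
            f"mean_{labels[1]}": mean_b,
            "s2": s2,
            "df": float(dg),
            "s2_post": s2_post,
            "t": t,
            "df_total": df_total,
            "p_value": p,
            "p_adjusted": bh_adjust(p),
        },
        index=data.index,
    )
    return ModeratedTResult(
        table=table, prior=prior, group_a=labels[0], group_b=labels[1]
    )


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


@dataclass
class DifferentialExpressionTable:
    """Per-transcript two-group statistics for one contrast (b over a)."""

    table: pd.DataFrame
    prior: VariancePrior
    condition_a: str
    condition_b: str
    fold_threshold: float | None = None
    alpha: float | None = None

    @property
    def contrast(self) -> str:
        return f"{self.condition_b}:{self.condition_a}"

    def significant_transcripts(self) -> list[str]:
        t = self.table
        if "passes_fold_filter" not in t.columns or self.alpha is None:
            raise ConfigError("run fold_change_filter first")
        mask = t["passes_fold_filter"] & (t["p_adjusted"] < self.alpha)
        return list(t.index[mask])


def moderated_t_test(
    expr: pd.DataFrame,
    design: SampleDesign,
    condition_pair: tuple[str, str],
    d0: float | None = None,
) -> DifferentialExpressionTable:
    """Moderated-t differential expression between two conditions.

    ``condition_pair = (a, b)``; log2 fold changes are b over a.
    """
    cond_a, cond_b = condition_pair
    cols_a = design.samples_for(cond_a)
    cols_b = design.samples_for(cond_b)
    res = moderated_t(
        expr, cols_a, cols_b, d0=d0, labels=(cond_a, cond_b)
    )
    return DifferentialExpressionTable(
        table=res.table,
        prior=res.prior,
        condition_a=cond_a,
        condition_b=cond_b,
    )


def fold_change_filter(
    de: DifferentialExpressionTable,
    threshold_fold: float = 2.0,
    alpha: float = 0.05,
    strict: bool = False,
) -> DifferentialExpressionTable:
    """Mark transcripts passing the fold-change cutoff (inclusive by default).

    ``strict=True`` switches the boundary to strictly greater-than.
    """
    if threshold_fold <= 1.0:
        raise ConfigError("threshold_fold must be > 1")
    if not 0.0 < alpha <= 1.0:
        raise ConfigError("alpha must be in (0, 1]")
    cut = math.log2(threshold_fold)
    absfc = de.table["log2_fc"].abs()
    passes = absfc > cut if strict else absfc >= cut
    de.table["passes_fold_filter"] = passes
    de.fold_threshold = threshold_fold
    de.alpha = alpha
    return de


# ---------------------------------------------------------------------------
# Venn partitioning
# ---------------------------------------------------------------------------


@dataclass
class VennPartition:
    """Disjoint regions of a labelled family of sets.

    Keys are sorted tuples of the labels containing each member; the regions
    partition the union of the inputs.
    """

    regions: dict[tuple[str, ...], list]

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def region(self, *labels: str) -> list:
        return self.regions.get(tuple(sorted(labels)), [])

    def unique_to(self, label: str) -> list:
        return self.regions.get((label,), [])

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.regions.values())


def venn_partition(named_sets: Mapping[str, Iterable]) -> VennPartition:
    """Assign every member to the region of exactly the labels containing it."""
    if not named_sets:
        raise ConfigError("venn_partition needs a non-empty input")
    if len(named_sets) < 2:
        raise ConfigError("venn_partition needs >= 2 named sets")
    sets = {label: set(v) for label, v in named_sets.items()}
    union = set().union(*sets.values())
    regions: dict[tuple[str, ...], list] = {}
    for member in union:
        key = tuple(sorted(l for l, s in sets.items() if member in s))
        regions.setdefault(key, []).append(member)
    for key in regions:
        regions[key] = sorted(regions[key])
    return VennPartition(regions)
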