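"""Splicing index and the dual-test differential-splicing caller.

The per-probe splicing index is the probe's background-corrected intensity
divided by its transcript's overall expression — a log2 difference here,
since everything downstream is log scale:

    SI(p, s) = log2 I(p, s) - E(t(p), s)

so by construction the probe-level SI of a transcript averages to zero in
every sample, and any transcript-wide (transcription-level) change cancels.
Probeset-level SI is the unweighted mean over the probeset's probes.

Two independent probeset-level tests are run on the SI values — a one-way
ANOVA across conditions ("MIDAS-style") and an empirical-Bayes moderated t
between two conditions ("MADS-style") — and a probeset is called
alternatively spliced only when *both* tests fall below alpha (default
0.01).  No multiplicity correction is applied to the splicing p-values;
the two-test conjunction is the error control.  BH-adjusted columns are
emitted for information only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .errors import ConfigError, IntegrityError
from .expression import VariancePrior, moderated_t
from .model_io import IntensityMatrix, ProbeAnnotation, SampleDesign
from .preprocess import _LOG_FLOOR, PresenceCalls

logger = logging.getLogger(__name__)


@dataclass
class SplicingIndexMatrix:
    """Per-probe and per-probeset log2 splicing indices."""

    probe_si: pd.DataFrame  # probe x sample
    probeset_si: pd.DataFrame  # probeset x sample
    probe_to_probeset: pd.Series
    probeset_to_transcript: pd.Series

    @property
    def probeset_ids(self) -> list[str]:
        return list(self.probeset_si.index)


def splicing_index(
    m: IntensityMatrix,
    expr: pd.DataFrame,
    annotation: ProbeAnnotation,
    presence: PresenceCalls | None = None,
    conditions: Sequence[str] | None = None,
) -> SplicingIndexMatrix:
    """Compute log2 splicing indices from a corrected matrix.

    ``expr`` must be the transcript summary of the same corrected matrix.
    When ``presence`` and ``conditions`` are given, only transcripts present
    in *all* the named conditions are scored (prevents absence-driven
    pseudo-splicing).
    """
    if not m.is_background_corrected:
        raise ConfigError("splicing_index needs a background-corrected matrix")
    genomic = annotation.genomic
    genomic = genomic[genomic["probe_id"].isin(m.values.index)]

    keep_tx = set(genomic["transcript_id"])
    if presence is not None:
        if conditions is None:
            raise ConfigError("conditions required when presence is given")
        keep_tx &= set(presence.present_in_all(conditions))
    genomic = genomic[genomic["transcript_id"].isin(keep_tx)]

    missing_expr = keep_tx - set(expr.index)
    if missing_expr:
        raise IntegrityError(
            f"{len(missing_expr)} transcript(s) lack an expression value, "
            f"e.g. {sorted(missing_expr)[:5]}"
        )

    probes = genomic["probe_id"].to_numpy()
    tx_of_probe = genomic.set_index("probe_id")["transcript_id"]
    log2m = np.log2(m.values.loc[probes].clip(lower=_LOG_FLOOR))
    e = expr.loc[tx_of_probe.loc[probes], m.values.columns].to_numpy()
    probe_si = log2m - e

    ps_of_probe = genomic.set_index("probe_id")["probeset_id"]
    probeset_si = probe_si.groupby(ps_of_probe.loc[probes]).mean()
    probeset_si.index.name = "probeset_id"
    ps2tx = genomic.drop_duplicates("probeset_id").set_index("probeset_id")[
        "transcript_id"
    ]
    return SplicingIndexMatrix(
        probe_si=probe_si,
        probeset_si=probeset_si.sort_index(),
        probe_to_probeset=ps_of_probe,
        probeset_to_transcript=ps2tx.sort_index(),
    )


# ---------------------------------------------------------------------------
# probeset-level tests
# ---------------------------------------------------------------------------


def midas_test(
    si: SplicingIndexMatrix,
    design: SampleDesign,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One-way ANOVA of probeset-level SI across conditions.

    Returns a probeset-indexed frame with F, p_value and a ``degenerate``
    flag (set, with p = 1, when both between- and within-group variation
    vanish).  With exactly two groups, F = t^2 and the p equals the
    equal-variance two-sample t-test's.
    """
    if conditions is None:
        conditions = design.conditions
    conditions = list(conditions)
    if len(conditions) < 2:
        raise ConfigError("midas_test needs >= 2 conditions")
    groups = []
    for c in conditions:
        cols = design.samples_for(c)
        if len(cols) < 2:
            raise ConfigError(f"condition {c!r} has < 2 replicates")
        groups.append(si.probeset_si[cols].to_numpy(dtype=float))
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    n_total = int(ns.sum())

    means = np.stack([g.mean(axis=1) for g in groups], axis=1)
    grand = np.concatenate(groups, axis=1).mean(axis=1)
    ssb = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = sum(
        ((g - mg[:, None]) ** 2).sum(axis=1)
        for g, mg in zip(groups, means.T)
    )
    df_b, df_w = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    degenerate = (ssw <= 0) & (ssb <= 0)
    f = np.where(degenerate, 0.0, f)
    f = np.where((ssw <= 0) & (ssb > 0), np.inf, f)
    p = stats.f.sf(f, df_b, df_w)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"F": f, "p_value": p, "degenerate": degenerate},
        index=si.probeset_si.index,
    )


def mads_test(
    si: SplicingIndexMatrix,
    design: SampleDesign,
    condition_pair: tuple[str, str],
    d0: float | None = None,
    probe_level: bool = False,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t on SI between exactly two conditions.

    Default operates on probeset-level SI with the variance prior shared
    across all probesets.  ``probe_level=True`` switches to per-probe
    moderated t combined per probeset by Fisher's method — provided for
    comparison, but not the default, because correlation between probes of
    one probeset inflates the Fisher combination.
    """
    cond_a, cond_b = condition_pair
    cols_a = design.samples_for(cond_a)
    cols_b = design.samples_for(cond_b)
    if not probe_level:
        res = moderated_t(
            si.probeset_si, cols_a, cols_b, d0=d0, labels=(cond_a, cond_b)
        )
        out = res.table[
            ["log2_fc", f"mean_{cond_a}", f"mean_{cond_b}", "t", "p_value"]
        ].copy()
        out.attrs["prior"] = res.prior
        return out
    res = moderated_t(
        si.probe_si, cols_a, cols_b, d0=d0, labels=(cond_a, cond_b)
    )
    per_probe_p = res.table["p_value"]
    grouped = per_probe_p.groupby(si.probe_to_probeset.loc[per_probe_p.index])
    chi2 = grouped.apply(lambda p: -2.0 * np.log(np.maximum(p, 1e-300)).sum())
    kk = grouped.size()
    p = pd.Series(
        stats.chi2.sf(chi2.to_numpy(), 2 * kk.to_numpy()), index=chi2.index
    )
    mean_a = si.probeset_si[cols_a].mean(axis=1)
    mean_b = si.probeset_si[cols_b].mean(axis=1)
    out = pd.DataFrame(
        {
            "log2_fc": mean_b - mean_a,
            f"mean_{cond_a}": mean_a,
            f"mean_{cond_b}": mean_b,
            "t": np.nan,
            "p_value": p,
        }
    ).loc[si.probeset_si.index]
    out.attrs["prior"] = res.prior
    return out


# ---------------------------------------------------------------------------
# consensus call
# ---------------------------------------------------------------------------


@dataclass
class SplicingCallTable:
    """Dual-test consensus: called iff both p-values are below alpha."""

    table: pd.DataFrame  # probeset-indexed
    transcript_calls: pd.Series  # transcript -> bool (any probeset called)
    alpha: float

    @property
    def called_probesets(self) -> list[str]:
        return list(self.table.index[self.table["is_alternatively_spliced"]])

    @property
    def called_transcripts(self) -> list[str]:
        return list(self.transcript_calls.index[self.transcript_calls])

    def called_genes(self, annotation: ProbeAnnotation) -> list[str]:
        tx2gene = annotation.transcript_to_gene()
        return sorted({tx2gene[t] for t in self.called_transcripts})


def consensus_splicing_calls(
    p_midas: pd.Series,
    p_mads: pd.Series,
    annotation_or_map: ProbeAnnotation | pd.Series,
    alpha: float = 0.01,
) -> SplicingCallTable:
    """Conjunction of the two splicing tests at a raw-p threshold.

    A probeset is called iff ``p_midas < alpha`` and ``p_mads < alpha``;
    a transcript is called iff any of its probesets is.  The two p maps
    must cover the same probesets.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must be in (0, 1)")
    set_midas, set_mads = set(p_midas.index), set(p_mads.index)
    if set_midas != set_mads:
        diff = sorted(set_midas.symmetric_difference(set_mads))
        raise IntegrityError(
            f"p-value maps cover different probesets; symmetric difference "
            f"({len(diff)}): {diff[:10]}"
        )
    if isinstance(annotation_or_map, ProbeAnnotation):
        ps2tx = annotation_or_map.probeset_to_transcript()
    else:
        ps2tx = annotation_or_map
    idx = p_midas.sort_index().index
    pm = p_midas.loc[idx].astype(float)
    pd_ = p_mads.loc[idx].astype(float)
    called = (pm < alpha) & (pd_ < alpha)
    table = pd.DataFrame(
        {
            "transcript_id": ps2tx.loc[idx].to_numpy(),
            "p_midas": pm,
            "p_mads": pd_,
            "p_midas_adjusted": bh_adjust(pm.to_numpy()),
            "p_mads_adjusted": bh_adjust(pd_.to_numpy()),
            "is_alternatively_spliced": called,
        },
        index=idx,
    )
    table.index.name = "probeset_id"
    transcript_calls = called.groupby(table["transcript_id"]).any()
    transcript_calls.name = "is_alternatively_spliced"
    return SplicingCallTable(
        table=table, transcript_calls=transcript_calls, alpha=alpha
    )
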