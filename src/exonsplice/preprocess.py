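"""Background correction, cross-hybridizer removal, probe-effect
estimation/correction, and present/absent detection.

Probe affinities are estimated with Tukey median polish, the standard
robust additive decomposition of a log2 probe x sample block, and are
re-centered to zero mean within each probeset.  Detection-above-background
uses the empirical distribution of the dedicated background probes:
a transcript is detected in a sample when its mean probe log2 intensity
exceeds the background log2 mean by ``z_threshold`` background SDs, and is
present in a condition when detected in at least ``min_replicates`` of its
samples.  All thresholds are exposed as parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError
from .model_io import IntensityMatrix, ProbeAnnotation, SampleDesign

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 1.0
_LOG_FLOOR = 1e-6  # positive floor used before taking log2 of raw values


@dataclass
class ProbeEffects:
    """Per-probe log2 affinity estimates, zero-mean within each probeset."""

    affinities: pd.Series  # probe_id -> affinity (log2)
    converged: bool = True
    n_iterations: int = 0
    single_probe_probesets: list[str] = field(default_factory=list)


@dataclass
class PresenceCalls:
    """Transcript x condition presence flags plus per-sample scores."""

    present: pd.DataFrame  # transcript x condition, bool
    detected: pd.DataFrame  # transcript x sample, bool
    scores: pd.DataFrame  # transcript x sample, mean probe log2 intensity
    z_threshold: float = 2.0
    min_replicates: int = 3

    def present_transcripts(self, condition: str) -> list[str]:
        col = self.present[condition]
        return list(col.index[col])

    def present_in_all(self, conditions) -> list[str]:
        mask = self.present[list(conditions)].all(axis=1)
        return list(mask.index[mask])


@dataclass
class CrossHybReport:
    removed_probes: list[str]
    emptied_probesets: list[str]


def background_correct(
    m: IntensityMatrix,
    annotation: ProbeAnnotation,
    floor_epsilon: float = DEFAULT_FLOOR,
) -> IntensityMatrix:
    """Subtract each sample's mean background-probe intensity, floored.

    The floor (``floor_epsilon`` > 0) keeps every value strictly positive so
    log2 is defined downstream.  Background probe rows are corrected too and
    retained; they end up at the floor on average.
    """
    if m.is_background_corrected:
        raise ConfigError("matrix is already background-corrected")
    if floor_epsilon <= 0:
        raise ConfigError("floor_epsilon must be > 0")
    bg_ids = [p for p in annotation.background_probe_ids if p in m.values.index]
    if not bg_ids:
        raise ConfigError(
            "no background probes in matrix; background correction needs "
            "them — pass an explicit background constant via "
            "subtract_constant() instead"
        )
    bg_mean = m.values.loc[bg_ids].mean(axis=0)
    corrected = (m.values - bg_mean).clip(lower=floor_epsilon)
    return IntensityMatrix(corrected, is_background_corrected=True)


def subtract_constant(
    m: IntensityMatrix, background: float, floor_epsilon: float = DEFAULT_FLOOR
) -> IntensityMatrix:
    """Background correction fallback when no background probes exist."""
    if m.is_background_corrected:
        raise ConfigError("matrix is already background-corrected")
    if floor_epsilon <= 0:
        raise ConfigError("floor_epsilon must be > 0")
    corrected = (m.values - background).clip(lower=floor_epsilon)
    return IntensityMatrix(corrected, is_background_corrected=True)


def drop_cross_hyb(
    m: IntensityMatrix, annotation: ProbeAnnotation
) -> tuple[IntensityMatrix, CrossHybReport]:
    """Remove rows flagged as cross-hybridizing.

    Probesets whose every probe is flagged vanish from downstream scope and
    are listed in the report.
    """
    flagged = [p for p in annotation.cross_hyb_probe_ids if p in m.values.index]
    keep = [p for p in m.values.index if p not in set(flagged)]
    g = annotation.genomic
    before = set(g["probeset_id"])
    after = set(g.loc[~g["cross_hyb_flag"], "probeset_id"])
    emptied = sorted(before - after)
    if emptied:
        logger.warning(
            "drop_cross_hyb: %d probeset(s) lost all probes: %s",
            len(emptied), ", ".join(emptied[:10]),
        )
    out = IntensityMatrix(
        m.values.loc[keep], is_background_corrected=m.is_background_corrected
    )
    return out, CrossHybReport(sorted(flagged), emptied)


def _median_polish(
    x: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, int, bool]:
    """Row effects of a Tukey median polish of ``x`` (rows x cols)."""
    resid = x.astype(float).copy()
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rmed = np.median(resid, axis=1)
        row += rmed
        resid -= rmed[:, None]
        cmed = np.median(resid, axis=0)
        col += cmed
        resid -= cmed[None, :]
        delta = max(np.abs(rmed).max(), np.abs(cmed).max())
        if delta < tol:
            converged = True
            break
    return row, it, converged


def estimate_probe_effects(
    m: IntensityMatrix,
    annotation: ProbeAnnotation,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> ProbeEffects:
    """Median-polish probe affinities, per transcript, on log2 intensities.

    Each transcript's probe x sample log2 block is decomposed into
    sample effect + probe effect + residual; the probe effects are then
    re-centered to zero mean within each probeset.  Probesets with a single
    probe get affinity 0 (with a warning), since a lone probe's affinity is
    unidentifiable from its probeset mean.
    """
    if not m.is_background_corrected:
        raise ConfigError("estimate_probe_effects requires a corrected matrix")
    log2m = np.log2(m.values.clip(lower=_LOG_FLOOR))
    genomic = annotation.genomic
    in_matrix = genomic["probe_id"].isin(m.values.index)
    genomic = genomic[in_matrix]

    affinities = pd.Series(0.0, index=genomic["probe_id"].to_numpy())
    all_converged = True
    worst_iter = 0
    for _, block in genomic.groupby("transcript_id", sort=True):
        probes = block["probe_id"].to_numpy()
        sub = log2m.loc[probes].to_numpy()
        row, it, conv = _median_polish(sub, max_iter=max_iter, tol=tol)
        all_converged &= conv
        worst_iter = max(worst_iter, it)
        affinities.loc[probes] = row
    # re-center within probesets
    ps = genomic.set_index("probe_id")["probeset_id"]
    affinities = affinities - affinities.groupby(ps).transform("mean")

    sizes = ps.groupby(ps).size()
    singles = sorted(sizes.index[sizes == 1])
    if singles:
        logger.warning(
            "estimate_probe_effects: %d single-probe probeset(s) assigned "
            "affinity 0", len(singles),
        )
    affinities.name = "affinity"
    return ProbeEffects(
        affinities=affinities,
        converged=all_converged,
        n_iterations=worst_iter,
        single_probe_probesets=singles,
    )


def apply_probe_effects(
    m: IntensityMatrix, effects: ProbeEffects
) -> IntensityMatrix:
    """Divide out 2**affinity per probe (log2 subtraction), linear output."""
    missing = m.values.index.difference(effects.affinities.index)
    if len(missing):
        raise IntegrityError(
            f"probe effects missing for {len(missing)} probe(s), "
            f"e.g. {list(missing[:5])}"
        )
    aff = effects.affinities.loc[m.values.index].to_numpy()
    corrected = m.values / np.exp2(aff)[:, None]
    return IntensityMatrix(
        corrected, is_background_corrected=m.is_background_corrected
    )


def negate_effects(effects: ProbeEffects) -> ProbeEffects:
    return ProbeEffects(
        affinities=-effects.affinities,
        converged=effects.converged,
        n_iterations=effects.n_iterations,
        single_probe_probesets=list(effects.single_probe_probesets),
    )


def detect_present(
    m: IntensityMatrix,
    annotation: ProbeAnnotation,
    design: SampleDesign,
    z_threshold: float = 2.0,
    min_replicates: int = 3,
) -> PresenceCalls:
    """Present/absent calls against the background-probe distribution.

    Operates on the *raw* (pre-correction) matrix so the background probes
    still carry the background distribution.  A transcript is detected in a
    sample iff its mean probe log2 intensity exceeds
    ``background mean + z_threshold * background sd`` (log2 scale); it is
    present in a condition iff detected in >= ``min_replicates`` samples.
    """
    if m.is_background_corrected:
        raise ConfigError(
            "detect_present expects the raw matrix (background probes must "
            "still carry the background distribution)"
        )
    bg_ids = [p for p in annotation.background_probe_ids if p in m.values.index]
    if not bg_ids:
        raise ConfigError("no background probes available for detection")
    counts = design.table.groupby("condition")["sample_id"].count()
    short = counts[counts < min_replicates]
    if len(short):
        raise ConfigError(
            f"condition(s) with fewer samples than min_replicates="
            f"{min_replicates}: {dict(short)}"
        )

    log2m = np.log2(m.values.clip(lower=_LOG_FLOOR))
    bg = log2m.loc[bg_ids]
    bg_mean = bg.mean(axis=0)
    bg_sd = bg.std(axis=0, ddof=1) if len(bg_ids) > 1 else bg.iloc[0] * 0.0
    threshold = bg_mean + z_threshold * bg_sd

    genomic = annotation.genomic
    genomic = genomic[genomic["probe_id"].isin(m.values.index)]
    scores = (
        log2m.loc[genomic["probe_id"]]
        .groupby(genomic.set_index("probe_id")["transcript_id"])
        .mean()
    )
    detected = scores.gt(threshold, axis=1)

    conditions = design.conditions
    present = pd.DataFrame(index=scores.index, columns=conditions, dtype=bool)
    for c in conditions:
        cols = design.samples_for(c)
        present[c] = detected[cols].sum(axis=1) >= min_replicates
    return PresenceCalls(
        present=present,
        detected=detected,
        scores=scores,
        z_threshold=z_threshold,
        min_replicates=min_replicates,
    )
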