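"""Synthetic exon-array experiment generator with planted ground truth.

Generative model (per genomic probe p in probeset ps of transcript t,
sample s in condition c):

    I(p, s) = bg(p, s) + 2 ** ( a_t(c) + affinity_p
                                + log2 PSI_ps(c)
                                + xhyb_offset_p + eps(p, s) )

with ``eps ~ Normal(0, noise_sd)``, ``bg`` drawn from a normal truncated at
zero, constitutive probesets at PSI = 1, planted alternatively-spliced
probesets differing by ``delta_inclusion`` between a named condition pair,
and cross-hybridizing probes carrying a condition-independent log2 offset.
Transcripts planted as absent in a condition contribute no signal there.

Randomness is split into a *structure* stream (which transcripts/probesets
carry events, affinities, layout) and a *noise* stream (eps, background),
so two runs sharing the structure seed plant identical events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .model_io import (
    GeneSet,
    GeneSetCollection,
    IntensityMatrix,
    ProbeAnnotation,
    SampleDesign,
)

DEFAULT_CONDITIONS = ("naive", "TCR", "TCR_CD28")


@dataclass
class SimulationConfig:
    """Parameters of the generative model.  All log2 quantities unless noted."""

    n_transcripts: int = 200
    exons_per_transcript: tuple[int, int] = (4, 8)
    probes_per_probeset: tuple[int, int] = (3, 4)
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates: int = 4
    baseline_log2_abundance: tuple[float, float] = (8.0, 1.0)  # mean, sd
    probe_affinity_sd: float = 0.5
    noise_sd: float = 0.25
    background_mean: float = 50.0  # linear units
    background_sd: float = 10.0  # linear units
    n_background_probes: int = 100
    frac_de_transcripts: float = 0.0
    de_log2fc: float = 2.0
    de_condition_pair: tuple[str, str] | None = None
    frac_as_transcripts: float = 0.0
    delta_inclusion: float = 0.4
    as_condition_pair: tuple[str, str] | None = None
    as_mode: str = "single"
    frac_absent_transcripts: float = 0.0
    frac_cross_hyb_probes: float = 0.0
    cross_hyb_offset: float = 1.0
    seed: int = 0
    structure_seed: int | None = None
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "frac_de_transcripts",
            "frac_as_transcripts",
            "frac_absent_transcripts",
            "frac_cross_hyb_probes",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("probe_affinity_sd", "noise_sd", "background_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 < self.delta_inclusion <= 1.0:
            raise ConfigError("delta_inclusion must be in (0, 1]")
        if self.replicates < 2:
            raise ConfigError("replicates must be >= 2")
        if self.n_transcripts < 1:
            raise ConfigError("n_transcripts must be >= 1")
        if self.as_mode not in ("single", "switch"):
            raise ConfigError("as_mode must be 'single' or 'switch'")
        if len(self.conditions) < 2:
            raise ConfigError("need >= 2 conditions")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigError("conditions must be unique")
        self.exons_per_transcript = _as_range(
            self.exons_per_transcript, "exons_per_transcript"
        )
        self.probes_per_probeset = _as_range(
            self.probes_per_probeset, "probes_per_probeset"
        )
        for name in ("de_condition_pair", "as_condition_pair"):
            pair = getattr(self, name)
            if pair is not None:
                pair = tuple(pair)
                if len(pair) != 2 or any(
                    c not in self.conditions for c in pair
                ):
                    raise ConfigError(
                        f"{name} must name 2 declared conditions, got {pair}"
                    )
                setattr(self, name, pair)

    def resolved_pair(self, which: str) -> tuple[str, str]:
        pair = getattr(self, which)
        if pair is None:
            pair = (self.conditions[-2], self.conditions[-1])
        return pair


def _as_range(value, name: str) -> tuple[int, int]:
    if isinstance(value, int):
        value = (value, value)
    lo, hi = int(value[0]), int(value[1])
    if lo < 1 or hi < lo:
        raise ConfigError(f"{name} must be a positive (lo, hi) range")
    return (lo, hi)


@dataclass
class GroundTruth:
    """Planted parameters for recovery scoring.

    Attributes
    ----------
    abundance
        transcript x condition log2 abundance (DE offsets included).
    psi
        probeset x condition inclusion level in [0, 1].
    presence
        transcript x condition boolean presence flags.
    affinity
        per-probe planted log2 affinity (genomic probes only).
    """

    abundance: pd.DataFrame
    psi: pd.DataFrame
    presence: pd.DataFrame
    affinity: pd.Series
    de_transcripts: list[str] = field(default_factory=list)
    as_transcripts: list[str] = field(default_factory=list)
    as_probesets: list[str] = field(default_factory=list)
    cross_hyb_probes: list[str] = field(default_factory=list)

    def log2fc(self, transcript: str, cond_a: str, cond_b: str) -> float:
        """Planted log2 fold change of ``cond_b`` over ``cond_a``."""
        row = self.abundance.loc[transcript]
        return float(row[cond_b] - row[cond_a])

    def delta_psi(self, probeset: str, cond_a: str, cond_b: str) -> float:
        row = self.psi.loc[probeset]
        return float(row[cond_b] - row[cond_a])

    def centered_affinities(self, annotation: ProbeAnnotation) -> pd.Series:
        """Planted affinities re-centered to zero mean within each probeset."""
        g = annotation.genomic.set_index("probe_id")
        aff = self.affinity.loc[g.index]
        return aff - aff.groupby(g["probeset_id"]).transform("mean")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size
) -> np.ndarray:
    """Normal(mean, sd) truncated at 0 (proper truncation, not clipping)."""
    if sd == 0:
        return np.full(size, max(mean, 0.0))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(
        a, np.inf, loc=mean, scale=sd, size=size, random_state=rng
    )


def _build_layout(cfg: SimulationConfig, rng: np.random.Generator):
    """Draw the probe/probeset/transcript nesting (structure stream)."""
    rows = []
    tw = max(4, len(str(cfg.n_transcripts)))
    probe_counter = 0
    for ti in range(cfg.n_transcripts):
        tx = f"T{ti + 1:0{tw}d}"
        gene = f"G{ti + 1:0{tw}d}"
        n_exons = int(rng.integers(*cfg.exons_per_transcript, endpoint=True))
        for ei in range(1, n_exons + 1):
            ps = f"{tx}_E{ei:02d}"
            n_probes = int(
                rng.integers(*cfg.probes_per_probeset, endpoint=True)
            )
            for _ in range(n_probes):
                probe_counter += 1
                rows.append(
                    {
                        "probe_id": f"P{probe_counter:07d}",
                        "probeset_id": ps,
                        "transcript_id": tx,
                        "gene_id": gene,
                        "exon_index": ei,
                        "cross_hyb_flag": False,
                        "probe_kind": "genomic",
                    }
                )
    n_genomic = len(rows)
    if cfg.frac_cross_hyb_probes > 0:
        n_xh = int(round(cfg.frac_cross_hyb_probes * n_genomic))
        idx = rng.choice(n_genomic, size=n_xh, replace=False)
        for i in idx:
            rows[i]["cross_hyb_flag"] = True
    for bi in range(1, cfg.n_background_probes + 1):
        rows.append(
            {
                "probe_id": f"BG{bi:05d}",
                "probeset_id": np.nan,
                "transcript_id": np.nan,
                "gene_id": np.nan,
                "exon_index": pd.NA,
                "cross_hyb_flag": False,
                "probe_kind": "background",
            }
        )
    df = pd.DataFrame(rows)
    df["exon_index"] = df["exon_index"].astype("Int64")
    return ProbeAnnotation(df)


def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[IntensityMatrix, ProbeAnnotation, SampleDesign, GroundTruth]:
    """Generate one experiment plus ground truth; bit-identical per seed."""
    if cfg.structure_seed is not None or cfg.noise_seed is not None:
        if cfg.structure_seed is None or cfg.noise_seed is None:
            raise ConfigError(
                "structure_seed and noise_seed must be given together"
            )
        struct_ss = np.random.SeedSequence(cfg.structure_seed)
        noise_ss = np.random.SeedSequence(cfg.noise_seed)
    else:
        struct_ss, noise_ss = np.random.SeedSequence(cfg.seed).spawn(2)
    s_rng = np.random.Generator(np.random.PCG64(struct_ss))
    n_rng = np.random.Generator(np.random.PCG64(noise_ss))

    annotation = _build_layout(cfg, s_rng)
    genomic = annotation.genomic
    transcripts = sorted(genomic["transcript_id"].unique())
    probesets = sorted(genomic["probeset_id"].unique())
    conditions = list(cfg.conditions)

    design = SampleDesign(
        pd.DataFrame(
            [
                {
                    "sample_id": f"{c}_r{r}",
                    "condition": c,
                    "replicate": r,
                }
                for c in conditions
                for r in range(1, cfg.replicates + 1)
            ]
        )
    )

    # -- abundance and presence (structure stream) -------------------------
    mean_ab, sd_ab = cfg.baseline_log2_abundance
    base = s_rng.normal(mean_ab, sd_ab, size=len(transcripts))
    abundance = pd.DataFrame(
        np.tile(base[:, None], (1, len(conditions))),
        index=transcripts,
        columns=conditions,
    )
    presence = pd.DataFrame(
        True, index=transcripts, columns=conditions, dtype=bool
    )

    n_absent = int(round(cfg.frac_absent_transcripts * len(transcripts)))
    absent_tx = sorted(
        map(str, s_rng.choice(transcripts, size=n_absent, replace=False))
    )
    for tx in absent_tx:
        # transcript is ON in a random non-empty proper subset of conditions
        k_on = int(s_rng.integers(1, len(conditions)))
        on = set(s_rng.choice(conditions, size=k_on, replace=False))
        for c in conditions:
            presence.loc[tx, c] = c in on

    n_de = int(round(cfg.frac_de_transcripts * len(transcripts)))
    if n_de > len(transcripts):
        raise ConfigError("more DE transcripts requested than transcripts")
    de_tx = sorted(map(str, s_rng.choice(transcripts, size=n_de, replace=False)))
    de_pair = cfg.resolved_pair("de_condition_pair")
    for tx in de_tx:
        sign = 1.0 if s_rng.random() < 0.5 else -1.0
        abundance.loc[tx, de_pair[1]] += sign * cfg.de_log2fc

    # -- alternative splicing (structure stream) ---------------------------
    psi = pd.DataFrame(1.0, index=probesets, columns=conditions)
    as_pair = cfg.resolved_pair("as_condition_pair")
    eligible = [
        tx
        for tx in transcripts
        if presence.loc[tx, as_pair[0]] and presence.loc[tx, as_pair[1]]
    ]
    n_as = int(round(cfg.frac_as_transcripts * len(transcripts)))
    if n_as > len(eligible):
        raise ConfigError(
            f"requested {n_as} AS transcripts but only {len(eligible)} are "
            "present in both compared conditions"
        )
    as_tx = sorted(map(str, s_rng.choice(eligible, size=n_as, replace=False)))
    as_probesets = []
    ps_by_tx = genomic.drop_duplicates("probeset_id").groupby("transcript_id")[
        "probeset_id"
    ]
    ps_lists = {tx: sorted(v) for tx, v in ps_by_tx}
    for tx in as_tx:
        if cfg.as_mode == "switch":
            # isoform switch: two probesets with opposite inclusion changes,
            # so the transcript-mean expression stays balanced
            if len(ps_lists[tx]) < 2:
                raise ConfigError(
                    f"as_mode='switch' needs >=2 probesets per AS "
                    f"transcript; {tx} has {len(ps_lists[tx])}"
                )
            ps_up, ps_down = map(
                str, s_rng.choice(ps_lists[tx], size=2, replace=False)
            )
            psi.loc[ps_up, as_pair[0]] = 1.0 - cfg.delta_inclusion
            psi.loc[ps_down, as_pair[1]] = 1.0 - cfg.delta_inclusion
            as_probesets.extend([ps_up, ps_down])
        else:
            ps = str(s_rng.choice(ps_lists[tx]))
            as_probesets.append(ps)
            lowered = as_pair[int(s_rng.random() < 0.5)]
            psi.loc[ps, lowered] = 1.0 - cfg.delta_inclusion

    affinity = pd.Series(
        s_rng.normal(0.0, cfg.probe_affinity_sd, size=len(genomic)),
        index=genomic["probe_id"].to_numpy(),
        name="affinity",
    )

    truth = GroundTruth(
        abundance=abundance,
        psi=psi,
        presence=presence,
        affinity=affinity,
        de_transcripts=de_tx,
        as_transcripts=as_tx,
        as_probesets=sorted(as_probesets),
        cross_hyb_probes=sorted(annotation.cross_hyb_probe_ids),
    )

    # -- intensities (noise stream) ----------------------------------------
    samples = design.sample_ids
    cond_of = dict(zip(design.table["sample_id"], design.table["condition"]))
    all_probes = annotation.table["probe_id"].to_numpy()
    values = np.zeros((len(all_probes), len(samples)))

    g = genomic.set_index("probe_id")
    tx_arr = g["transcript_id"].to_numpy()
    ps_arr = g["probeset_id"].to_numpy()
    aff_arr = affinity.loc[g.index].to_numpy()
    xhyb_arr = np.where(
        g["cross_hyb_flag"].to_numpy(), cfg.cross_hyb_offset, 0.0
    )
    is_genomic = annotation.table["probe_kind"].to_numpy() == "genomic"
    n_genomic = int(is_genomic.sum())

    for j, sample in enumerate(samples):
        c = cond_of[sample]
        a = abundance.loc[tx_arr, c].to_numpy()
        p = psi.loc[ps_arr, c].to_numpy()
        on = presence.loc[tx_arr, c].to_numpy()
        eps = n_rng.normal(0.0, cfg.noise_sd, size=n_genomic)
        signal = np.where(
            on, np.exp2(a + aff_arr + np.log2(p) + xhyb_arr + eps), 0.0
        )
        bg = _truncated_normal(
            n_rng, cfg.background_mean, cfg.background_sd, len(all_probes)
        )
        col = bg
        col[is_genomic] = col[is_genomic] + signal
        values[:, j] = col

    matrix = IntensityMatrix(
        pd.DataFrame(values, index=all_probes, columns=samples),
        is_background_corrected=False,
    )
    matrix.values.index.name = "probe_id"
    return matrix, annotation, design, truth


def simulate_null(
    cfg: SimulationConfig,
) -> tuple[IntensityMatrix, ProbeAnnotation, SampleDesign, GroundTruth]:
    """As :func:`simulate_experiment` with all planted events forced off."""
    null_cfg = replace(
        cfg,
        frac_de_transcripts=0.0,
        frac_as_transcripts=0.0,
        frac_absent_transcripts=0.0,
    )
    return simulate_experiment(null_cfg)


def truth_gene_sets(
    truth: GroundTruth, annotation: ProbeAnnotation
) -> GeneSetCollection:
    """Planted DE/AS transcripts as gene sets (handy for enrichment tests)."""
    tx2gene = annotation.transcript_to_gene()
    sets = {}
    if truth.de_transcripts:
        sets["planted_de"] = GeneSet(
            "planted_de",
            "genes with planted expression changes",
            tuple(sorted({tx2gene[t] for t in truth.de_transcripts})),
        )
    if truth.as_transcripts:
        sets["planted_as"] = GeneSet(
            "planted_as",
            "genes with planted splicing changes",
            tuple(sorted({tx2gene[t] for t in truth.as_transcripts})),
        )
    return GeneSetCollection(sets)
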