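"""Core data model and readers/writers for the external TSV/GMT formats.

All tabular I/O is tab-separated with a header row and ``'\n'`` line
endings; writers emit a deterministic column order so that
read -> write -> read round-trips are byte-stable.  Gene identifiers are
opaque, case-sensitive strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

PROBE_KINDS = ("genomic", "background")

ANNOTATION_COLUMNS = [
    "probe_id",
    "probeset_id",
    "transcript_id",
    "gene_id",
    "exon_index",
    "cross_hyb_flag",
    "probe_kind",
]

DESIGN_COLUMNS = ["sample_id", "condition", "replicate"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class IntensityMatrix:
    """Probe-level fluorescence intensities (probes x samples, linear scale).

    Parameters
    ----------
    values
        DataFrame indexed by probe_id with sample_id columns; float dtype.
    is_background_corrected
        Whether per-sample background has already been subtracted.
    """

    values: pd.DataFrame
    is_background_corrected: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate probe ids: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate sample ids: {dups}")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            raise IntegrityError("intensity values must be finite")
        if not self.is_background_corrected and (arr < 0).any():
            raise IntegrityError("raw intensities must be non-negative")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probe_ids: Iterable[str]) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.loc[list(probe_ids)],
            is_background_corrected=self.is_background_corrected,
        )

    def log2(self) -> pd.DataFrame:
        """log2 of the values; caller must ensure positivity."""
        return np.log2(self.values)


@dataclass
class ProbeAnnotation:
    """Probe -> probeset -> transcript -> gene nesting with probe flags.

    Background probes carry empty probeset/transcript/gene fields and a null
    exon index.  Nesting invariants are validated on construction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ANNOTATION_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        t = t[ANNOTATION_COLUMNS].reset_index(drop=True)
        if t["probe_id"].duplicated().any():
            dups = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()
            raise IntegrityError(
                f"probe assigned more than once: {sorted(set(dups))}"
            )
        bad_kind = set(t["probe_kind"]) - set(PROBE_KINDS)
        if bad_kind:
            raise FormatError(f"unknown probe_kind values: {sorted(bad_kind)}")
        bg = t["probe_kind"] == "background"
        for col in ("probeset_id", "transcript_id", "gene_id"):
            if t.loc[bg, col].notna().any() and (t.loc[bg, col] != "").any():
                raise IntegrityError(
                    "background probes must not carry a " + col
                )
        gen = t[~bg]
        for col in ("probeset_id", "transcript_id", "gene_id"):
            if gen[col].isna().any() or (gen[col] == "").any():
                raise IntegrityError(f"genomic probe with empty {col}")
        # probeset nested in exactly one transcript
        ps_tx = gen.groupby("probeset_id")["transcript_id"].nunique()
        bad = ps_tx[ps_tx > 1]
        if len(bad):
            raise IntegrityError(
                f"probeset(s) spanning multiple transcripts: {list(bad.index)}"
            )
        tx_gene = gen.groupby("transcript_id")["gene_id"].nunique()
        bad = tx_gene[tx_gene > 1]
        if len(bad):
            raise IntegrityError(
                f"transcript(s) spanning multiple genes: {list(bad.index)}"
            )
        self.table = t

    # -- convenience views -------------------------------------------------

    @property
    def genomic(self) -> pd.DataFrame:
        return self.table[self.table["probe_kind"] == "genomic"]

    @property
    def background_probe_ids(self) -> list[str]:
        bg = self.table["probe_kind"] == "background"
        return self.table.loc[bg, "probe_id"].tolist()

    @property
    def cross_hyb_probe_ids(self) -> list[str]:
        g = self.genomic
        return g.loc[g["cross_hyb_flag"], "probe_id"].tolist()

    @property
    def transcript_ids(self) -> list[str]:
        return sorted(self.genomic["transcript_id"].unique())

    @property
    def probeset_ids(self) -> list[str]:
        return sorted(self.genomic["probeset_id"].unique())

    def probes_by_transcript(self) -> "pd.core.groupby.DataFrameGroupBy":
        return self.genomic.groupby("transcript_id", sort=True)

    def probeset_to_transcript(self) -> pd.Series:
        g = self.genomic.drop_duplicates("probeset_id")
        return g.set_index("probeset_id")["transcript_id"]

    def transcript_to_gene(self) -> pd.Series:
        g = self.genomic.drop_duplicates("transcript_id")
        return g.set_index("transcript_id")["gene_id"]

    def subset_probes(self, probe_ids: Iterable[str]) -> "ProbeAnnotation":
        keep = set(probe_ids)
        return ProbeAnnotation(
            self.table[self.table["probe_id"].isin(keep)].copy()
        )


@dataclass
class SampleDesign:
    """Sample -> (condition, replicate) assignment."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"design missing columns: {missing}")
        t = t[DESIGN_COLUMNS].reset_index(drop=True)
        if t["sample_id"].duplicated().any():
            raise IntegrityError("duplicate sample_id in design")
        if t.duplicated(["condition", "replicate"]).any():
            raise IntegrityError("duplicate (condition, replicate) pair")
        if (t["replicate"].astype(int) < 1).any():
            raise IntegrityError("replicate indices must be positive")
        t["replicate"] = t["replicate"].astype(int)
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        # first-appearance order
        return list(dict.fromkeys(self.table["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        t = self.table
        out = t.loc[t["condition"] == condition, "sample_id"].tolist()
        if not out:
            raise KeyError(f"unknown condition {condition!r}")
        return out


@dataclass
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        # dedupe preserving first-occurrence order
        self.members = tuple(dict.fromkeys(self.members))
        if not self.members:
            raise IntegrityError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Named, deduplicated gene sets (GMT semantics)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise IntegrityError("set name key/value mismatch")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.values())

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class OrthologMappingReport:
    """Per-set accounting of an ortholog translation."""

    unmapped: dict[str, list[str]]
    dropped_sets: list[str]

    @property
    def n_unmapped(self) -> int:
        return sum(len(v) for v in self.unmapped.values())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    return text.splitlines()


def read_intensity_tsv(path: str | Path) -> IntensityMatrix:
    """Read a probe x sample intensity matrix.

    First column is ``probe_id``; remaining columns are samples.  Duplicate
    probe ids, non-numeric cells and empty files are format errors.
    """
    lines = _read_lines(path)
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: need a probe_id column plus >=1 sample")
    sample_ids = header[1:]
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, "
                f"got {len(fields)}"
            )
        pid = fields[0]
        if pid in seen:
            raise FormatError(f"{path}: duplicate probe id {pid!r}")
        seen.add(pid)
        vals = []
        for col, cell in zip(sample_ids, fields[1:]):
            try:
                vals.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value {cell!r} "
                    f"in column {col!r}"
                ) from None
        probe_ids.append(pid)
        rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    df = pd.DataFrame(rows, index=probe_ids, columns=sample_ids, dtype=float)
    df.index.name = "probe_id"
    return IntensityMatrix(df, is_background_corrected=False)


def write_intensity_tsv(m: IntensityMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "probe_id": str,
            "probeset_id": str,
            "transcript_id": str,
            "gene_id": str,
            "cross_hyb_flag": str,
            "probe_kind": str,
        },
        keep_default_na=False,
    )
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("probeset_id", "transcript_id", "gene_id"):
        df[col] = df[col].replace("", np.nan)
    flag = df["cross_hyb_flag"].str.lower()
    bad = ~flag.isin(["true", "false", "0", "1"])
    if bad.any():
        raise FormatError(
            f"{path}: cross_hyb_flag must be boolean, got "
            f"{sorted(df.loc[bad, 'cross_hyb_flag'].unique())}"
        )
    df["cross_hyb_flag"] = flag.isin(["true", "1"])
    df["exon_index"] = pd.to_numeric(
        df["exon_index"].replace("", np.nan), errors="coerce"
    ).astype("Int64")
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    df = ann.table.copy()
    df["cross_hyb_flag"] = df["cross_hyb_flag"].map(
        {True: "true", False: "false"}
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_design_tsv(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    return SampleDesign(df)


def write_design_tsv(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: name, description, then member genes."""
    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
            )
        name, desc = fields[0], fields[1]
        members = [f for f in fields[2:] if f]
        if not members:
            raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = GeneSet(name, desc, tuple(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    """Two-column (source_id, target_id) mapping table; may be one-to-many."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise FormatError(
            f"{path}: ortholog map must have exactly 2 columns, "
            f"got {df.shape[1]}"
        )
    df.columns = ["source_id", "target_id"]
    return df


def map_orthologs(
    sets: GeneSetCollection, mapping: pd.DataFrame
) -> tuple[GeneSetCollection, OrthologMappingReport]:
    """Translate every set member through a (source, target) mapping.

    Each member is replaced by all of its targets; members with no mapping
    are dropped and reported; duplicates after translation are collapsed;
    sets that become empty are dropped with a warning.
    """
    if mapping is None or len(mapping) == 0:
        raise FormatError("ortholog mapping table is empty")
    lut: dict[str, list[str]] = {}
    for src, tgt in zip(mapping.iloc[:, 0], mapping.iloc[:, 1]):
        lut.setdefault(str(src), []).append(str(tgt))
    out: dict[str, GeneSet] = {}
    unmapped: dict[str, list[str]] = {}
    dropped: list[str] = []
    for gs in sets:
        translated: list[str] = []
        missing: list[str] = []
        for member in gs.members:
            targets = lut.get(member)
            if targets:
                translated.extend(targets)
            else:
                missing.append(member)
        if missing:
            unmapped[gs.name] = missing
            logger.info(
                "map_orthologs: %d unmapped member(s) dropped from %s: %s",
                len(missing), gs.name, ", ".join(missing),
            )
        if translated:
            out[gs.name] = GeneSet(gs.name, gs.description, tuple(translated))
        else:
            dropped.append(gs.name)
            logger.warning(
                "map_orthologs: set %s empty after mapping; dropped", gs.name
            )
    return GeneSetCollection(out), OrthologMappingReport(unmapped, dropped)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    return [ln.strip() for ln in _read_lines(path) if ln.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
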