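"""Reading, validating, filtering and writing the study's table formats.

The on-disk dialect follows MaxQuant/Perseus conventions:

* a "GlyGly (K) sites" style TSV with one row per modification site, columns
  ``Protein``, ``Position``, ``Localization prob``, ``Sequence window``,
  one ``Intensity <timepoint>_<replicate>`` column per sample, and the decoy
  flag columns ``Reverse`` and ``Potential contaminant`` ("+" = flagged,
  blank = not);
* a "proteinGroups" style TSV with ``Protein`` and per-sample
  ``LFQ intensity <timepoint>_<replicate>`` columns;
* FASTA for protein sequences (id = first whitespace-delimited header token);
* a per-residue structural annotation TSV (see :func:`read_annotations`);
* a YAML sample-design file mapping intensity columns to (timepoint,
  replicate).

Positions are 1-based throughout, matching the source tables.  Missing
intensities are empty cells (or "NaN") on disk and ``None`` in memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_SEQ_CHARS = set(AMINO_ACIDS) | {"*"}

#: Default timepoint labels of the meiotic time course: pre-meiotic G0,
#: S phase, double-strand break, strand invasion, double Holliday junction,
#: crossover.
DEFAULT_TIMEPOINTS = ("G0", "S", "DSB", "SI", "dHJ", "CO")


class SchemaError(ValueError):
    """A mandatory column is missing or a table-level contract is violated."""


class RowParseError(ValueError):
    """A single row could not be parsed; the message names the row number."""


@dataclass
class SampleDesign:
    """Maps sample (intensity-column) ids to (timepoint, replicate) pairs."""

    samples: list[str]
    timepoint_of: dict[str, str]
    replicate_of: dict[str, int]

    def __post_init__(self) -> None:
        pairs = set()
        for s in self.samples:
            if s not in self.timepoint_of or s not in self.replicate_of:
                raise SchemaError(f"sample {s!r} lacks a (timepoint, replicate) assignment")
            pair = (self.timepoint_of[s], self.replicate_of[s])
            if pair in pairs:
                raise SchemaError(f"duplicate (timepoint, replicate) pair {pair}")
            pairs.add(pair)

    @property
    def timepoints(self) -> list[str]:
        """Timepoint labels in first-seen sample order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.timepoint_of[s], None)
        return list(seen)

    def replicates_of(self, timepoint: str) -> list[str]:
        return [s for s in self.samples if self.timepoint_of[s] == timepoint]

    @classmethod
    def from_layout(
        cls,
        timepoints: Sequence[str] = DEFAULT_TIMEPOINTS,
        n_replicates: int = 3,
    ) -> "SampleDesign":
        """Build the study's crossed design: sample ids ``<tp>_<rep>``."""
        samples, tp_of, rep_of = [], {}, {}
        for tp in timepoints:
            for rep in range(1, n_replicates + 1):
                sid = f"{tp}_{rep}"
                samples.append(sid)
                tp_of[sid] = tp
                rep_of[sid] = rep
        return cls(samples, tp_of, rep_of)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "samples": [
                {"id": s, "timepoint": self.timepoint_of[s], "replicate": self.replicate_of[s]}
                for s in self.samples
            ]
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SampleDesign":
        doc = yaml.safe_load(Path(path).read_text())
        samples = [row["id"] for row in doc["samples"]]
        tp_of = {row["id"]: str(row["timepoint"]) for row in doc["samples"]}
        rep_of = {row["id"]: int(row["replicate"]) for row in doc["samples"]}
        return cls(samples, tp_of, rep_of)


@dataclass
class SiteRecord:
    """One SUMO-conjugation site.

    ``position`` is the 1-based residue index of the modified lysine.
    ``sequence_window`` is an odd-length window centered on that lysine,
    padded with "_" beyond the protein termini.  ``intensities`` maps
    sample id to a non-negative intensity or ``None`` for missing.
    """

    site_id: str
    protein_id: str
    position: int
    localization_prob: float
    sequence_window: str
    intensities: dict[str, float | None]
    is_reverse: bool = False
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.site_id}: position must be >= 1, got {self.position}")
        if not 0.0 <= self.localization_prob <= 1.0:
            raise ValueError(
                f"{self.site_id}: localization probability {self.localization_prob} outside [0, 1]"
            )
        w = self.sequence_window
        if len(w) % 2 == 0:
            raise ValueError(f"{self.site_id}: sequence window length must be odd, got {len(w)}")
        # Decoy (reverse) windows need not be centered on K.
        if not self.is_reverse and w[len(w) // 2] != "K":
            raise ValueError(f"{self.site_id}: sequence window is not centered on K: {w!r}")


@dataclass
class ProteinRecord:
    """A protein with its sequence, lysine positions and per-sample LFQ values.

    ``sequence`` may be empty when only quantitative columns are known
    (a proteinGroups table carries no sequence); ``lysine_positions`` are
    1-based and always consistent with ``sequence``.
    """

    protein_id: str
    sequence: str = ""
    lysine_positions: list[int] = field(default_factory=list)
    lfq: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = [i + 1 for i, aa in enumerate(self.sequence) if aa == "K"]
        if not self.lysine_positions and self.sequence:
            self.lysine_positions = expected
        elif self.lysine_positions != expected:
            raise ValueError(
                f"{self.protein_id}: lysine_positions inconsistent with sequence"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# sites table

_SITE_COLUMNS = ("Protein", "Position", "Localization prob", "Sequence window",
                 "Reverse", "Potential contaminant")


def _parse_flag(cell: object) -> bool:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return False
    return str(cell).strip() == "+"


def _parse_intensity(cell: object) -> float | None:
    if cell is None:
        return None
    if isinstance(cell, float) and math.isnan(cell):
        return None
    s = str(cell).strip()
    if s == "" or s.lower() == "nan":
        return None
    v = float(s)
    if v < 0:
        raise ValueError(f"negative intensity {v}")
    return v


def read_sites_table(path: str | Path, design: SampleDesign) -> list[SiteRecord]:
    """Read a GlyGly-sites style TSV into :class:`SiteRecord` objects.

    Empty or "NaN" intensity cells become missing; the flag columns map
    "+" to True and blank to False.

    Raises
    ------
    SchemaError
        if a mandatory column (or any per-sample intensity column) is absent.
    RowParseError
        if a row carries a non-integer position; the message names the
        1-based data-row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    intensity_cols = {s: f"Intensity {s}" for s in design.samples}
    for col in list(_SITE_COLUMNS) + list(intensity_cols.values()):
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")

    records: list[SiteRecord] = []
    for rownum, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            position = int(rowd["Position"])
        except ValueError as exc:
            raise RowParseError(
                f"row {rownum}: non-integer position {rowd['Position']!r}"
            ) from exc
        intensities = {
            s: _parse_intensity(rowd[col]) for s, col in intensity_cols.items()
        }
        protein = rowd["Protein"]
        records.append(
            SiteRecord(
                site_id=f"{protein}_K{position}",
                protein_id=protein,
                position=position,
                localization_prob=float(rowd["Localization prob"]),
                sequence_window=rowd["Sequence window"],
                intensities=intensities,
                is_reverse=_parse_flag(rowd["Reverse"]),
                is_contaminant=_parse_flag(rowd["Potential contaminant"]),
            )
        )
    return records


def write_sites_table(sites: Iterable[SiteRecord], path: str | Path, design: SampleDesign) -> None:
    """Write sites in the GlyGly-sites dialect; missing intensities as empty cells."""
    rows = []
    for s in sites:
        row: dict[str, object] = {
            "Protein": s.protein_id,
            "Position": s.position,
            "Localization prob": f"{s.localization_prob:.12g}",
            "Sequence window": s.sequence_window,
            "Reverse": "+" if s.is_reverse else "",
            "Potential contaminant": "+" if s.is_contaminant else "",
        }
        for sid in design.samples:
            v = s.intensities.get(sid)
            row[f"Intensity {sid}"] = "" if v is None else f"{v:.12g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_sites(
    sites: Sequence[SiteRecord], min_loc_prob: float | None = None
) -> list[SiteRecord]:
    """Drop reverse-database and potential-contaminant sites.

    When ``min_loc_prob`` is given, additionally keep only sites whose
    localization probability is at or above it (the study's high-confidence
    cut is 0.96, inclusive).  Order is preserved; idempotent.
    """
    kept = [s for s in sites if not (s.is_reverse or s.is_contaminant)]
    if min_loc_prob is not None:
        kept = [s for s in kept if s.localization_prob >= min_loc_prob]
    return kept


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein sequences; id is the first whitespace-delimited header token."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise SchemaError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        seq = str(rec.seq).upper().rstrip("*")
        bad = set(seq) - _VALID_SEQ_CHARS
        if bad:
            raise SchemaError(
                f"protein {pid!r}: characters outside the amino-acid alphabet: {sorted(bad)}"
            )
        records.append(ProteinRecord(protein_id=pid, sequence=seq))
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
        for p in proteins
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# protein (LFQ) table

def read_protein_table(
    path: str | Path,
    design: SampleDesign,
    sequences: Mapping[str, str] | None = None,
) -> list[ProteinRecord]:
    """Read a proteinGroups style TSV of per-sample LFQ intensities.

    ``sequences`` optionally attaches protein sequences (e.g. from FASTA);
    otherwise records carry an empty sequence.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "Protein" not in df.columns:
        raise SchemaError(f"mandatory column 'Protein' missing from {path}")
    lfq_cols = {s: f"LFQ intensity {s}" for s in design.samples}
    for col in lfq_cols.values():
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rownum, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        pid = rowd["Protein"]
        if pid in seen:
            raise SchemaError(f"row {rownum}: duplicate protein id {pid!r}")
        seen.add(pid)
        lfq = {s: _parse_intensity(rowd[col]) for s, col in lfq_cols.items()}
        seq = (sequences or {}).get(pid, "")
        records.append(ProteinRecord(protein_id=pid, sequence=seq, lfq=lfq))
    return records


def write_protein_table(
    proteins: Iterable[ProteinRecord], path: str | Path, design: SampleDesign
) -> None:
    rows = []
    for p in proteins:
        row: dict[str, object] = {"Protein": p.protein_id}
        for sid in design.samples:
            v = p.lfq.get(sid)
            row[f"LFQ intensity {sid}"] = "" if v is None else f"{v:.12g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# per-residue structural annotation tracks

_ANNOT_COLUMNS = (
    "protein_id", "position", "globular", "long_disorder",
    "short_disorder_score", "exposed", "buried", "coiled_coil", "transmembrane",
)


def read_annotations(path: str | Path) -> dict[str, "ResidueAnnotation"]:
    """Read the per-residue annotation TSV into per-protein track objects.

    One row per residue: ``protein_id, position, globular, long_disorder,
    short_disorder_score, exposed, buried, coiled_coil, transmembrane``
    with boolean tracks encoded 0/1.  Rows must cover positions 1..length
    contiguously for each protein.
    """
    from sumoscape.structure import ResidueAnnotation  # deferred: avoids cycle

    df = pd.read_csv(path, sep="\t")
    for col in _ANNOT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    out: dict[str, ResidueAnnotation] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy()
        n = len(positions)
        if not np.array_equal(positions, np.arange(1, n + 1)):
            raise SchemaError(f"protein {pid!r}: positions are not contiguous 1..{n}")
        out[str(pid)] = ResidueAnnotation(
            protein_id=str(pid),
            length=n,
            globular=grp["globular"].to_numpy(bool),
            long_disorder=grp["long_disorder"].to_numpy(bool),
            short_disorder_score=grp["short_disorder_score"].to_numpy(float),
            exposed=grp["exposed"].to_numpy(bool),
            buried=grp["buried"].to_numpy(bool),
            coiled_coil=grp["coiled_coil"].to_numpy(bool),
            transmembrane=grp["transmembrane"].to_numpy(bool),
        )
    return out


def write_annotations(annotations: Mapping[str, "ResidueAnnotation"], path: str | Path) -> None:
    frames = []
    for pid, ann in annotations.items():
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": pid,
                    "position": np.arange(1, ann.length + 1),
                    "globular": ann.globular.astype(int),
                    "long_disorder": ann.long_disorder.astype(int),
                    "short_disorder_score": np.round(ann.short_disorder_score, 9),
                    "exposed": ann.exposed.astype(int),
                    "buried": ann.buried.astype(int),
                    "coiled_coil": ann.coiled_coil.astype(int),
                    "transmembrane": ann.transmembrane.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
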