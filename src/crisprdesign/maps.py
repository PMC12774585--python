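"""Annotated sequence maps and GenBank serialization.

An :class:`AssemblyMap` is the unit of every pipeline output: a (linear or
circular) DNA sequence with labelled features, serializable to a GenBank
flat file that round-trips losslessly through :func:`write_genbank` /
:func:`read_genbank`. Every feature carries an Ape-style ``/label``
qualifier so maps open usefully in common plasmid editors.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AssemblyMap",
    "MapFeature",
    "read_genbank",
    "read_genbank_all",
    "write_genbank",
]

# fixed LOCUS date so identical designs serialize byte-identically
_FIXED_DATE = "01-JAN-1980"


@dataclass(frozen=True)
class MapFeature:
    """One annotated interval: 0-based half-open, strand in {+1, -1, 0}."""

    start: int
    end: int
    strand: int
    type: str
    label: str
    qualifiers: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def get(self, key: str, default: str | None = None) -> str | None:
        for k, v in self.qualifiers:
            if k == key:
                return v
        return default

    def shifted(self, offset: int) -> "MapFeature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class AssemblyMap:
    name: str
    sequence: str
    topology: str = "linear"  # linear | circular
    features: tuple[MapFeature, ...] = field(default_factory=tuple)
    provenance_notes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {self.topology!r}")
        for f in self.features:
            if not (0 <= f.start <= f.end <= len(self.sequence)):
                raise ValueError(
                    f"feature {f.label!r} [{f.start}, {f.end}) outside "
                    f"sequence of length {len(self.sequence)}"
                )

    def features_labelled(self, label: str) -> list[MapFeature]:
        return [f for f in self.features if f.label == label]

    def with_note(self, note: str) -> "AssemblyMap":
        return replace(self, provenance_notes=self.provenance_notes + (note,))


def _safe_locus_name(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.]", "_", name)[:30] or "map"


def to_seqrecord(amap: AssemblyMap) -> SeqRecord:
    record = SeqRecord(
        Seq(amap.sequence),
        id=_safe_locus_name(amap.name),
        name=_safe_locus_name(amap.name),
        description=amap.name,
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = amap.topology
    record.annotations["data_file_division"] = "SYN"
    record.annotations["date"] = _FIXED_DATE
    if amap.provenance_notes:
        record.annotations["comment"] = "\n".join(amap.provenance_notes)
    for f in amap.features:
        qualifiers = {"label": [f.label]}
        for k, v in f.qualifiers:
            qualifiers.setdefault(k, []).append(v)
        record.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=f.strand or None),
                type=f.type,
                qualifiers=qualifiers,
            )
        )
    return record


def from_seqrecord(record: SeqRecord) -> AssemblyMap:
    features = []
    for sf in record.features:
        label = sf.qualifiers.get("label", [sf.type])[0]
        extra = tuple(
            (k, v)
            for k, vals in sorted(sf.qualifiers.items())
            if k != "label"
            for v in vals
        )
        features.append(
            MapFeature(
                start=int(sf.location.start),
                end=int(sf.location.end),
                strand=int(sf.location.strand or 0),
                type=sf.type,
                label=label,
                qualifiers=extra,
            )
        )
    notes = tuple(
        record.annotations.get("comment", "").split("\n")
    ) if record.annotations.get("comment") else ()
    return AssemblyMap(
        name=record.description.strip() or record.name,
        sequence=str(record.seq).upper(),
        topology=record.annotations.get("topology", "linear"),
        features=tuple(features),
        provenance_notes=notes,
    )


def write_genbank(maps: AssemblyMap | list[AssemblyMap], path: str | Path) -> None:
    """Write one or several maps to a GenBank flat file."""
    if isinstance(maps, AssemblyMap):
        maps = [maps]
    records = [to_seqrecord(m) for m in maps]
    with open(path, "w") as fh:
        with warnings.catch_warnings():
            # long vector names overflow the classic LOCUS column layout;
            # the files still parse everywhere we care about
            warnings.filterwarnings(
                "ignore", message=".*length of locus line.*"
            )
            SeqIO.write(records, fh, "genbank")


def read_genbank(path: str | Path) -> AssemblyMap:
    """Read the first record of a GenBank file."""
    return read_genbank_all(path)[0]


def read_genbank_all(path: str | Path) -> list[AssemblyMap]:
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"GenBank parse error in {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no GenBank records in {path}")
    return [from_seqrecord(r) for r in records]
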