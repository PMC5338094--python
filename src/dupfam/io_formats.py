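"""Readers/writers for the on-disk formats and basic sequence utilities.

All internal coordinates are 0-based half-open; 1-based coordinates appear
only at the depth-TSV boundary (the dialect emitted by ``samtools depth``)
and in BED's documented convention (BED is already 0-based half-open).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import protein_weights

__all__ = [
    "FormatError",
    "SequenceRecord",
    "MultipleAlignment",
    "DepthTrack",
    "Region",
    "RegionSet",
    "read_fasta",
    "write_fasta",
    "read_depth_tsv",
    "write_depth_tsv",
    "read_bed",
    "write_bed",
    "read_droplet_csv",
    "write_droplet_csv",
    "validate_droplet_table",
    "read_newick",
    "write_newick",
    "protein_molecular_weight",
    "kilodaltons",
    "WATER_MASS",
]


class FormatError(ValueError):
    """Malformed or invalid input file content."""


# Average mass of one water molecule (Da), added once per chain.
WATER_MASS = 18.0153

_DNA_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_DNA_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named sequence, nucleotide or amino acid."""

    id: str
    sequence: str
    description: str = ""
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MultipleAlignment:
    """Equal-length sequences tagged with species and paralog labels.

    The tags drive the within/between-species partition used by the
    concerted-evolution statistic: ``species[i]`` and ``paralogs[i]``
    label ``records[i]``.
    """

    records: list[SequenceRecord]
    species: list[str]
    paralogs: list[str]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        if not (len(self.records) == len(self.species) == len(self.paralogs)):
            raise ValueError("records, species and paralogs must align")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        if any(not s for s in self.species) or any(not p for p in self.paralogs):
            raise ValueError("species and paralog labels must be non-empty")

    @property
    def labels(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_sites(self) -> int:
        return len(self.records[0].sequence)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class DepthTrack:
    """Per-base read depth along one contig, starting at ``start`` (0-based)."""

    contig: str
    start: int
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.ndim != 1 or self.depths.size < 1:
            raise ValueError("depths must be a non-empty 1-D vector")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def end(self) -> int:
        return self.start + self.depths.size


@dataclass(frozen=True)
class Region:
    """0-based half-open genomic interval with a label."""

    contig: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.label}: start {self.start} >= end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate region labels: {sorted(dupes)}")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    def by_label(self, label: str) -> Region:
        for r in self.regions:
            if r.label == label:
                return r
        raise KeyError(label)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Sequences are uppercased; gap characters are preserved. Duplicate ids
    and empty sequences are format errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for id {rec.id!r} in {path}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, seq, desc, alphabet))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Depth TSV (samtools-depth dialect: contig, 1-based position, depth)

def read_depth_tsv(path) -> list[DepthTrack]:
    """Parse a 3-column contig/position/depth TSV into per-contig tracks.

    Positions are 1-based on disk. Positions absent between the first and
    last reported base of a contig are taken as depth 0 (``samtools depth``
    omits zero-depth sites unless run with ``-a``).
    """
    per_contig: dict[str, dict[int, int]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
            contig, pos_s, depth_s = parts
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer position or depth ({pos_s!r}, {depth_s!r})"
                ) from None
            if pos < 1 or depth < 0:
                raise FormatError(f"{path}:{lineno}: position must be >=1 and depth >=0")
            if contig not in per_contig:
                per_contig[contig] = {}
                order.append(contig)
            per_contig[contig][pos] = depth
    tracks = []
    for contig in order:
        positions = per_contig[contig]
        lo, hi = min(positions), max(positions)
        depths = np.zeros(hi - lo + 1, dtype=np.int64)
        for pos, depth in positions.items():
            depths[pos - lo] = depth
        tracks.append(DepthTrack(contig, lo - 1, depths))
    return tracks


def write_depth_tsv(tracks: Iterable[DepthTrack], path) -> None:
    """Write tracks in the 1-based TSV dialect, including zero-depth bases."""
    with open(path, "w") as fh:
        for track in tracks:
            for offset, depth in enumerate(track.depths):
                fh.write(f"{track.contig}\t{track.start + offset + 1}\t{depth}\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> RegionSet:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: BED needs 4 columns (contig, start, end, name)")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            regions.append(Region(parts[0], start, end, parts[3]))
    try:
        return RegionSet(regions)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.label}\n")


# ---------------------------------------------------------------------------
# Droplet CSV

DROPLET_COLUMNS = ["sample_id", "population", "channel", "positives", "total"]


def validate_droplet_table(df: pd.DataFrame, source: str = "droplet table") -> pd.DataFrame:
    """Check the droplet-count invariants; returns the validated frame.

    Each sample must carry one 'target' and one 'reference' row, with
    0 <= positives <= total and total > 0.
    """
    missing = [c for c in DROPLET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing columns {missing}")
    bad_channel = ~df["channel"].isin(["target", "reference"])
    if bad_channel.any():
        row = int(df.index[bad_channel][0]) + 1
        raise FormatError(f"{source}: row {row}: channel must be 'target' or 'reference'")
    if (df["total"] <= 0).any():
        row = int(df.index[df["total"] <= 0][0]) + 1
        raise FormatError(f"{source}: row {row}: total must be positive")
    bad = (df["positives"] < 0) | (df["positives"] > df["total"])
    if bad.any():
        row = int(df.index[bad][0]) + 1
        raise FormatError(f"{source}: row {row}: positives must be in [0, total]")
    chan_counts = df.groupby("sample_id")["channel"].agg(lambda s: sorted(s))
    for sample, chans in chan_counts.items():
        if chans != ["reference", "target"]:
            raise FormatError(
                f"{source}: sample {sample!r} must have exactly one target and one reference row"
            )
    return df


def read_droplet_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "population": str, "channel": str})
    return validate_droplet_table(df, source=str(path))


def write_droplet_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=DROPLET_COLUMNS)


# ---------------------------------------------------------------------------
# Newick

def write_newick(tree: dendropy.Tree, path) -> None:
    """Write a tree with branch lengths and integer bootstrap supports
    carried as internal-node labels."""
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            )
        )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


# ---------------------------------------------------------------------------
# Protein mass

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def protein_molecular_weight(seq: str | SequenceRecord) -> float:
    """Average molecular weight of a protein chain, in Daltons.

    Sum of average residue masses plus one water. Only the 20 standard
    uppercase residues are accepted; anything else (lowercase, U, X, gaps)
    raises with the offending character and its 1-based position.
    """
    if isinstance(seq, SequenceRecord):
        seq = seq.sequence
    if not seq:
        raise ValueError("empty protein sequence")
    mass = WATER_MASS
    for i, aa in enumerate(seq, start=1):
        if aa not in _STANDARD_AA:
            raise ValueError(f"unknown residue {aa!r} at position {i}")
        mass += protein_weights[aa] - WATER_MASS
    return mass


def kilodaltons(mass_da: float) -> int:
    """Mass in kD rounded to the nearest integer, the convention used for
    predicted molecular weights on gels."""
    return round(mass_da / 1000.0)
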