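"""Species metadata, alignment IO, dataset restrictions, and coverage filtering.

The comparative analyses take three kinds of input: per-gene multiple sequence
alignments (aligned FASTA), a species metadata table (TSV/CSV with the
migratory phenotype category and the two migratory predictors), and Newick
trees.  This module reads and validates all three, applies the dataset
restrictions used throughout the analyses (full dataset, obligate migrants vs
residents only, a single clade), and applies the reference-coverage filter
that removes fragmentary gene sequences.

Phenotype categories follow the 0/1/2 coding: 0 resident, 1 partial
migrant/dispersive (intermediate movement), 2 obligate migrant.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _tree

__all__ = [
    "SpeciesRecord",
    "GeneAlignment",
    "read_alignment",
    "write_alignment",
    "read_metadata",
    "write_metadata",
    "restrict_dataset",
    "filter_by_coverage",
    "read_newick",
    "write_newick",
    "check_consistency",
]

RESIDENT, PARTIAL, OBLIGATE = 0, 1, 2
_VALID_PHENOTYPES = {RESIDENT, PARTIAL, OBLIGATE}

# bases the distance/codon kernels understand; everything else becomes N
_ALPHABET = set("ACGTN-")


@dataclass(frozen=True)
class SpeciesRecord:
    """One taxon's migratory phenotype and predictors.

    ``migratory_distance`` (km) is only meaningful for migratory phenotypes
    (1/2); residents legitimately have none.  ``breeding_latitude`` is in
    degrees from the equator, i.e. absolute latitude in [0, 90].
    """

    species_id: str
    phenotype: int
    breeding_latitude: float | None = None
    migratory_distance: float | None = None
    clade: str | None = None

    def __post_init__(self):
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if self.phenotype not in _VALID_PHENOTYPES:
            raise ValueError(
                f"{self.species_id}: phenotype must be 0, 1 or 2, "
                f"got {self.phenotype!r}"
            )
        if self.breeding_latitude is not None and not (
            0.0 <= self.breeding_latitude <= 90.0
        ):
            raise ValueError(
                f"{self.species_id}: breeding_latitude must be in [0, 90]"
            )
        if self.migratory_distance is not None and self.migratory_distance < 0:
            raise ValueError(
                f"{self.species_id}: migratory_distance must be >= 0"
            )


@dataclass
class GeneAlignment:
    """Aligned sequences for one gene, keyed by species id.

    All rows have identical length; sequences are upper-case over
    ``{A,C,G,T,N,-}`` (ambiguity codes are collapsed to N on construction).
    """

    gene: str
    rows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        cleaned = {}
        length = None
        for sid, seq in self.rows.items():
            s = _clean_sequence(seq)
            if length is None:
                length = len(s)
            elif len(s) != length:
                raise ValueError(
                    f"alignment {self.gene!r}: row {sid!r} has length "
                    f"{len(s)}, expected {length}"
                )
            cleaned[sid] = s
        self.rows = cleaned

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, species_ids) -> "GeneAlignment":
        keep = [s for s in self.rows if s in set(species_ids)]
        return GeneAlignment(self.gene, {s: self.rows[s] for s in keep})


def _clean_sequence(seq: str) -> str:
    s = seq.upper()
    if set(s) <= _ALPHABET:
        return s
    return re.sub(r"[^ACGT\-]", "N", s)


# ---------------------------------------------------------------------------
# FASTA

def read_alignment(path, gene: str | None = None) -> GeneAlignment:
    """Read one aligned FASTA file into a :class:`GeneAlignment`.

    The gene name defaults to the file stem.  Ragged row lengths, duplicate
    ids and empty files are errors.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences")
    rows: dict[str, str] = {}
    for rec in records:
        if rec.id in rows:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        rows[rec.id] = str(rec.seq)
    name = gene if gene is not None else path.stem
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError(
            f"{path}: ragged alignment, row lengths {sorted(lengths)}"
        )
    return GeneAlignment(name, rows)


def write_alignment(aln: GeneAlignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in aln.rows.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# metadata TSV

_META_COLUMNS = [
    "species_id",
    "phenotype",
    "breeding_latitude",
    "migratory_distance",
    "clade",
]


def read_metadata(path, sep: str | None = None) -> list[SpeciesRecord]:
    """Read the species metadata table (tab- or comma-separated).

    Expected columns: species_id, phenotype, breeding_latitude,
    migratory_distance, clade; the latter three may be empty per row.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in _META_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    records = []
    seen = set()
    for idx, row in df.iterrows():
        sid = str(row["species_id"])
        if sid in seen:
            raise ValueError(f"row {idx}: duplicate species_id {sid!r}")
        seen.add(sid)
        try:
            phen = int(row["phenotype"])
        except (TypeError, ValueError):
            raise ValueError(
                f"row {idx} ({sid}): invalid phenotype code "
                f"{row['phenotype']!r}"
            ) from None
        lat = _opt_float(row.get("breeding_latitude"))
        dist = _opt_float(row.get("migratory_distance"))
        clade = row.get("clade")
        clade = None if pd.isna(clade) else str(clade)
        try:
            records.append(
                SpeciesRecord(sid, phen, lat, dist, clade)
            )
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from None
    return records


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if pd.isna(value):
        return None
    return float(value)


def write_metadata(records, path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "phenotype": r.phenotype,
                "breeding_latitude": r.breeding_latitude,
                "migratory_distance": r.migratory_distance,
                "clade": r.clade,
            }
            for r in records
        ],
        columns=_META_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# dataset restrictions

def restrict_dataset(records, mode: str) -> list[SpeciesRecord]:
    """Apply a dataset restriction.

    ``full`` keeps everything; ``extremes`` keeps only obligate migrants (2)
    and residents (0); ``clade:<label>`` keeps records whose clade equals the
    label (e.g. ``clade:Passeriformes``).
    """
    records = list(records)
    if not records:
        raise ValueError("no records to restrict")
    if mode == "full":
        out = records
    elif mode == "extremes":
        out = [r for r in records if r.phenotype in (RESIDENT, OBLIGATE)]
    elif mode.startswith("clade:"):
        label = mode.split(":", 1)[1]
        out = [r for r in records if r.clade == label]
    else:
        raise ValueError(f"unknown restriction mode {mode!r}")
    if not out:
        raise ValueError(f"restriction {mode!r} leaves no taxa")
    return out


# ---------------------------------------------------------------------------
# coverage filter

def filter_by_coverage(
    aln: GeneAlignment, reference_id: str, threshold: float = 0.5
) -> GeneAlignment:
    """Drop rows covering less than *threshold* of the reference gene.

    Coverage of a row is the number of its non-gap characters in columns
    where the reference is non-gap, divided by the reference's non-gap column
    count — i.e. coverage of the reference gene, not of the alignment.  Rows
    at exactly the threshold are retained; the reference itself always is.
    """
    if reference_id not in aln.rows:
        raise ValueError(
            f"reference {reference_id!r} absent from alignment {aln.gene!r}"
        )
    ref = aln.rows[reference_id]
    ref_cols = [i for i, c in enumerate(ref) if c != "-"]
    if not ref_cols:
        raise ValueError(f"reference {reference_id!r} is all gaps")
    kept = {}
    for sid, seq in aln.rows.items():
        if sid == reference_id:
            kept[sid] = seq
            continue
        covered = sum(1 for i in ref_cols if seq[i] != "-")
        if covered / len(ref_cols) >= threshold:
            kept[sid] = seq
    return GeneAlignment(aln.gene, kept)


# ---------------------------------------------------------------------------
# Newick

def read_newick(path) -> dendropy.Tree:
    """Read a single Newick tree from a file."""
    text = Path(path).read_text()
    return _tree.parse_newick(text)


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize a tree to Newick; write to *path* if given."""
    text = _tree.to_newick(tree)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# cross-dataset consistency

def check_consistency(records, alignments=(), trees=()) -> None:
    """Fail fast when ids do not match across metadata, alignments and trees.

    Species ids are case-sensitive.  Every alignment row and tree leaf must
    name a metadata record; raises ``ValueError`` naming the offenders.
    """
    known = {r.species_id for r in records}
    problems = []
    for aln in alignments:
        extra = set(aln.rows) - known
        if extra:
            problems.append(
                f"alignment {aln.gene!r}: unknown species {sorted(extra)}"
            )
    for i, tree in enumerate(trees):
        extra = set(_tree.leaf_labels(tree)) - known
        if extra:
            problems.append(f"tree #{i}: unknown species {sorted(extra)}")
    if problems:
        raise ValueError("; ".join(problems))
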