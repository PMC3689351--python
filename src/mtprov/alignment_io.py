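"""Aligned mtDNA sequence input/output and reference-coordinate bookkeeping.

This module is the entry stage of the provenance pipeline.  It reads a
multiple sequence alignment (FASTA) together with a per-sample metadata
table (TSV), validates both, and keeps track of how alignment columns map
onto positions of a reference mitochondrial genome so that windows such as
a short control-region segment can be excised without losing the ability
to translate diagnostic-site coordinates.

Conventions
-----------
* Reference positions are 1-based inclusive; alignment columns are 1-based.
* Sequences are stored uppercase over the alphabet ``{A, C, G, T, -, N}``.
  IUPAC ambiguity codes other than ``N`` are collapsed to ``N`` with a
  logged warning: voucher data commonly contain them and the downstream
  missing-data policy treats all uncertainty uniformly.
* Input alignments are assumed pre-oriented; no reverse-complement
  detection is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STATES = frozenset("ACGT-N")
#: IUPAC nucleotide ambiguity codes that are collapsed to N on load.
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVU")

SPECIES_LABELS = ("savanna", "forest", "hybrid_zone", "unknown")

METADATA_COLUMNS = ("sample_id", "locality", "country", "species")


class AlignmentError(ValueError):
    """Raised for malformed alignments (length mismatch, bad characters)."""


class MetadataError(ValueError):
    """Raised when sequence/metadata bookkeeping is inconsistent."""


class DuplicateSampleError(MetadataError):
    """Raised when a sample id occurs more than once."""


class RangeError(ValueError):
    """Raised when a reference interval falls outside the frame."""


@dataclass(frozen=True)
class AlignedSample:
    """One aligned mtDNA sequence plus its sample metadata."""

    sample_id: str
    sequence: str
    locality: str = ""
    country: str = "unknown"
    species: str = "unknown"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_STATES
        if bad:
            raise AlignmentError(
                f"sample {self.sample_id!r}: invalid characters {sorted(bad)}"
            )
        if self.species not in SPECIES_LABELS:
            raise MetadataError(
                f"sample {self.sample_id!r}: species {self.species!r} not one of "
                f"{SPECIES_LABELS}"
            )


@dataclass(frozen=True)
class ReferenceFrame:
    """Mapping between alignment columns and reference genome positions.

    ``column_to_ref[i]`` gives the 1-based reference position of alignment
    column ``i + 1``, or ``None`` for columns that are gaps relative to the
    reference.  The mapping is monotone non-decreasing over non-gap columns.
    """

    reference_id: str
    ref_start: int
    ref_end: int
    column_to_ref: tuple

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise RangeError("ref_start must be < ref_end")
        positions = [p for p in self.column_to_ref if p is not None]
        if positions != sorted(positions):
            raise RangeError("column_to_ref must be monotone over non-gap columns")

    @classmethod
    def ungapped(cls, reference_id: str, ref_start: int, length: int) -> "ReferenceFrame":
        """Frame for an alignment with no gaps relative to the reference."""
        return cls(
            reference_id=reference_id,
            ref_start=ref_start,
            ref_end=ref_start + length - 1,
            column_to_ref=tuple(range(ref_start, ref_start + length)),
        )

    @classmethod
    def from_gapped_reference(
        cls, reference_id: str, ref_start: int, gapped_reference: str
    ) -> "ReferenceFrame":
        """Frame from the aligned (gapped) copy of the reference sequence."""
        mapping = []
        pos = ref_start
        for ch in gapped_reference:
            if ch == "-":
                mapping.append(None)
            else:
                mapping.append(pos)
                pos += 1
        return cls(reference_id, ref_start, pos - 1, tuple(mapping))

    @property
    def n_columns(self) -> int:
        return len(self.column_to_ref)

    def ref_position(self, column: int):
        """Reference position of a 1-based alignment column (None for gaps)."""
        return self.column_to_ref[column - 1]

    def column_of(self, ref_position: int) -> int:
        """1-based alignment column holding a reference position."""
        try:
            return self.column_to_ref.index(ref_position) + 1
        except ValueError:
            raise RangeError(
                f"reference position {ref_position} not present in frame"
            ) from None

    def columns_for_interval(self, start: int, end: int) -> tuple:
        """1-based inclusive column span covering reference interval [start, end].

        Interior columns that are gaps relative to the reference are included,
        so the span is always contiguous.
        """
        if start > end:
            raise RangeError(f"interval start {start} > end {end}")
        if start < self.ref_start or end > self.ref_end:
            raise RangeError(
                f"interval ({start}, {end}) outside reference frame "
                f"[{self.ref_start}, {self.ref_end}]"
            )
        cols = [
            i + 1
            for i, p in enumerate(self.column_to_ref)
            if p is not None and start <= p <= end
        ]
        return cols[0], cols[-1]

    def subframe(self, col_start: int, col_end: int) -> "ReferenceFrame":
        sub = self.column_to_ref[col_start - 1 : col_end]
        positions = [p for p in sub if p is not None]
        return ReferenceFrame(self.reference_id, positions[0], positions[-1], tuple(sub))


@dataclass(frozen=True)
class SampleTable:
    """Per-sample metadata records plus the locality->country lookup."""

    records: tuple  # of (sample_id, locality, country, species)
    locality_to_country: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen_country: dict = {}
        for _, locality, country, _ in self.records:
            if locality in seen_country and seen_country[locality] != country:
                raise MetadataError(
                    f"locality {locality!r} maps to multiple countries: "
                    f"{seen_country[locality]!r} and {country!r}"
                )
            seen_country[locality] = country

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=list(METADATA_COLUMNS))


@dataclass(frozen=True)
class AlignmentDataset:
    """A validated collection of equal-length :class:`AlignedSample`."""

    samples: tuple
    frame: ReferenceFrame | None = None

    def __post_init__(self) -> None:
        if not self.samples:
            raise AlignmentError("dataset contains no samples")
        length = len(self.samples[0].sequence)
        for s in self.samples:
            if len(s.sequence) != length:
                raise AlignmentError(
                    f"sample {s.sample_id!r} has length {len(s.sequence)}, "
                    f"expected {length}"
                )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateSampleError(f"duplicate sample ids: {dup}")
        if self.frame is not None and self.frame.n_columns != length:
            raise AlignmentError(
                f"reference frame covers {self.frame.n_columns} columns but the "
                f"alignment has {length}"
            )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def length(self) -> int:
        return len(self.samples[0].sequence)

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    def get(self, sample_id: str) -> AlignedSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


def _clean_sequence(sample_id: str, raw: str) -> str:
    seq = raw.upper().replace(".", "-")
    bad = set(seq) - VALID_STATES
    ambiguous = bad & IUPAC_AMBIGUOUS
    if ambiguous:
        logger.warning(
            "sample %s: collapsing IUPAC ambiguity codes %s to N",
            sample_id,
            sorted(ambiguous),
        )
        seq = "".join("N" if c in IUPAC_AMBIGUOUS else c for c in seq)
        bad = set(seq) - VALID_STATES
    if bad:
        raise AlignmentError(f"sample {sample_id!r}: invalid characters {sorted(bad)}")
    return seq


def load_alignment(
    fasta_path, metadata_path, frame: ReferenceFrame | None = None
) -> AlignmentDataset:
    """Read an aligned FASTA plus a metadata TSV into a validated dataset.

    The metadata TSV must have header columns ``sample_id``, ``locality``,
    ``country`` and ``species``; every FASTA record must have a metadata row.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("unknown")
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise MetadataError(f"metadata missing columns: {sorted(missing_cols)}")
    if meta["sample_id"].duplicated().any():
        dup = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"])
        raise DuplicateSampleError(f"duplicate metadata rows for: {dup}")
    by_id = meta.set_index("sample_id")

    samples = []
    for rec in records:
        sid = rec.id
        if sid not in by_id.index:
            raise MetadataError(f"no metadata record for sequence {sid!r}")
        row = by_id.loc[sid]
        samples.append(
            AlignedSample(
                sample_id=sid,
                sequence=_clean_sequence(sid, str(rec.seq)),
                locality=row["locality"],
                country=row["country"],
                species=row["species"],
            )
        )
    return AlignmentDataset(samples=tuple(samples), frame=frame)


def write_dataset(dataset: AlignmentDataset, fasta_path, metadata_path) -> None:
    """Write a dataset back to FASTA + metadata TSV (round-trip exact)."""
    recs = [
        SeqRecord(Seq(s.sequence), id=s.sample_id, description="")
        for s in dataset.samples
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    rows = [
        (s.sample_id, s.locality, s.country, s.species) for s in dataset.samples
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
        metadata_path, sep="\t", index=False
    )


def infer_metadata_from_ids(
    dataset: AlignmentDataset,
    prefix_length: int = 2,
    locality_to_country: Mapping[str, str] | None = None,
    locality_to_species: Mapping[str, str] | None = None,
) -> SampleTable:
    """Derive sample metadata from id prefixes (e.g. ``KR0001`` -> locality KR).

    Locality codes embedded in sequence names are a common deposition
    convention; ``locality_to_country`` supplies the code->country lookup.
    Unknown prefixes yield country/species ``"unknown"`` with a warning —
    the loader is permissive by design and downstream stages may exclude
    unknowns.
    """
    if prefix_length < 1:
        raise ValueError("prefix_length must be >= 1")
    locality_to_country = dict(locality_to_country or {})
    locality_to_species = dict(locality_to_species or {})
    rows = []
    for s in dataset.samples:
        loc = s.sample_id[:prefix_length]
        country = locality_to_country.get(loc)
        if country is None:
            logger.warning("no country lookup for locality prefix %r", loc)
            country = "unknown"
        species = locality_to_species.get(loc, "unknown")
        rows.append((s.sample_id, loc, country, species))
    return SampleTable(records=tuple(rows), locality_to_country=locality_to_country)


def apply_sample_table(dataset: AlignmentDataset, table: SampleTable) -> AlignmentDataset:
    """Return a dataset whose samples carry the metadata from ``table``."""
    by_id = {r[0]: r for r in table.records}
    samples = []
    for s in dataset.samples:
        if s.sample_id not in by_id:
            raise MetadataError(f"no metadata record for sequence {s.sample_id!r}")
        _, loc, country, species = by_id[s.sample_id]
        samples.append(replace(s, locality=loc, country=country, species=species))
    return AlignmentDataset(samples=tuple(samples), frame=dataset.frame)


def extract_region(
    dataset: AlignmentDataset,
    ref_interval: tuple,
    frame: ReferenceFrame | None = None,
) -> AlignmentDataset:
    """Restrict a dataset to the alignment columns covering a reference interval.

    ``ref_interval`` is 1-based inclusive in reference coordinates.  The
    returned dataset carries a subframe so diagnostic-site coordinates remain
    translatable.  Samples with missing data inside the window are retained
    (their Ns are handled by the haplotype missing-data policy downstream).
    """
    frame = frame if frame is not None else dataset.frame
    if frame is None:
        raise RangeError("extract_region requires a reference frame")
    start, end = ref_interval
    col_start, col_end = frame.columns_for_interval(start, end)
    samples = tuple(
        replace(s, sequence=s.sequence[col_start - 1 : col_end])
        for s in dataset.samples
    )
    return AlignmentDataset(samples=samples, frame=frame.subframe(col_start, col_end))
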