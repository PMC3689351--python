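"""Collapse aligned sequences into unique haplotypes and enumerate variable sites.

A *haplotype* is a distinct mtDNA sequence that may be carried by many
individuals; collapsing an alignment into its haplotypes is the substrate
for every downstream statistic (geographic specificity, F_ST, networks).

Identity policy
---------------
Haplotype identity is decided on the variable columns of the alignment:
two sequences are the same haplotype iff they agree at every variable
column.  Gap ``-`` is a fifth character state that never matches a base
(alignments whose raw lengths differ by a few bases imply indels that can
distinguish haplotypes).  ``N`` is missing data, handled by an explicit
policy:

``strict``
    any sequence with N at a variable column is excluded (and reported);
``resolve`` (default)
    a sequence with Ns is merged into an existing haplotype iff exactly
    one haplotype matches it at all of its non-N columns, else excluded.

Haplotype ids are assigned deterministically (descending total count,
then lexicographic sequence) so outputs diff stably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .alignment_io import AlignmentDataset, ReferenceFrame, extract_region

_N = ord("N")

MISSING_POLICIES = ("strict", "resolve")


@dataclass(frozen=True)
class Haplotype:
    """A unique sequence with its carriers and per-unit counts."""

    hap_id: str
    sequence: str
    members: frozenset
    counts_by_locality: Mapping[str, int]
    counts_by_country: Mapping[str, int]

    @property
    def total_count(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HaplotypeTable:
    """All haplotypes of a dataset plus the variable-site inventory."""

    haplotypes: tuple
    variable_sites: tuple  # 1-based alignment columns, ascending
    n_samples_collapsed: int
    n_samples_excluded: int
    excluded: tuple = ()  # of (sample_id, reason)
    frame: ReferenceFrame | None = None
    # per-sample metadata for collapsed members (used for error reporting
    # and per-sample haplotype lookups downstream)
    sample_to_hap: Mapping[str, str] = field(default_factory=dict)
    sample_locality: Mapping[str, str] = field(default_factory=dict)
    sample_country: Mapping[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def get(self, hap_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.hap_id == hap_id:
                return h
        raise KeyError(hap_id)

    def units(self, level: str = "locality") -> list:
        """Sorted list of geographic units observed at the given level."""
        key = _level_key(level)
        out: set = set()
        for h in self.haplotypes:
            out.update(getattr(h, key))
        return sorted(out)

    def counts_frame(self, level: str = "locality") -> pd.DataFrame:
        """Haplotype x unit matrix of individual counts."""
        key = _level_key(level)
        units = self.units(level)
        data = {
            h.hap_id: [getattr(h, key).get(u, 0) for u in units]
            for h in self.haplotypes
        }
        return pd.DataFrame(data, index=units).T.astype(int)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.haplotypes:
            locs = ";".join(
                f"{u}:{c}" for u, c in sorted(h.counts_by_locality.items())
            )
            rows.append((h.hap_id, h.total_count, locs, h.sequence))
        return pd.DataFrame(
            rows, columns=["hap_id", "total_count", "locality_counts", "sequence"]
        )


def _level_key(level: str) -> str:
    if level not in ("locality", "country"):
        raise ValueError(f"level must be 'locality' or 'country', got {level!r}")
    return f"counts_by_{level}"


def _char_matrix(sequences: Iterable[str]) -> np.ndarray:
    return np.array(
        [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in sequences]
    )


def find_variable_sites(dataset) -> list:
    """1-based alignment columns with >= 2 distinct states in {A,C,G,T,-}.

    ``N`` never creates variability.  Accepts an :class:`AlignmentDataset`
    or a plain iterable of equal-length sequences.
    """
    seqs = [s.sequence for s in dataset] if isinstance(dataset, AlignmentDataset) else list(dataset)
    if not seqs:
        return []
    mat = _char_matrix(seqs)
    out = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        states = np.unique(col[col != _N])
        if states.size >= 2:
            out.append(j + 1)
    return out


def collapse_haplotypes(
    dataset: AlignmentDataset, missing_policy: str = "resolve"
) -> HaplotypeTable:
    """Collapse a dataset into its unique haplotypes.

    See the module docstring for the identity and missing-data policy.
    Representative haplotype sequences are full-length, with N at invariant
    columns replaced by the column consensus (the unique non-N state).
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    samples = list(dataset.samples)
    mat = _char_matrix(s.sequence for s in samples)
    n, L = mat.shape

    var_sites = find_variable_sites(dataset)
    var_idx = np.array([c - 1 for c in var_sites], dtype=int)
    proj = mat[:, var_idx] if var_idx.size else np.empty((n, 0), dtype=np.uint8)
    has_missing = (proj == _N).any(axis=1) if var_idx.size else np.zeros(n, bool)

    # group complete sequences by their variable-column projection
    groups: dict = {}
    for i in np.flatnonzero(~has_missing):
        groups.setdefault(proj[i].tobytes(), []).append(i)

    excluded: list = []
    if groups:
        keys = list(groups)
        key_mat = np.array([np.frombuffer(k, dtype=np.uint8) for k in keys])
        if key_mat.size == 0:
            key_mat = key_mat.reshape(len(keys), 0)
    else:
        keys, key_mat = [], np.empty((0, var_idx.size), dtype=np.uint8)

    for i in np.flatnonzero(has_missing):
        row = proj[i]
        known = row != _N
        if missing_policy == "strict" or key_mat.shape[0] == 0:
            excluded.append((samples[i].sample_id, "N at variable column"))
            continue
        matches = np.flatnonzero((key_mat[:, known] == row[known]).all(axis=1))
        if matches.size == 1:
            groups[keys[matches[0]]].append(i)
        else:
            reason = "no matching haplotype" if matches.size == 0 else (
                f"ambiguous: matches {matches.size} haplotypes"
            )
            excluded.append((samples[i].sample_id, reason))

    # column consensus for filling N at invariant columns of representatives
    consensus = np.full(L, _N, dtype=np.uint8)
    for j in range(L):
        col = mat[:, j]
        states = np.unique(col[col != _N])
        if states.size >= 1:
            consensus[j] = states[0]  # invariant columns have exactly one state

    haps = []
    for key, idxs in groups.items():
        # representative: first complete member, consensus-filled at its Ns
        rep_i = idxs[0]
        rep = mat[rep_i].copy()
        missing_pos = rep == _N
        rep[missing_pos] = consensus[missing_pos]
        if var_idx.size:
            rep[var_idx] = np.frombuffer(key, dtype=np.uint8)
        seq = rep.tobytes().decode("ascii")
        members = [samples[i] for i in idxs]
        by_loc: dict = {}
        by_cty: dict = {}
        for s in members:
            by_loc[s.locality] = by_loc.get(s.locality, 0) + 1
            by_cty[s.country] = by_cty.get(s.country, 0) + 1
        haps.append(
            dict(
                sequence=seq,
                members=frozenset(s.sample_id for s in members),
                counts_by_locality=by_loc,
                counts_by_country=by_cty,
            )
        )

    haps.sort(key=lambda h: (-len(h["members"]), h["sequence"]))
    width = max(3, len(str(len(haps))))
    haplotypes = tuple(
        Haplotype(hap_id=f"H{i + 1:0{width}d}", **h) for i, h in enumerate(haps)
    )

    sample_to_hap: dict = {}
    sample_locality: dict = {}
    sample_country: dict = {}
    for h in haplotypes:
        for sid in h.members:
            sample_to_hap[sid] = h.hap_id
    for s in samples:
        if s.sample_id in sample_to_hap:
            sample_locality[s.sample_id] = s.locality
            sample_country[s.sample_id] = s.country

    n_collapsed = sum(h.total_count for h in haplotypes)
    return HaplotypeTable(
        haplotypes=haplotypes,
        variable_sites=tuple(var_sites),
        n_samples_collapsed=n_collapsed,
        n_samples_excluded=len(excluded),
        excluded=tuple(excluded),
        frame=dataset.frame,
        sample_to_hap=sample_to_hap,
        sample_locality=sample_locality,
        sample_country=sample_country,
    )


def haplotype_table_by_region(
    dataset: AlignmentDataset,
    window: tuple,
    missing_policy: str = "resolve",
) -> HaplotypeTable:
    """Haplotype table for a reference window (e.g. a control-region segment).

    Equivalent to collapsing the region-restricted dataset; haplotypes that
    are distinct over the full alignment may merge in a shorter window.
    """
    return collapse_haplotypes(extract_region(dataset, window), missing_policy)


def write_haplotype_table(table: HaplotypeTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_variable_sites(table: HaplotypeTable, path) -> None:
    rows = []
    for col in table.variable_sites:
        ref = table.frame.ref_position(col) if table.frame is not None else ""
        states = sorted(
            {h.sequence[col - 1] for h in table.haplotypes if h.sequence[col - 1] != "N"}
        )
        rows.append((col, ref, "".join(states)))
    pd.DataFrame(rows, columns=["column", "ref_position", "states"]).to_csv(
        path, sep="\t", index=False
    )
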