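"""Hierarchical diagnostic-site key: clade then subclade assignment.

African elephant mtDNA falls into two deep clades (F, which originates in
forest elephants but is carried by many savanna elephants, and S, found
only in savanna elephants), each subdivided into regionally restricted
subclades.  Short sequences — e.g. a control-region fragment amplified
from ivory — can be assigned to a subclade by inspecting a small set of
diagnostic alignment columns, evaluated as a flowchart: clade-level sites
first, then subclade-level sites within the assigned clade.

A site is *fixed* for a split when, in the training data, every child
group is monomorphic at that column; fixed sites may declare conflicts.
Sites that carry between-group information but show within-group
exceptions are retained with ``fixed=False`` and participate only in
plurality voting, never in conflict declaration.  Ties abstain
(``unassigned``) rather than guessing: in a forensic setting a false
assignment is worse than no assignment.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import pandas as pd

from .alignment_io import AlignmentDataset
from .haplotypes import HaplotypeTable

ROOT = "root"

#: the eight canonical subclade labels and their clade membership
DEFAULT_HIERARCHY = {
    "F": (
        "western",
        "west-central",
        "north-central",
        "east-central",
        "south-central",
    ),
    "S": ("northern-savanna", "savanna-wide", "southeast-savanna"),
}


class KeyDerivationError(ValueError):
    """Raised when a diagnostic key cannot be derived from the training data."""


@dataclass(frozen=True)
class DiagnosticSite:
    """One diagnostic alignment column for one split of the hierarchy."""

    column: int  # 1-based alignment column
    level: str  # "clade" | "subclade"
    parent_label: str  # ROOT for clade-level sites, else the clade
    state_map: Mapping[str, str]  # base -> child label (unique-state bases only)
    fixed: bool
    ref_position: int | None = None


@dataclass(frozen=True)
class DiagnosticKey:
    """Hierarchical clade -> subclade decision table of diagnostic columns."""

    hierarchy: Mapping[str, tuple]  # clade -> subclade labels
    sites: tuple  # of DiagnosticSite; clade-level first

    @property
    def clades(self) -> tuple:
        return tuple(sorted(self.hierarchy))

    @property
    def subclades(self) -> tuple:
        return tuple(sc for c in self.clades for sc in self.hierarchy[c])

    def clade_sites(self) -> list:
        return [s for s in self.sites if s.level == "clade"]

    def subclade_sites(self, clade: str) -> list:
        return [
            s for s in self.sites if s.level == "subclade" and s.parent_label == clade
        ]

    def to_json(self, path=None) -> str:
        payload = {
            "hierarchy": {c: list(v) for c, v in self.hierarchy.items()},
            "sites": [
                {**asdict(s), "state_map": dict(s.state_map)} for s in self.sites
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DiagnosticKey":
        if hasattr(source, "read"):
            payload = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        sites = tuple(
            DiagnosticSite(
                column=s["column"],
                level=s["level"],
                parent_label=s["parent_label"],
                state_map=dict(s["state_map"]),
                fixed=bool(s["fixed"]),
                ref_position=s.get("ref_position"),
            )
            for s in payload["sites"]
        )
        hierarchy = {c: tuple(v) for c, v in payload["hierarchy"].items()}
        return cls(hierarchy=hierarchy, sites=sites)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            states = ";".join(f"{b}>{lbl}" for b, lbl in sorted(s.state_map.items()))
            rows.append(
                (s.column, s.ref_position, s.level, s.parent_label, states, s.fixed)
            )
        return pd.DataFrame(
            rows,
            columns=["column", "ref_position", "level", "parent", "state_map", "fixed"],
        )


@dataclass(frozen=True)
class SubcladeAssignment:
    """Outcome of classifying one sequence against a diagnostic key."""

    sample_id: str
    clade: str  # clade label or "unassigned"
    subclade: str  # subclade label, "unassigned" or "conflict"
    n_sites_evaluated: int
    n_sites_missing: int
    votes: Mapping[str, int] = field(default_factory=dict)


def _group_states(sequences: Iterable[str], column: int) -> set:
    out = set()
    for seq in sequences:
        ch = seq[column - 1]
        if ch != "N":
            out.add(ch)
    return out


def _sites_for_split(
    groups: Mapping[str, list],
    columns: Iterable[int],
    level: str,
    parent: str,
    frame,
) -> list:
    """Scan columns for states unique to one child group of a split."""
    sites = []
    for col in columns:
        states_by_group = {g: _group_states(seqs, col) for g, seqs in groups.items()}
        owner: dict = {}
        shared: set = set()
        for g, states in states_by_group.items():
            for st in states:
                if st in owner or st in shared:
                    owner.pop(st, None)
                    shared.add(st)
                else:
                    owner[st] = g
        if not owner:
            continue
        fixed = all(len(states) == 1 for states in states_by_group.values())
        sites.append(
            DiagnosticSite(
                column=col,
                level=level,
                parent_label=parent,
                state_map=dict(sorted(owner.items())),
                fixed=fixed,
                ref_position=frame.ref_position(col) if frame is not None else None,
            )
        )
    return sites


def derive_key(
    training: HaplotypeTable,
    labels: Mapping[str, str],
    hierarchy: Mapping[str, Iterable] | None = None,
) -> DiagnosticKey:
    """Derive a diagnostic key from labeled training haplotypes.

    ``labels`` maps every training ``hap_id`` to its subclade;
    ``hierarchy`` maps each clade to its subclade labels (defaults to the
    canonical two-clade, eight-subclade structure).  Every subclade in the
    hierarchy must have at least one training haplotype.
    """
    hierarchy = {
        c: tuple(v) for c, v in (hierarchy or DEFAULT_HIERARCHY).items()
    }
    clade_of = {sc: c for c, subs in hierarchy.items() for sc in subs}

    unlabeled = [h.hap_id for h in training.haplotypes if h.hap_id not in labels]
    if unlabeled:
        raise KeyDerivationError(f"unlabeled training haplotypes: {unlabeled}")
    unknown = sorted(set(labels.values()) - set(clade_of))
    if unknown:
        raise KeyDerivationError(f"labels outside the hierarchy: {unknown}")

    by_subclade: dict = {sc: [] for sc in clade_of}
    for h in training.haplotypes:
        by_subclade[labels[h.hap_id]].append(h.sequence)
    empty = sorted(sc for sc, seqs in by_subclade.items() if not seqs)
    if empty:
        raise KeyDerivationError(f"no training haplotypes for subclade(s): {empty}")

    columns = list(training.variable_sites)
    frame = training.frame

    clade_groups = {
        c: [seq for sc in subs for seq in by_subclade[sc]]
        for c, subs in hierarchy.items()
    }
    sites = _sites_for_split(clade_groups, columns, "clade", ROOT, frame)
    for clade in sorted(hierarchy):
        subs = hierarchy[clade]
        if len(subs) < 2:
            continue  # degenerate hierarchy: nothing to discriminate within
        groups = {sc: by_subclade[sc] for sc in subs}
        sites.extend(_sites_for_split(groups, columns, "subclade", clade, frame))
    return DiagnosticKey(hierarchy=hierarchy, sites=tuple(sites))


def classify(
    sequence: str,
    key: DiagnosticKey,
    sample_id: str = "",
    column_map: Mapping[int, int] | None = None,
) -> SubcladeAssignment:
    """Assign a sequence to a clade and subclade via the diagnostic key.

    Clade-level sites are evaluated first (majority over non-missing fixed
    sites; ties or zero usable sites abstain and stop).  Within the
    assigned clade, agreement of all usable fixed sites fixes the
    subclade; contradictory fixed sites declare a conflict; with no usable
    fixed site, non-fixed sites vote and a strict plurality is required.
    ``column_map`` translates key columns into coordinates of a windowed
    sequence; sites falling outside the sequence count as missing.
    """

    def state_at(col: int):
        if column_map is not None:
            col = column_map.get(col)
            if col is None:
                return None
        if not 1 <= col <= len(sequence):
            return None
        ch = sequence[col - 1]
        return None if ch == "N" else ch

    n_eval = 0
    n_missing = 0

    clade_votes: Counter = Counter()
    for site in key.clade_sites():
        if not site.fixed:
            continue
        ch = state_at(site.column)
        if ch is None:
            n_missing += 1
            continue
        n_eval += 1
        label = site.state_map.get(ch)
        if label is not None:
            clade_votes[label] += 1
    winners = _plurality(clade_votes)
    if len(winners) != 1:
        return SubcladeAssignment(
            sample_id=sample_id,
            clade="unassigned",
            subclade="unassigned",
            n_sites_evaluated=n_eval,
            n_sites_missing=n_missing,
            votes=dict(clade_votes),
        )
    clade = winners[0]

    fixed_support: Counter = Counter()
    soft_votes: Counter = Counter()
    for site in key.subclade_sites(clade):
        ch = state_at(site.column)
        if ch is None:
            n_missing += 1
            continue
        n_eval += 1
        label = site.state_map.get(ch)
        if label is None:
            continue
        if site.fixed:
            fixed_support[label] += 1
        else:
            soft_votes[label] += 1

    if fixed_support:
        subclade = (
            next(iter(fixed_support)) if len(fixed_support) == 1 else "conflict"
        )
        votes = dict(fixed_support)
    else:
        winners = _plurality(soft_votes)
        subclade = winners[0] if len(winners) == 1 else "unassigned"
        votes = dict(soft_votes)
    return SubcladeAssignment(
        sample_id=sample_id,
        clade=clade,
        subclade=subclade,
        n_sites_evaluated=n_eval,
        n_sites_missing=n_missing,
        votes=votes,
    )


def _plurality(votes: Counter) -> list:
    if not votes:
        return []
    top = max(votes.values())
    return [label for label, v in votes.items() if v == top]


def classify_dataset(
    dataset: AlignmentDataset,
    key: DiagnosticKey,
    column_map: Mapping[int, int] | None = None,
) -> tuple:
    """Classify every sample; returns (assignments, per-locality summary).

    The summary is a locality x subclade count table (the data behind a
    per-locality subclade frequency pie chart).
    """
    assignments = [
        classify(s.sequence, key, sample_id=s.sample_id, column_map=column_map)
        for s in dataset.samples
    ]
    rows = [
        {"locality": s.locality, "subclade": a.subclade}
        for s, a in zip(dataset.samples, assignments)
    ]
    if rows:
        summary = (
            pd.DataFrame(rows)
            .groupby(["locality", "subclade"])
            .size()
            .unstack(fill_value=0)
        )
    else:
        summary = pd.DataFrame()
    return assignments, summary


def flag_species_discordance(
    dataset: AlignmentDataset, assignments: Iterable[SubcladeAssignment]
) -> list:
    """Samples labeled species=forest but carrying S clade mtDNA.

    S clade mtDNA is expected only in savanna elephants (and rare
    hybrids); this validation flags violations without enforcing them.
    """
    by_id = {a.sample_id: a for a in assignments}
    flagged = []
    for s in dataset.samples:
        a = by_id.get(s.sample_id)
        if a is not None and s.species == "forest" and a.clade == "S":
            flagged.append(s.sample_id)
    return flagged
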