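"""Mito-nuclear triangulation of sample provenance.

Nuclear microsatellite assignment and mtDNA phylogeography carry nearly
independent geographic signals in elephants (male-mediated nuclear gene
flow versus matrilocal mtDNA).  Given a table of nuclear assignments
(true locality versus nuclear-assigned locality per sample), this module
asks, for every mis-assigned sample, whether mtDNA evidence would have
helped:

``nuclear_correct``
    the nuclear assignment matches the true locality;
``mtdna_precludes``
    the true and assigned localities share no mtDNA haplotype, so
    sequencing would have ruled the wrong locality out;
``mtdna_distinguishes``
    haplotypes are shared, but the pair shows a significant haplotype
    F_ST (permutation p < alpha), so haplotype frequencies could still
    separate them;
``unresolved``
    none of the above.

Categories are evaluated in that priority order.  The batch scoring
helper extends the same idea to confiscated batches: with several
samples from one source, per-locality haplotype frequencies (and private
haplotypes) sharpen the assignment.  Its likelihood form with add-one
smoothing is this package's own construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .differentiation import FstMatrix
from .geo_specificity import SharingMatrix
from .haplotypes import HaplotypeTable

CATEGORIES = ("nuclear_correct", "mtdna_precludes", "mtdna_distinguishes", "unresolved")

SPECIES_GROUPS = ("forest", "savanna")


class TriangulationError(ValueError):
    """Raised for incomplete inputs (missing matrix pairs, unknown samples)."""


@dataclass(frozen=True)
class AssignmentRecord:
    """One sample's true locality versus its nuclear-assigned locality."""

    sample_id: str
    true_locality: str
    nuclear_assigned_locality: str
    species_group: str

    def __post_init__(self) -> None:
        if self.species_group not in SPECIES_GROUPS:
            raise TriangulationError(
                f"species_group must be one of {SPECIES_GROUPS}, "
                f"got {self.species_group!r}"
            )


@dataclass(frozen=True)
class TriangulationOutcome:
    """Per-sample category plus the mtDNA evidence behind it."""

    sample_id: str
    category: str
    shared_haplotypes: int | None = None
    fst: float | None = None
    p_value: float | None = None


@dataclass(frozen=True)
class TriangulationReport:
    """All outcomes plus category tallies overall and by species group."""

    outcomes: tuple
    counts: Mapping[str, int]
    counts_by_species: pd.DataFrame  # species_group x category
    alpha: float

    @property
    def n_records(self) -> int:
        return len(self.outcomes)

    @property
    def n_misassigned(self) -> int:
        return self.n_records - self.counts.get("nuclear_correct", 0)

    @property
    def improvement_count(self) -> int:
        """Mis-assignments where mtDNA precludes or distinguishes."""
        return self.counts.get("mtdna_precludes", 0) + self.counts.get(
            "mtdna_distinguishes", 0
        )

    @property
    def improvement_fraction(self) -> float:
        mis = self.n_misassigned
        return self.improvement_count / mis if mis else 0.0


def triangulate(
    records: Iterable[AssignmentRecord],
    sharing: SharingMatrix,
    fst: FstMatrix,
    alpha: float = 0.05,
) -> TriangulationReport:
    """Categorize every record by combining nuclear and mtDNA evidence.

    ``alpha`` is the raw permutation p-value threshold for calling a
    locality pair distinguishable by haplotype frequencies (no
    multiple-testing correction by default).
    """
    if not 0 < alpha < 1:
        raise TriangulationError("alpha must be in (0, 1)")
    outcomes = []
    for rec in records:
        a, b = rec.true_locality, rec.nuclear_assigned_locality
        if a == b:
            outcomes.append(
                TriangulationOutcome(sample_id=rec.sample_id, category="nuclear_correct")
            )
            continue
        try:
            shared = sharing.shared(a, b)
        except KeyError as exc:
            raise TriangulationError(
                f"locality pair ({a}, {b}) absent from sharing matrix"
            ) from exc
        if shared == 0:
            outcomes.append(
                TriangulationOutcome(
                    sample_id=rec.sample_id,
                    category="mtdna_precludes",
                    shared_haplotypes=0,
                )
            )
            continue
        try:
            f, p = fst.result(a, b)
        except KeyError as exc:
            raise TriangulationError(
                f"locality pair ({a}, {b}) absent from F_ST matrix"
            ) from exc
        category = "mtdna_distinguishes" if p < alpha else "unresolved"
        outcomes.append(
            TriangulationOutcome(
                sample_id=rec.sample_id,
                category=category,
                shared_haplotypes=shared,
                fst=f,
                p_value=p,
            )
        )

    records = list(records)
    counts = {c: 0 for c in CATEGORIES}
    for o in outcomes:
        counts[o.category] += 1
    rows = [
        {"species_group": r.species_group, "category": o.category}
        for r, o in zip(records, outcomes)
    ]
    if rows:
        by_species = (
            pd.DataFrame(rows)
            .groupby(["species_group", "category"])
            .size()
            .unstack(fill_value=0)
            .reindex(columns=list(CATEGORIES), fill_value=0)
        )
    else:
        by_species = pd.DataFrame(columns=list(CATEGORIES))
    return TriangulationReport(
        outcomes=tuple(outcomes),
        counts=counts,
        counts_by_species=by_species,
        alpha=alpha,
    )


def batch_frequency_support(
    samples: Iterable[str],
    table: HaplotypeTable,
    candidate_units: Iterable[str],
) -> pd.DataFrame:
    """Per-unit log-likelihood score for a batch of samples.

    The score for unit ``u`` is the sum over batch samples of the log of
    the add-one-smoothed frequency of each sample's haplotype in ``u``::

        log p(h | u) = log((n_{u,h} + 1) / (n_u + H))

    with ``H`` the number of haplotypes in the global inventory.  A unit
    is flagged when the batch contains a haplotype private to it — the
    strongest possible locality evidence.
    """
    samples = list(samples)
    candidate_units = list(candidate_units)
    if not samples:
        raise TriangulationError("batch must contain at least one sample")
    if not candidate_units:
        raise TriangulationError("candidate_units must be non-empty")
    missing = [s for s in samples if s not in table.sample_to_hap]
    if missing:
        raise TriangulationError(f"samples absent from haplotype table: {missing}")

    cf = table.counts_frame("locality")
    for u in candidate_units:
        if u not in cf.columns:
            raise TriangulationError(f"unit {u!r} not present in table")
    n_haps = len(table.haplotypes)
    spread = (cf > 0).sum(axis=1)

    rows = []
    for u in candidate_units:
        unit_counts = cf[u]
        n_u = int(unit_counts.sum())
        log_score = 0.0
        private_flag = False
        for sid in samples:
            h = table.sample_to_hap[sid]
            c = int(unit_counts.get(h, 0))
            log_score += math.log((c + 1) / (n_u + n_haps))
            if c > 0 and spread[h] == 1:
                private_flag = True
        rows.append((u, log_score, private_flag))
    return pd.DataFrame(
        rows, columns=["unit", "log_score", "has_private_haplotype"]
    ).set_index("unit")


def read_assignment_records(path) -> list:
    """Load assignment records from a TSV with the standard four columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "true_locality", "assigned_locality", "species_group"}
    missing = required - set(df.columns)
    if missing:
        raise TriangulationError(f"assignment TSV missing columns: {sorted(missing)}")
    return [
        AssignmentRecord(
            sample_id=r.sample_id,
            true_locality=r.true_locality,
            nuclear_assigned_locality=r.assigned_locality,
            species_group=r.species_group,
        )
        for r in df.itertuples()
    ]


def write_assignment_records(records: Iterable[AssignmentRecord], path) -> None:
    pd.DataFrame(
        [
            (r.sample_id, r.true_locality, r.nuclear_assigned_locality, r.species_group)
            for r in records
        ],
        columns=["sample_id", "true_locality", "assigned_locality", "species_group"],
    ).to_csv(path, sep="\t", index=False)
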