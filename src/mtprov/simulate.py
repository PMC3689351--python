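"""Synthetic matrilocal mtDNA datasets with ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: two deep clades (F, S) each split into subclades separated by
fixed diagnostic sites; locality-restricted haplotype pools with a
controlled private-haplotype fraction; skewed (geometric) haplotype
frequencies within each locality; optional missing data; and a nuclear
assignment process whose errors are independent of mtDNA subclade
(mito-nuclear discordance).

Mutations follow an infinite-sites model — every new mutation hits a
previously untouched alignment column — which keeps the planted
diagnostic sites unambiguous for the classifier and makes the generating
diagnostic key exactly recoverable.  Within each locality, haplotype
draw probabilities decay geometrically (ratio ``frequency_skew``),
producing the common-plus-rare mix seen in real haplotype tables.

The private-haplotype fraction is enforced per haplotype slot: with
probability ``private_fraction`` a slot receives a fresh
locality-exclusive haplotype; otherwise its haplotype is also injected
into a second locality of the same subclade region.  Every slot is thus
one distinct haplotype, and the fraction of pool haplotypes restricted
to a single locality is exactly binomial in the configured parameter.

Everything is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .alignment_io import AlignedSample, AlignmentDataset, ReferenceFrame
from .diagnostic_key import DEFAULT_HIERARCHY, DiagnosticKey, DiagnosticSite, ROOT
from .triangulation import AssignmentRecord

BASES = "ACGT"


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the scale of a continental voucher survey: 22
    two-letter localities, ~30 sequenced individuals each, a 4258-column
    alignment, two clades split 5 + 3 into subclades, 72% of each
    locality's haplotype pool private to it, and a nuclear assignment
    process that mis-assigns 45% of samples.
    """

    seed: int = 1
    L: int = 4258
    subclades_per_clade: tuple = (5, 3)
    n_fixed_sites_per_split: int = 3
    n_localities: int = 22
    localities_per_country: int = 2
    samples_per_locality: int = 30
    haplotypes_per_locality: int = 5
    private_fraction: float = 0.72
    within_subclade_mutations: int = 4
    frequency_skew: float = 0.5
    missing_rate: float = 0.0
    nuclear_misassignment_rate: float = 0.45
    locality_region_map: Mapping[str, Mapping[str, float]] | None = None
    ref_start: int = 11_750

    def validate(self) -> None:
        if not 0 <= self.private_fraction <= 1:
            raise SimulationError("private_fraction must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise SimulationError("missing_rate must be in [0, 1)")
        if not 0 <= self.nuclear_misassignment_rate <= 1:
            raise SimulationError("nuclear_misassignment_rate must be in [0, 1]")
        if not 0 < self.frequency_skew <= 1:
            raise SimulationError("frequency_skew must be in (0, 1]")
        if self.n_fixed_sites_per_split < 1:
            raise SimulationError("n_fixed_sites_per_split must be >= 1")
        for name in (
            "L",
            "n_localities",
            "samples_per_locality",
            "haplotypes_per_locality",
            "localities_per_country",
        ):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        if self.within_subclade_mutations < 0:
            raise SimulationError("within_subclade_mutations must be >= 0")
        n_subclades = sum(self.subclades_per_clade)
        n_branches = 2 + n_subclades
        budget = (
            n_branches * self.n_fixed_sites_per_split
            + self.n_localities
            * self.haplotypes_per_locality
            * self.within_subclade_mutations
        )
        if budget > self.L:
            raise SimulationError(
                f"alignment length L={self.L} too short for the infinite-sites "
                f"mutation budget ({budget} columns)"
            )

    def subclade_labels(self) -> Mapping[str, tuple]:
        nf, ns = self.subclades_per_clade
        if (nf, ns) == (5, 3):
            return {c: tuple(v) for c, v in DEFAULT_HIERARCHY.items()}
        return {
            "F": tuple(f"F{i + 1}" for i in range(nf)),
            "S": tuple(f"S{i + 1}" for i in range(ns)),
        }


@dataclass(frozen=True)
class SimHaplotype:
    """One generated haplotype with its placement ground truth."""

    hap_code: str
    sequence: str
    subclade: str
    localities: frozenset
    private: bool


@dataclass(frozen=True)
class SimTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    subclade_of_sample: Mapping[str, str]
    locality_of_sample: Mapping[str, str]
    haplotype_of_sample: Mapping[str, str]
    haplotypes: tuple  # of SimHaplotype
    hierarchy: Mapping[str, tuple]
    key: DiagnosticKey
    locality_species: Mapping[str, str]

    def spread(self, hap_code: str) -> int:
        for h in self.haplotypes:
            if h.hap_code == hap_code:
                return len(h.localities)
        raise KeyError(hap_code)

    def clade_of(self, subclade: str) -> str:
        for clade, subs in self.hierarchy.items():
            if subclade in subs:
                return clade
        raise KeyError(subclade)


def _locality_codes(n: int) -> list:
    codes = []
    for i in range(n):
        codes.append(chr(ord("A") + i // 26) + chr(ord("A") + i % 26))
    return codes


def _default_region_map(localities: list, subclades: list) -> dict:
    """One subclade per locality, cycled, so each subclade spans >= 2
    localities whenever n_localities >= 2 * n_subclades."""
    return {
        loc: {subclades[i % len(subclades)]: 1.0} for i, loc in enumerate(localities)
    }


class _InfiniteSites:
    """Hands out unused alignment columns (0-based) in seeded random order."""

    def __init__(self, L: int, rng: np.random.Generator):
        self._cols = list(rng.permutation(L))

    def take(self, k: int) -> list:
        if k > len(self._cols):
            raise SimulationError("infinite-sites column budget exhausted")
        out = self._cols[:k]
        del self._cols[:k]
        return out


def _mutate(seq: np.ndarray, columns: list, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for c in columns:
        current = chr(out[c])
        out[c] = ord(rng.choice([b for b in BASES if b != current]))
    return out


def simulate_mtdna(config: SimConfig) -> tuple:
    """Generate (dataset, truth) for the configured synthetic study."""
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    hierarchy = config.subclade_labels()
    subclades = [sc for c in sorted(hierarchy) for sc in hierarchy[c]]
    localities = _locality_codes(config.n_localities)
    region_map = (
        {loc: dict(w) for loc, w in config.locality_region_map.items()}
        if config.locality_region_map is not None
        else _default_region_map(localities, subclades)
    )
    if sorted(region_map) != sorted(localities):
        raise SimulationError("locality_region_map must cover every locality")

    sites = _InfiniteSites(config.L, rng)
    base = np.frombuffer(
        "".join(rng.choice(list(BASES), size=config.L)).encode(), dtype=np.uint8
    ).copy()

    # plant fixed diagnostic mutations on every internal branch
    key_sites = []
    clade_seq: dict = {}
    for clade in sorted(hierarchy):
        cols = sites.take(config.n_fixed_sites_per_split)
        clade_seq[clade] = _mutate(base, cols, rng)
        other = [c for c in sorted(hierarchy) if c != clade][0]
        for c in cols:
            key_sites.append(
                DiagnosticSite(
                    column=c + 1,
                    level="clade",
                    parent_label=ROOT,
                    state_map={
                        chr(clade_seq[clade][c]): clade,
                        chr(base[c]): other,
                    },
                    fixed=True,
                    ref_position=config.ref_start + c,
                )
            )
    subclade_seq: dict = {}
    for clade in sorted(hierarchy):
        siblings = hierarchy[clade]
        for sc in siblings:
            cols = sites.take(config.n_fixed_sites_per_split)
            subclade_seq[sc] = _mutate(clade_seq[clade], cols, rng)
            for c in cols:
                state_map = {chr(subclade_seq[sc][c]): sc}
                if len(siblings) == 2:
                    sib = [s for s in siblings if s != sc][0]
                    state_map[chr(clade_seq[clade][c])] = sib
                key_sites.append(
                    DiagnosticSite(
                        column=c + 1,
                        level="subclade",
                        parent_label=clade,
                        state_map=state_map,
                        fixed=True,
                        ref_position=config.ref_start + c,
                    )
                )
    key = DiagnosticKey(hierarchy=hierarchy, sites=tuple(key_sites))

    # decide per-slot privacy, then build pools; shared slots are paired
    # across localities of the same subclade region
    loc_subclade_slots: dict = {loc: [] for loc in localities}
    for loc in localities:
        weights = region_map[loc]
        names = sorted(weights)
        probs = np.array([weights[n] for n in names], dtype=float)
        probs = probs / probs.sum()
        for _ in range(config.haplotypes_per_locality):
            sc = names[rng.choice(len(names), p=probs)]
            loc_subclade_slots[loc].append(sc)

    hap_records: list = []
    pools: dict = {loc: [] for loc in localities}
    hap_counter = [0]

    def new_hap(sc: str, locs: list, private: bool) -> str:
        hap_counter[0] += 1
        code = f"G{hap_counter[0]:04d}"
        cols = sites.take(config.within_subclade_mutations)
        seq = _mutate(subclade_seq[sc], cols, rng)
        hap_records.append(
            SimHaplotype(
                hap_code=code,
                sequence=seq.tobytes().decode("ascii"),
                subclade=sc,
                localities=frozenset(locs),
                private=private,
            )
        )
        for loc in locs:
            pools[loc].append(code)
        return code

    for loc in localities:
        for sc in loc_subclade_slots[loc]:
            if rng.random() < config.private_fraction:
                new_hap(sc, [loc], private=True)
            else:
                # shared slot: the haplotype is also injected into a second
                # locality of the same subclade region, so a shared slot is
                # genuinely multi-locality while every slot remains one
                # distinct haplotype (the pool-level spread-1 fraction is
                # exactly Binomial(private_fraction))
                partners = sorted(
                    l
                    for l in localities
                    if l != loc and region_map[l].get(sc, 0) > 0
                )
                if partners:
                    partner = partners[int(rng.integers(len(partners)))]
                    new_hap(sc, [loc, partner], private=False)
                else:
                    # single-locality region: sharing impossible
                    new_hap(sc, [loc], private=False)

    locality_species: dict = {}
    clade_lookup = {sc: c for c, subs in hierarchy.items() for sc in subs}
    for loc in localities:
        clades_here = {clade_lookup[sc] for sc in region_map[loc] if region_map[loc][sc] > 0}
        if clades_here == {"F"}:
            locality_species[loc] = "forest"
        elif clades_here == {"S"}:
            locality_species[loc] = "savanna"
        else:
            locality_species[loc] = "hybrid_zone"

    country_of = {
        loc: f"C{(i // config.localities_per_country) + 1:02d}"
        for i, loc in enumerate(localities)
    }

    hap_by_code = {h.hap_code: h for h in hap_records}
    samples = []
    subclade_of_sample: dict = {}
    locality_of_sample: dict = {}
    haplotype_of_sample: dict = {}
    for loc in localities:
        pool = list(pools[loc])
        rng.shuffle(pool)
        w = config.frequency_skew ** np.arange(len(pool))
        w = w / w.sum()
        draws = rng.choice(len(pool), size=config.samples_per_locality, p=w)
        for i, d in enumerate(draws):
            code = pool[d]
            hap = hap_by_code[code]
            sid = f"{loc}{i + 1:04d}"
            seq = np.frombuffer(hap.sequence.encode(), dtype=np.uint8).copy()
            if config.missing_rate > 0:
                mask = rng.random(config.L) < config.missing_rate
                seq[mask] = ord("N")
            samples.append(
                AlignedSample(
                    sample_id=sid,
                    sequence=seq.tobytes().decode("ascii"),
                    locality=loc,
                    country=country_of[loc],
                    species=locality_species[loc],
                )
            )
            subclade_of_sample[sid] = hap.subclade
            locality_of_sample[sid] = loc
            haplotype_of_sample[sid] = code

    frame = ReferenceFrame.ungapped("synthetic-ref", config.ref_start, config.L)
    dataset = AlignmentDataset(samples=tuple(samples), frame=frame)
    truth = SimTruth(
        subclade_of_sample=subclade_of_sample,
        locality_of_sample=locality_of_sample,
        haplotype_of_sample=haplotype_of_sample,
        haplotypes=tuple(hap_records),
        hierarchy=hierarchy,
        key=key,
        locality_species=locality_species,
    )
    return dataset, truth


def simulate_nuclear_assignments(config: SimConfig, truth: SimTruth) -> list:
    """Nuclear assignment records whose errors ignore mtDNA subclade.

    Each sample keeps its true locality with probability
    ``1 - nuclear_misassignment_rate``, otherwise it is assigned to a
    uniformly random *other* locality, independent of its mtDNA subclade.
    The species group follows the clade side of the sample's subclade.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 977])
    localities = sorted(set(truth.locality_of_sample.values()))
    records = []
    for sid in truth.locality_of_sample:
        true_loc = truth.locality_of_sample[sid]
        if len(localities) > 1 and rng.random() < config.nuclear_misassignment_rate:
            others = [l for l in localities if l != true_loc]
            assigned = others[int(rng.integers(len(others)))]
        else:
            assigned = true_loc
        clade = truth.clade_of(truth.subclade_of_sample[sid])
        records.append(
            AssignmentRecord(
                sample_id=sid,
                true_locality=true_loc,
                nuclear_assigned_locality=assigned,
                species_group="forest" if clade == "F" else "savanna",
            )
        )
    return records


def truth_hap_labels(truth: SimTruth, table) -> dict:
    """Map collapsed haplotype ids to true subclade labels.

    Convenience for training :func:`mtprov.diagnostic_key.derive_key` on
    synthetic data: each collapsed haplotype inherits the subclade of its
    member samples (which agree by construction).
    """
    labels: dict = {}
    for h in table.haplotypes:
        subs = {truth.subclade_of_sample[sid] for sid in h.members}
        if len(subs) != 1:
            raise SimulationError(
                f"haplotype {h.hap_id} spans multiple true subclades: {sorted(subs)}"
            )
        labels[h.hap_id] = subs.pop()
    return labels
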