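"""Geographic specificity of haplotypes and locality-level haplotype sharing.

Because female elephants are matrilocal, maternally inherited mtDNA
disperses very little: most haplotypes are observed at a single sampling
locality or within a single country.  This module quantifies that
specificity (what fraction of haplotypes — and of individuals carrying
them — are restricted to exactly *k* geographic units) and computes the
locality x locality haplotype-sharing matrix consumed by the
triangulation stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .haplotypes import HaplotypeTable


class SpecificityError(ValueError):
    """Raised when metadata at the requested level is missing."""


_MISSING_VALUES = {None, "", "unknown"}


@dataclass(frozen=True)
class SpecificityReport:
    """Spread-by-k summary of haplotype geographic restriction.

    ``hap_fraction_by_spread[k]`` is the fraction of unique haplotypes
    observed in exactly ``k`` units; ``individual_fraction_by_spread[k]``
    the fraction of individuals carrying such haplotypes.  Fractions are
    kept at full precision; use :func:`render_percent` for the rounded
    whole-percent presentation.
    """

    level: str
    per_haplotype_spread: Mapping[str, int]
    hap_fraction_by_spread: Mapping[int, float]
    individual_fraction_by_spread: Mapping[int, float]
    n_units_with_private: int
    n_haplotypes: int
    n_individuals: int

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.hap_fraction_by_spread)
        return pd.DataFrame(
            {
                "spread": ks,
                "haplotype_fraction": [self.hap_fraction_by_spread[k] for k in ks],
                "individual_fraction": [
                    self.individual_fraction_by_spread[k] for k in ks
                ],
            }
        )


@dataclass(frozen=True)
class SharingMatrix:
    """Symmetric matrix of haplotypes observed in both of two units."""

    units: tuple
    shared_count: pd.DataFrame

    def shared(self, unit_a: str, unit_b: str) -> int:
        try:
            return int(self.shared_count.loc[unit_a, unit_b])
        except KeyError as exc:
            raise KeyError(f"unit pair ({unit_a}, {unit_b}) not in matrix") from exc


def render_percent(fraction: float) -> int:
    """Whole-percent rendering, rounding half away from zero."""
    import math

    value = fraction * 100.0
    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))


def _check_metadata(table: HaplotypeTable, level: str) -> None:
    if level == "country":
        bad = sorted(
            sid
            for sid, c in table.sample_country.items()
            if c in _MISSING_VALUES
        )
        if bad:
            raise SpecificityError(
                f"country metadata missing for samples: {bad}"
            )
    elif level == "locality":
        bad = sorted(
            sid for sid, c in table.sample_locality.items() if c in _MISSING_VALUES
        )
        if bad:
            raise SpecificityError(f"locality metadata missing for samples: {bad}")


def specificity(table: HaplotypeTable, level: str = "locality") -> SpecificityReport:
    """Spread statistics: how many units each haplotype is observed in.

    Individuals excluded during collapsing (missing data) are excluded from
    all denominators; their count is available on the haplotype table.
    """
    _check_metadata(table, level)
    cf = table.counts_frame(level)
    if cf.empty:
        return SpecificityReport(
            level=level,
            per_haplotype_spread={},
            hap_fraction_by_spread={},
            individual_fraction_by_spread={},
            n_units_with_private=0,
            n_haplotypes=0,
            n_individuals=0,
        )
    spread = (cf > 0).sum(axis=1)
    individuals = cf.sum(axis=1)
    n_haps = len(cf)
    n_ind = int(individuals.sum())
    hap_frac = (spread.value_counts() / n_haps).to_dict()
    ind_frac = (individuals.groupby(spread).sum() / n_ind).to_dict()
    private_units = (cf.loc[spread[spread == 1].index] > 0).any(axis=0)
    return SpecificityReport(
        level=level,
        per_haplotype_spread={h: int(k) for h, k in spread.items()},
        hap_fraction_by_spread={int(k): float(v) for k, v in hap_frac.items()},
        individual_fraction_by_spread={int(k): float(v) for k, v in ind_frac.items()},
        n_units_with_private=int(private_units.sum()),
        n_haplotypes=n_haps,
        n_individuals=n_ind,
    )


def sharing_matrix(table: HaplotypeTable, level: str = "locality") -> SharingMatrix:
    """Number of haplotypes observed in both units, for every unit pair.

    The diagonal equals each unit's haplotype count.
    """
    cf = table.counts_frame(level)
    presence = (cf > 0).astype(int)
    shared = presence.T @ presence
    return SharingMatrix(units=tuple(shared.index), shared_count=shared)


def private_haplotype_units(table: HaplotypeTable, level: str = "locality") -> list:
    """Units possessing at least one haplotype found nowhere else (sorted)."""
    if not table.haplotypes:
        return []
    cf = table.counts_frame(level)
    spread = (cf > 0).sum(axis=1)
    private = cf.loc[spread[spread == 1].index]
    return sorted(private.columns[(private > 0).any(axis=0)])
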