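"""Pollen-pool genetics and pollinator-community response variables.

A seed's paternal (pollen) haplotype is obtained per microsatellite
locus by subtracting the maternal genotype from the seed genotype.  The
subtraction is unambiguous except when mother and seed share the same
heterozygous genotype, in which case either allele may be paternal.
Pooled over the maternal plants of a sampling site, the pollen
haplotypes give per-locus allele frequencies from which Nei's gene
diversity (here *haplotype diversity* h) is computed: the probability,
averaged over loci, that the paternal alleles of two randomly chosen
seeds differ.

The pollinator-community response is the proportion of high-mobility
(traplining) hummingbirds among captures, shrunk toward 1/2 by four
pseudo-observations (two successes and two failures) so small samples
stay strictly inside (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class IncompatibleGenotypeError(ValueError):
    """Seed shares no allele with its putative mother at some locus.

    Signals a mislabeled family or a genotyping error.
    """


class EmptyPoolError(ValueError):
    """No pollen haplotypes available for a site."""


class UndefinedDiversityError(ValueError):
    """Fewer than two haplotype contributions at every locus."""


Allele = str
Genotype = tuple[Allele, Allele]  # unordered pair; homozygote = repeated label


@dataclass
class MultilocusGenotype:
    """Diploid genotype over a set of microsatellite loci.

    ``loci`` maps a locus name to an unordered allele pair, or to None
    for missing data.
    """

    individual_id: str
    loci: dict[str, Genotype | None]

    def __post_init__(self) -> None:
        for locus, g in self.loci.items():
            if g is not None and len(g) != 2:
                raise ValueError(f"{self.individual_id}: locus {locus} needs 2 alleles")


# per-locus haplotype states
@dataclass(frozen=True)
class Resolved:
    allele: Allele


@dataclass(frozen=True)
class Ambiguous:
    alleles: frozenset[Allele]  # exactly two candidates


MISSING = None
HaploState = Resolved | Ambiguous | None


@dataclass
class PollenHaplotype:
    """Paternal allelic contribution to one seed, per locus."""

    seed_id: str
    mother_id: str
    loci: dict[str, HaploState]


def _subtract_locus(
    mother: Genotype | None, seed: Genotype | None, on_incompatible: str
) -> HaploState:
    if mother is None or seed is None:
        return MISSING
    mset, sset = set(mother), set(seed)
    novel = sset - mset
    if len(novel) == 1:
        return Resolved(next(iter(novel)))
    if len(novel) >= 2:  # seed carries no maternal allele
        if on_incompatible == "missing":
            return MISSING
        raise IncompatibleGenotypeError(
            f"seed alleles {sorted(sset)} share none with mother {sorted(mset)}"
        )
    # novel empty: seed genotype within the maternal alleles
    if seed[0] == seed[1]:  # homozygote: the paternal allele is forced
        return Resolved(seed[0])
    if len(mset) == 1:
        # mother homozygous AA, seed {A,B} handled above (B novel); here
        # seed {A,A} also handled; unreachable but kept for clarity
        return Resolved(seed[0])
    # mother and seed are the same heterozygote {A,B}
    return Ambiguous(frozenset(seed))


def infer_pollen_haplotype(
    mother: MultilocusGenotype,
    seed: MultilocusGenotype,
    on_incompatible: str = "error",
) -> PollenHaplotype:
    """Subtract the maternal genotype from a seed genotype, locus by locus.

    ``on_incompatible`` is ``"error"`` (default: raise on a locus where
    the seed carries no maternal allele) or ``"missing"`` (treat such a
    locus as missing data).
    """
    if on_incompatible not in ("error", "missing"):
        raise ValueError("on_incompatible must be 'error' or 'missing'")
    if set(mother.loci) != set(seed.loci):
        raise ValueError("mother and seed must share the same locus set")
    loci = {
        locus: _subtract_locus(mother.loci[locus], seed.loci[locus], on_incompatible)
        for locus in mother.loci
    }
    return PollenHaplotype(seed_id=seed.individual_id, mother_id=mother.individual_id, loci=loci)


@dataclass
class PollenPool:
    """Site-level collection of pollen haplotypes with allele frequencies."""

    site_id: str
    haplotypes: list[PollenHaplotype]
    include_ambiguous: bool = True

    def allele_counts(self, locus: str) -> dict[Allele, float]:
        """Weighted allele counts: resolved alleles count 1, each allele
        of an ambiguous pair counts 1/2 (unless ambiguous are excluded)."""
        counts: dict[Allele, float] = {}
        for hap in self.haplotypes:
            state = hap.loci.get(locus)
            if isinstance(state, Resolved):
                counts[state.allele] = counts.get(state.allele, 0.0) + 1.0
            elif isinstance(state, Ambiguous) and self.include_ambiguous:
                for a in state.alleles:
                    counts[a] = counts.get(a, 0.0) + 0.5
        return counts

    def allele_frequencies(self, locus: str) -> dict[Allele, float]:
        counts = self.allele_counts(locus)
        total = sum(counts.values())
        if total == 0:
            return {}
        return {a: c / total for a, c in counts.items()}

    @property
    def loci(self) -> list[str]:
        seen: dict[str, None] = {}
        for hap in self.haplotypes:
            for locus in hap.loci:
                seen.setdefault(locus, None)
        return list(seen)


def pool_pollen(
    haplotypes_by_site: Mapping[str, Iterable[PollenHaplotype]],
    include_ambiguous: bool = True,
) -> dict[str, PollenPool]:
    """One pollen pool per sampling site.

    Sites sampled in several years contribute a single combined pool
    (callers concatenate the years' haplotype lists before grouping).
    """
    pools: dict[str, PollenPool] = {}
    for site_id, haps in haplotypes_by_site.items():
        haps = list(haps)
        if not haps:
            raise EmptyPoolError(f"site {site_id!r} has no pollen haplotypes")
        pools[site_id] = PollenPool(site_id, haps, include_ambiguous)
    return pools


def haplotype_diversity(pool: PollenPool, unbiased: bool = False) -> float:
    """Nei gene diversity of a pollen pool, averaged across loci.

    Per locus, h_L = 1 - sum(p_a^2); h is the arithmetic mean over loci
    with at least two haplotype contributions.  ``unbiased`` applies the
    n/(n-1) small-sample factor per locus.
    """
    h_vals = []
    for locus in pool.loci:
        counts = pool.allele_counts(locus)
        n = sum(counts.values())
        if n < 2:
            continue
        freqs = np.array(list(counts.values())) / n
        h_l = 1.0 - float(np.sum(freqs**2))
        if unbiased:
            h_l *= n / (n - 1.0)
        h_vals.append(h_l)
    if not h_vals:
        raise UndefinedDiversityError(
            f"site {pool.site_id!r}: no locus with >= 2 haplotype contributions"
        )
    return float(np.mean(h_vals))


def proportion_high_mobility(captures: Mapping[str, float]) -> float:
    """Proportion of high-mobility hummingbird captures, shrunk by four
    pseudo-observations: (n_high + 2) / (n_total + 4).

    ``captures`` maps mobility class ('high' / 'low') to a capture
    count.  With no captures the estimate is the prior mean 1/2; it is
    strictly inside (0, 1) for any counts.
    """
    if any(v < 0 for v in captures.values()):
        raise ValueError("capture counts must be non-negative")
    n_high = captures.get("high", 0)
    n_total = sum(captures.values())
    return (n_high + 2.0) / (n_total + 4.0)


def response_table(
    pools: Mapping[str, PollenPool],
    captures_by_site: Mapping[str, Mapping[str, float]] | None = None,
    tm_minus_ts: Mapping[str, float] | None = None,
    unbiased: bool = False,
) -> pd.DataFrame:
    """Assemble the site-level response table.

    Columns: ``site_id``, ``h`` (haplotype diversity),
    ``prop_high_mobility`` (NaN for sites without capture data) and
    ``tm_minus_ts`` (externally estimated biparental inbreeding, passed
    through; NaN when absent).
    """
    rows = []
    for site_id, pool in pools.items():
        row = {"site_id": site_id, "h": haplotype_diversity(pool, unbiased)}
        if captures_by_site is not None and site_id in captures_by_site:
            row["prop_high_mobility"] = proportion_high_mobility(captures_by_site[site_id])
        else:
            row["prop_high_mobility"] = np.nan
        if tm_minus_ts is not None and site_id in tm_minus_ts:
            row["tm_minus_ts"] = tm_minus_ts[site_id]
        else:
            row["tm_minus_ts"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["site_id", "h", "prop_high_mobility", "tm_minus_ts"])
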