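"""Synthetic unbalanced multi-year variety trials with known location groups.

Emulates the shape of a provincial registration/recommendation trial series:
a handful of years, locations drawn from two (or more) latent
mega-environments with some locations skipping some years, and a yearly
genotype roster that only partially overlaps between consecutive years.

Value model. Each genotype g carries one latent merit u_gk per location
group k; the vector (u_g1, ..., u_gK) is multivariate normal with unit
variances and off-diagonal correlation ``rho_between``. The observed trait is

    value(g, loc, year) = mu_loc + s * u_g,group(loc) + e,   e ~ N(0, noise_sd^2)

with the signal scale s = noise_sd_ref * sqrt(rho_within / (1 - rho_within))
calibrated at the reference noise level noise_sd_ref = 1, so that at the
default noise two same-group locations correlate rho_within across genotypes
(and two different-group locations about rho_between * rho_within). Raising
``noise_sd`` above 1 degrades both correlations monotonically, which is the
dial for studying how much unrepeatable interaction the method tolerates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datamodel import TrialRecord, TrialSet
from .errors import DesignError

_REF_NOISE_SD = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Design and signal parameters of the generator.

    Defaults mirror the shape of the motivating five-year oat series: 5
    years, 11 locations in two groups of 5 and 6, 30 genotypes per year with
    40% carried over between consecutive years, within-group genotype-ranking
    correlation 0.6, between-group latent correlation -0.2, and a ~30% chance
    that a location skips a year (at least 2 per group always retained).
    """

    n_years: int = 5
    locations_per_group: Sequence[int] = (5, 6)
    genotypes_per_year: int = 30
    genotype_overlap: float = 0.4
    rho_within: float = 0.6
    rho_between: float = -0.2
    noise_sd: float = 1.0
    location_dropout: float = 0.3
    seed: int = 0
    carryover_policy: str = "top"  # "top" = advance best by latent mean; or "random"

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise DesignError("need at least 2 years")
        if len(self.locations_per_group) < 1 or any(
            n < 2 for n in self.locations_per_group
        ):
            raise DesignError("each group needs at least 2 locations")
        if self.genotypes_per_year < 2:
            raise DesignError("need at least 2 genotypes per year")
        if not 0.0 <= self.genotype_overlap <= 1.0:
            raise DesignError("genotype_overlap must be in [0, 1]")
        if not (0.0 < self.rho_within < 1.0):
            raise DesignError("rho_within must be in (0, 1)")
        if not -1.0 <= self.rho_between <= 1.0:
            raise DesignError("rho_between must be in [-1, 1]")
        if self.noise_sd <= 0:
            raise DesignError("noise_sd must be positive")
        if not 0.0 <= self.location_dropout < 1.0:
            raise DesignError("location_dropout must be in [0, 1)")
        if self.carryover_policy not in ("top", "random"):
            raise DesignError("carryover_policy must be 'top' or 'random'")

    @property
    def signal_sd(self) -> float:
        """Latent signal scale giving rho_within at the reference noise level."""
        return _REF_NOISE_SD * float(
            np.sqrt(self.rho_within / (1.0 - self.rho_within))
        )


@dataclass
class SimResult:
    """Generated trials plus the ground truth the generator knows."""

    trials: TrialSet
    location_groups: dict[str, int]  # location -> 1-based group label
    config: SimConfig
    active_locations: dict[int, list[str]] = field(default_factory=dict)


def _location_names(sizes: Sequence[int]) -> dict[str, int]:
    groups = {}
    for g, n in enumerate(sizes, start=1):
        letter = chr(ord("A") + g - 1)
        for i in range(1, n + 1):
            groups[f"{letter}{i:02d}"] = g
    return groups


def simulate_trials(config: SimConfig) -> SimResult:
    """Generate one reproducible trial series from ``config``.

    Same seed, same output; the design (which locations run in which year,
    which genotypes advance) and all values derive from one generator stream.
    """
    rng = np.random.default_rng(config.seed)
    n_groups = len(config.locations_per_group)
    groups = _location_names(config.locations_per_group)
    locations = sorted(groups)
    mu_loc = {loc: rng.normal(0.0, 1.0) for loc in locations}

    # latent merit vectors, one component per group
    cov = np.full((n_groups, n_groups), config.rho_between, dtype=float)
    np.fill_diagonal(cov, 1.0)
    latents: dict[str, np.ndarray] = {}
    counter = 0

    def new_genotypes(n: int) -> list[str]:
        nonlocal counter
        out = []
        draws = rng.multivariate_normal(np.zeros(n_groups), cov, size=n)
        for row in draws:
            counter += 1
            name = f"G{counter:04d}"
            latents[name] = row
            out.append(name)
        return out

    records: list[TrialRecord] = []
    active_by_year: dict[int, list[str]] = {}
    roster: list[str] = []
    n_keep = int(round(config.genotype_overlap * config.genotypes_per_year))
    for year_idx in range(config.n_years):
        year = 2001 + year_idx
        if year_idx == 0:
            roster = new_genotypes(config.genotypes_per_year)
        else:
            if config.carryover_policy == "top":
                ranked = sorted(roster, key=lambda g: -latents[g].mean())
                kept = ranked[:n_keep]
            else:
                kept = list(rng.choice(roster, size=n_keep, replace=False))
            roster = sorted(kept) + new_genotypes(config.genotypes_per_year - n_keep)

        # location dropout, keeping at least 2 per group
        active: list[str] = []
        for g in range(1, n_groups + 1):
            members = [loc for loc in locations if groups[loc] == g]
            drop = rng.random(len(members)) < config.location_dropout
            retained = [loc for loc, d in zip(members, drop) if not d]
            if len(retained) < 2:
                dropped = [loc for loc, d in zip(members, drop) if d]
                extra = rng.choice(dropped, size=2 - len(retained), replace=False)
                retained = sorted(retained + list(extra))
            active.extend(retained)
        if len(active) < 2:
            raise DesignError(f"year {year}: fewer than 2 active locations")
        active_by_year[year] = sorted(active)

        s = config.signal_sd
        for loc in active_by_year[year]:
            k = groups[loc] - 1
            noise = rng.normal(0.0, config.noise_sd, size=len(roster))
            for genotype, e in zip(roster, noise):
                value = mu_loc[loc] + s * latents[genotype][k] + e
                records.append(TrialRecord(genotype, loc, year, float(value)))

    return SimResult(
        trials=TrialSet(records, trait_name="yield"),
        location_groups=groups,
        config=config,
        active_locations=active_by_year,
    )


def write_truth_labels(result: SimResult, path) -> None:
    """Write the location -> group truth table as CSV."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["location", "group"])
        for loc in sorted(result.location_groups):
            writer.writerow([loc, result.location_groups[loc]])
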