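"""Scenario engine: rotation clear-cuts, Reineke thinning, replanting rules,
and the historical age-structure initialisation.

Management options change which species are replanted after any death:
``base`` replants the pre-death PFT, ``toNE``/``toBD``/``toBE`` force a single
PFT, and ``unmanaged`` stops all management at the start year.  Clear-cuts are
synchronised across managed options; trees are replanted with a one-year lag
unless the death was a clear-cut, in which case replanting is immediate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ConfigError, ScenarioConfig
from .params import PFT_GROUP, PFTParams, ThinningParams, VegParams
from .vegetation import Patch


def schedule_clearcut(year: int, cfg: ScenarioConfig) -> bool:
    """True iff a synchronised clear-cut falls in ``year``.

    Clear-cuts occur at the management start and every ``rotation`` years
    thereafter, in the same years for all managed options; the unmanaged
    option never cuts after the start.
    """
    if year < 0:
        raise ValueError("year must be >= 0")
    if not (cfg.managed and cfg.clearcut_enabled):
        return False
    offset = year - cfg.management_start
    return offset >= 0 and offset % cfg.rotation == 0


@dataclass
class Felled:
    """Biomass removed from the live pools by one harvest event."""

    wood: float = 0.0
    leaf: float = 0.0
    froot: float = 0.0

    @property
    def total(self) -> float:
        return self.wood + self.leaf + self.froot


def fell_patch(patch: Patch) -> Felled:
    """Clear-cut: fell every cohort in the patch."""
    f = Felled()
    for coh in patch.cohorts:
        f.wood += coh.c_stem
        f.leaf += coh.c_leaf
        f.froot += coh.c_froot
    patch.cohorts.clear()
    return f


def patch_density_diameter(patch: Patch, veg: VegParams) -> tuple[float, float]:
    """Total stem density (m-2) and quadratic-mean diameter (cm) of a patch."""
    density = sum(c.density for c in patch.cohorts)
    if density <= 0:
        return 0.0, 0.0
    d2 = sum(c.density * c.diameter_cm(veg) ** 2 for c in patch.cohorts)
    return density, math.sqrt(d2 / density)


def reineke_thin(patch: Patch, thin_params: dict[str, ThinningParams],
                 pfts: dict[str, PFTParams], veg: VegParams) -> Felled:
    """Thin a managed patch down to the Reineke maximum-density line.

    N_max = k (D / D_ref)^-a with the broadleaf k below the conifer k, so
    broadleaved stands reach the trigger at lower densities.  When density
    exceeds ``trigger_frac x N_max``, stems are removed proportionally across
    cohorts down to ``target_frac x N_max`` and routed to harvest
    partitioning.
    """
    density, qmd = patch_density_diameter(patch, veg)
    if density <= 0:
        return Felled()
    if qmd <= 0:
        raise ValueError("positive density with nonpositive mean diameter")
    # parameter group of the dominant (highest basal-area share) cohort
    dom = max(patch.cohorts, key=lambda c: c.density * c.diameter_cm(veg) ** 2)
    tp = thin_params[PFT_GROUP[dom.pft]]
    n_max = tp.k_density * 1e-4 * (qmd / tp.d_ref_cm) ** (-tp.exponent)
    if density <= tp.trigger_frac * n_max:
        return Felled()
    frac = 1.0 - (tp.target_frac * n_max) / density
    frac = min(max(frac, 0.0), 1.0)
    f = Felled()
    for coh in patch.cohorts:
        f.wood += frac * coh.c_stem
        f.leaf += frac * coh.c_leaf
        f.froot += frac * coh.c_froot
        coh.c_stem *= (1.0 - frac)
        coh.c_leaf *= (1.0 - frac)
        coh.c_froot *= (1.0 - frac)
        coh.density *= (1.0 - frac)
    return f


def replant_pft(scenario: str, previous_pft: str | None,
                default_pft: str) -> str:
    """Species planted after a death, by management option.

    Before the management start the unmanaged option is initialised exactly
    like the baseline, so it shares the identity-replant rule here; after the
    start its patches regenerate naturally and this rule is never consulted.
    """
    if scenario in ("base", "unmanaged"):
        return previous_pft or default_pft
    if scenario == "toNE":
        return "NE"
    if scenario == "toBD":
        return "BD"
    if scenario == "toBE":
        return "BE"
    raise ConfigError(f"no replanting rule for scenario {scenario!r}")


def replant_year(event_year: int, cause: str, cfg: ScenarioConfig) -> int:
    """Clear-cut deaths replant the same year; any other death after a lag."""
    if cause == "clearcut":
        return event_year
    return event_year + cfg.replant_lag


@dataclass(frozen=True)
class AgeStructurePlan:
    """Wave schedule realising a target age histogram at the start year.

    ``conversion_year[i]`` gives the simulation year in which analysis patch
    ``i`` is first clear-cut and becomes managed; ``n_pristine`` patches (the
    >140-yr fraction) are never converted.
    """

    conversion_year: tuple[int, ...]
    n_pristine: int
    wave_years: tuple[int, ...]


def init_age_structure(n_patches: int, target_hist, management_start: int,
                       seed: int | np.random.Generator = 0,
                       init_years: int = 140) -> AgeStructurePlan:
    """Allocate patches to 10-yr clear-cut waves matching a target histogram.

    ``target_hist`` has one weight per 10-yr age bin (youngest first) plus a
    final >140-yr pristine bin; it must sum to 1.  Starting from all-pristine,
    waves every 10 years over the ``init_years`` before ``management_start``
    convert patch quanta so the realised age histogram at the start matches
    the target within one patch.  Largest-remainder apportionment; remainders
    are broken by the seeded stream for determinism.
    """
    hist = np.asarray(target_hist, dtype=float)
    if hist.ndim != 1 or hist.size < 2:
        raise ConfigError("target histogram needs age bins plus a pristine bin")
    if np.any(hist < 0) or abs(hist.sum() - 1.0) > 1e-9:
        raise ConfigError("target histogram must be nonnegative and sum to 1")
    n_bins = hist.size - 1
    n_waves = init_years // 10
    if n_bins > n_waves:
        raise ConfigError(
            f"target needs {n_bins} waves but only {n_waves} fit in "
            f"{init_years} initialisation years")

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(np.random.SeedSequence([int(seed), 37])))
    quota = hist * n_patches
    counts = np.floor(quota).astype(int)
    short = n_patches - counts.sum()
    if short > 0:
        remainders = quota - counts
        # deterministic tie-break: noise far below remainder resolution
        order = np.argsort(-(remainders + 1e-9 * rng.random(hist.size)))
        counts[order[:short]] += 1

    # age bin b (ages [10b, 10(b+1))) was converted 10b + 9 years before start
    conv: list[int] = []
    waves: set[int] = set()
    for b in range(n_bins):
        year = management_start - (10 * b + 9)
        for _ in range(counts[b]):
            conv.append(year)
            waves.add(year)
    return AgeStructurePlan(
        conversion_year=tuple(sorted(conv)),
        n_pristine=int(counts[n_bins]),
        wave_years=tuple(sorted(waves)))


def natural_regen_pft(patch_last_pft: str | None, cell_default: str,
                      viable: list[str]) -> str | None:
    """PFT that regenerates naturally in an unmanaged patch.

    Prefers the patch's previous species, then the cell's initial dominant,
    then the first locally viable PFT in a fixed order; None when nothing is
    viable.
    """
    for cand in (patch_last_pft, cell_default, "NE", "BD", "ND", "BE"):
        if cand is not None and cand in viable:
            return cand
    return None
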