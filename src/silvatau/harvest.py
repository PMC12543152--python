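"""Harvest partitioning and the wood product pool.

When trees are felled, 66% of wood biomass (stem, branches and coarse roots)
and 30% of leaf biomass are removed from the stand; the rest stays as litter.
All removed leaf carbon and 67% of removed wood carbon oxidise to the
atmosphere in the harvest year; the remaining 33% of removed wood enters a
product pool outside the ecosystem that oxidises at 4% per year.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import (LEAF_REMOVAL_FRAC, PRODUCT_OXIDATION_RATE,
                     WOOD_OXIDISED_FRAC, WOOD_REMOVAL_FRAC)


@dataclass
class HarvestSplit:
    """Fate of one felling event (all kgC m-2)."""

    removed_wood: float
    removed_leaf: float
    residue_wood: float   # stays in the stand as coarse/fine woody debris
    residue_leaf: float
    residue_froot: float  # fine roots are never removed

    @property
    def residue_total(self) -> float:
        return self.residue_wood + self.residue_leaf + self.residue_froot


def partition_harvest(felled_wood: float, felled_leaf: float,
                      felled_froot: float = 0.0,
                      wood_removal: float = WOOD_REMOVAL_FRAC,
                      leaf_removal: float = LEAF_REMOVAL_FRAC) -> HarvestSplit:
    """Split felled biomass into removals and in-stand residues."""
    if felled_wood < 0 or felled_leaf < 0 or felled_froot < 0:
        raise ValueError("felled biomass must be nonnegative")
    return HarvestSplit(
        removed_wood=wood_removal * felled_wood,
        removed_leaf=leaf_removal * felled_leaf,
        residue_wood=(1.0 - wood_removal) * felled_wood,
        residue_leaf=(1.0 - leaf_removal) * felled_leaf,
        residue_froot=felled_froot,
    )


def route_removals(removed_wood: float, removed_leaf: float,
                   wood_oxidised: float = WOOD_OXIDISED_FRAC
                   ) -> tuple[float, float]:
    """Split stand removals into (same-year atmospheric flux, product input)."""
    if removed_wood < 0 or removed_leaf < 0:
        raise ValueError("removals must be nonnegative")
    to_atm = removed_leaf + wood_oxidised * removed_wood
    to_products = (1.0 - wood_oxidised) * removed_wood
    return to_atm, to_products


@dataclass
class ProductPool:
    """Harvested-wood carbon stored outside the ecosystem.

    The pool oxidises before receiving the year's input (convention choice;
    at annual stepping the alternative ordering differs only in the fourth
    decimal of the pool trajectory).
    """

    carbon: float = 0.0
    oxidation_rate: float = PRODUCT_OXIDATION_RATE

    def step(self, input_c: float = 0.0) -> float:
        """Advance one year; returns the oxidation flux."""
        if input_c < 0:
            raise ValueError("product input must be nonnegative")
        flux = self.oxidation_rate * self.carbon
        self.carbon = self.carbon - flux + input_c
        return flux


def step_product_pool(pool: float, input_c: float,
                      rate: float = PRODUCT_OXIDATION_RATE
                      ) -> tuple[float, float]:
    """Functional form of :meth:`ProductPool.step`: (new pool, oxidation)."""
    if pool < 0 or input_c < 0:
        raise ValueError("pool and input must be nonnegative")
    flux = rate * pool
    return pool - flux + input_c, flux
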