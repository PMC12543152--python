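"""Annual pool/flux ledger for one stand run.

Every carbon flux entering the turnover-time arithmetic is recorded per
simulation year, on a per-m2 basis over the analysed patch set.  Stocks are
end-of-year states.  The ledger is the single source of truth for the tau
calculations and the conservation checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import SOIL_POOLS

FLUX_FIELDS = (
    "gpp", "fra", "npp", "frh", "fdoc",
    "ffire", "ffire_stem", "ffire_litter",
    "fmort", "fdist",
    "fharv_total", "fharv_stem",
    "fharv_to_products", "fharv_to_atm", "fharv_to_litter",
    "product_oxidation", "litter_input",
)
STOCK_FIELDS = (
    "c_leaf", "c_froot", "c_stem", "c_soil", "c_eco", "c_products", "height",
)
POOL_FIELDS = tuple(f"pool_{p}" for p in SOIL_POOLS)
OUT_FIELDS = tuple(f"out_{p}" for p in SOIL_POOLS)
ALL_FIELDS = FLUX_FIELDS + STOCK_FIELDS + POOL_FIELDS + OUT_FIELDS


@dataclass
class StandLedger:
    """Column store of annual stand accounting (kgC m-2 and kgC m-2 yr-1)."""

    n_years: int
    cell_id: int = 0
    scenario: str = "base"
    mode: str = "fixed"
    zone: str = ""
    data: dict[str, np.ndarray] = field(default_factory=dict)
    accel_years: tuple[int, ...] = ()   # years with a soil spin-up reset

    def __post_init__(self):
        if not self.data:
            self.data = {f: np.zeros(self.n_years) for f in ALL_FIELDS}

    def __getitem__(self, key: str) -> np.ndarray:
        return self.data[key]

    @property
    def fturn_eco(self) -> np.ndarray:
        """Ecosystem outflow: FRa + FRh + FDOC + Ffire + harvest exports."""
        d = self.data
        return (d["fra"] + d["frh"] + d["fdoc"] + d["ffire"]
                + d["fharv_to_products"] + d["fharv_to_atm"])

    @property
    def fturn_stem(self) -> np.ndarray:
        """Stem outflow: mortality + disturbance + stem combustion + felling."""
        d = self.data
        return d["fmort"] + d["fdist"] + d["ffire_stem"] + d["fharv_stem"]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data)
        df.insert(0, "year", np.arange(self.n_years))
        df.insert(0, "scenario", self.scenario)
        df.insert(0, "cell", self.cell_id)
        return df
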