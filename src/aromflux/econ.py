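"""Breakeven-titer substrate requirements and product ranking.

For a candidate bioproduct with breakeven titer T (g/L), molar mass Mp
(g/mol) and molar yield Y (mol product per mol substrate), the substrate
concentration needed to reach the breakeven titer is

    C_substrate = (T / Mp) / Y * Ms          [g/L]

where Ms is the substrate's molar mass. Products are ranked by this
requirement: the lower the substrate demand, the more attractive the
product at its breakeven point.

Yields are carried on a mol/mol basis by default. A carbon-basis option
converts mol-C/mol-C yields through the formula carbon counts; note that
published yield tables labeled per-carbon are not always arithmetically
consistent with that label, so the basis is explicit here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: neutral free-acid/free-base molar masses (g/mol) and carbon counts
REFERENCE_COMPOUNDS = {
    "glutarate": (132.12, 5),
    "zeaxanthin": (568.87, 40),
    "cis-cis muconic acid": (142.11, 6),
    "acetaldehyde": (44.05, 2),
    "glycerol": (92.09, 3),
    "citrate": (192.12, 6),
    "1-hexadecanol": (242.44, 16),
    "butanoate": (88.11, 4),
    "urea": (60.06, 1),
    "phenol": (94.11, 6),
    "propanoate": (74.08, 3),
    "acetate": (60.05, 2),
    "ethanolamine": (61.08, 2),
    "vanillic acid": (168.15, 8),
    "glucose": (180.16, 6),
    "2-pyrone-4,6-dicarboxylic acid": (184.10, 7),
}


class EconError(ValueError):
    pass


@dataclass
class ProductEconRecord:
    product: str
    value_usd_per_kg: float
    breakeven_titer_g_L: float
    molar_yield: float  # mol product per mol substrate
    product_molar_mass: float  # g/mol
    substrate_molar_mass: float = 168.15  # vanillic acid by default
    production_rate_g_L_h: float | None = None

    def validate(self) -> None:
        for name in ("breakeven_titer_g_L", "product_molar_mass",
                     "substrate_molar_mass"):
            if getattr(self, name) <= 0:
                raise EconError(f"{self.product}: {name} must be > 0")
        if self.molar_yield < 0:
            raise EconError(f"{self.product}: molar yield must be >= 0")


def breakeven_substrate_concentration(record: ProductEconRecord) -> float:
    """g/L of substrate needed to reach the product's breakeven titer.

    A zero yield gives an infinite requirement (the product cannot be
    reached at any substrate load).
    """
    record.validate()
    if record.molar_yield == 0:
        return math.inf
    mol_product = record.breakeven_titer_g_L / record.product_molar_mass
    return mol_product / record.molar_yield * record.substrate_molar_mass


def carbon_to_molar_yield(yield_per_carbon: float, product_carbons: int,
                          substrate_carbons: int) -> float:
    """Convert a mol-C/mol-C yield to mol/mol through carbon counts."""
    if product_carbons <= 0 or substrate_carbons <= 0:
        raise EconError("carbon counts must be positive")
    return yield_per_carbon * substrate_carbons / product_carbons


def rank_products(records) -> list[tuple[ProductEconRecord, float]]:
    """Sort records ascending by required substrate concentration.

    Ties break by product name for a stable, reproducible report.
    """
    if not records:
        raise EconError("no records to rank")
    scored = [(r, breakeven_substrate_concentration(r)) for r in records]
    return sorted(scored, key=lambda x: (x[1], x[0].product))


def read_econ_csv(path, substrate_molar_mass: float = 168.15):
    """CSV columns: product, value_usd_per_kg, breakeven_titer_g_L,
    molar_yield, rate_g_L_h (optional), product_molar_mass (optional,
    falls back to the reference table)."""
    import pandas as pd

    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        mw = row.get("product_molar_mass")
        if mw is None or pd.isna(mw):
            try:
                mw = REFERENCE_COMPOUNDS[row["product"]][0]
            except KeyError as exc:
                raise EconError(
                    f"no molar mass for {row['product']!r}; add a "
                    f"product_molar_mass column") from exc
        rate = row.get("rate_g_L_h")
        records.append(ProductEconRecord(
            product=row["product"],
            value_usd_per_kg=float(row["value_usd_per_kg"]),
            breakeven_titer_g_L=float(row["breakeven_titer_g_L"]),
            molar_yield=float(row["molar_yield"]),
            product_molar_mass=float(mw),
            substrate_molar_mass=substrate_molar_mass,
            production_rate_g_L_h=None if rate is None or pd.isna(rate)
            else float(rate),
        ))
    return records


def write_ranked_csv(records, path, printed: bool = False) -> None:
    """Ranked report CSV; ``printed=True`` rounds requirements to integers."""
    import pandas as pd

    rows = []
    for rank, (rec, req) in enumerate(rank_products(records), start=1):
        rows.append({
            "rank": rank,
            "product": rec.product,
            "value_usd_per_kg": rec.value_usd_per_kg,
            "breakeven_titer_g_L": rec.breakeven_titer_g_L,
            "molar_yield": rec.molar_yield,
            "rate_g_L_h": rec.production_rate_g_L_h,
            "required_substrate_g_L": round(req) if printed and math.isfinite(req)
            else req,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
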