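"""Concentration-dependent maximum uptake rates for exchange reactions.

The uptake bound for a substrate at extracellular concentration S
(mmol/L) follows substrate-inhibited Monod kinetics:

    rate(S) = Vmax * S / (S + Ks) * 1 / (1 + S / Ki)

with Vmax in mmol/gDW/h, and Ks, Ki in mmol/L. When no inhibition
constant is known, Ki defaults to Ks (delayed growth in the presence of
aromatics motivates keeping the inhibition term on by default). The rate
is zero at S = 0, peaks at S = sqrt(Ks * Ki), and decays toward zero as
S grows; it never reaches Vmax.

Parameters are carried per substrate exchange with a substrate-class
fallback (non-aromatic, G-type, S-type, H-type): an unparameterized
exchange inherits its class row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

SUBSTRATE_CLASSES = ("non-aromatic", "G-type", "S-type", "H-type")


class KineticsConfigError(ValueError):
    pass


@dataclass(frozen=True)
class KineticParams:
    substrate: str  # exchange reaction id, or a class name for fallback rows
    Vmax: float  # mmol/gDW/h
    Ks: float  # mmol/L
    Ki: float | None = None  # mmol/L; None -> Ks
    substrate_class: str | None = None

    def __post_init__(self):
        if self.Vmax <= 0:
            raise KineticsConfigError(f"{self.substrate}: Vmax must be > 0")
        if self.Ks <= 0:
            raise KineticsConfigError(f"{self.substrate}: Ks must be > 0")
        if self.Ki is None:
            object.__setattr__(self, "Ki", self.Ks)
        if self.Ki <= 0:
            raise KineticsConfigError(f"{self.substrate}: Ki must be > 0")
        if self.substrate_class is not None and self.substrate_class not in SUBSTRATE_CLASSES:
            raise KineticsConfigError(
                f"{self.substrate}: unknown substrate class {self.substrate_class!r}"
            )

    @property
    def peak_concentration(self) -> float:
        """Concentration maximizing the uptake rate: sqrt(Ks*Ki)."""
        return math.sqrt(self.Ks * self.Ki)


def uptake_rate(S: float, params: KineticParams) -> float:
    """Maximum allowed specific uptake rate (mmol/gDW/h) at concentration S."""
    if S < 0:
        raise ValueError(f"negative substrate concentration {S}")
    if S == 0:
        return 0.0
    return params.Vmax * S / (S + params.Ks) / (1.0 + S / params.Ki)


class ParamTable:
    """Per-substrate kinetic parameters with substrate-class fallback."""

    def __init__(self, rows=()):
        self.by_substrate: dict[str, KineticParams] = {}
        self.by_class: dict[str, KineticParams] = {}
        for row in rows:
            self.add(row)

    def add(self, params: KineticParams) -> None:
        if params.substrate in SUBSTRATE_CLASSES:
            self.by_class[params.substrate] = params
        else:
            self.by_substrate[params.substrate] = params

    def lookup(self, substrate: str, substrate_class: str | None = None) -> KineticParams:
        if substrate in self.by_substrate:
            return self.by_substrate[substrate]
        cls = substrate_class
        if cls is None:
            cls = getattr(self.by_substrate.get(substrate), "substrate_class", None)
        if cls is not None and cls in self.by_class:
            return self.by_class[cls]
        raise KineticsConfigError(
            f"no kinetic parameters for {substrate!r} and no class fallback"
        )

    # TSV columns: substrate_id, class, Vmax, Ks, Ki (blank Ki -> Ks)
    @classmethod
    def read_tsv(cls, path) -> "ParamTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        required = {"substrate_id", "class", "Vmax", "Ks", "Ki"}
        missing = required - set(df.columns)
        if missing:
            raise KineticsConfigError(f"kinetics TSV missing columns {sorted(missing)}")
        table = cls()
        for _, row in df.iterrows():
            ki = row["Ki"]
            subst_cls = row["class"] if isinstance(row["class"], str) else None
            table.add(KineticParams(
                substrate=row["substrate_id"],
                Vmax=float(row["Vmax"]), Ks=float(row["Ks"]),
                Ki=None if pd.isna(ki) else float(ki),
                substrate_class=subst_cls,
            ))
        return table

    def write_tsv(self, path) -> None:
        import pandas as pd

        rows = []
        for p in list(self.by_substrate.values()) + list(self.by_class.values()):
            rows.append((p.substrate, p.substrate_class, p.Vmax, p.Ks, p.Ki))
        pd.DataFrame(
            rows, columns=["substrate_id", "class", "Vmax", "Ks", "Ki"]
        ).to_csv(path, sep="\t", index=False)


def uptake_bounds(
    concentrations: dict[str, float],
    table: ParamTable,
    classes: dict[str, str] | None = None,
) -> dict[str, tuple]:
    """Per-exchange (lb, ub) tuples implementing the kinetic uptake caps.

    Substrates at S = 0 are closed to uptake (lb = 0); secretion is left
    to the structural bounds (ub = None).
    """
    bounds = {}
    for rid, S in concentrations.items():
        params = table.lookup(rid, (classes or {}).get(rid))
        rate = uptake_rate(S, params)
        bounds[rid] = (-rate, None)
    return bounds


def apply_uptake_bounds(
    model,
    concentrations: dict[str, float],
    table: ParamTable,
    classes: dict[str, str] | None = None,
):
    """Return a model copy whose substrate exchanges carry kinetic bounds."""
    for rid in concentrations:
        if rid not in model.reactions:
            raise KeyError(f"unknown exchange {rid}")
    out = model.copy()
    for rid, (lb, _) in uptake_bounds(concentrations, table, classes).items():
        rxn = out.reactions[rid]
        rxn.lower_bound = lb
    return out
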