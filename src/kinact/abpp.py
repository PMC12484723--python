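"""Single-dose competition ratios to K_I via warhead-class k_inact priors.

Competitive cysteine-profiling screens report one competition ratio (CR,
DMSO over treated orientation) per fragment-site pair at a single dose and
time — too little to fit both kinetic parameters. Assuming fragments sharing
a warhead class share intrinsic reactivity, a class-median k_inact prior
closes the system:

    occupancy = 1 - 1/CR
    k_obs     = -ln(1 - occupancy)/t
    K_I       = k_inact [I]/k_obs - [I]

The shipped class medians (chloroacetamide 0.0092 s^-1, acrylamide
0.0025 s^-1, curated from public covalent-inhibitor kinetics databases) are
constants, not recomputed here. When the implied k_obs reaches k_inact the
algebra gives K_I <= 0: the site reacts as fast as the warhead possibly can,
so only the bound K_I <= [I] is reportable ("reactivity-limited").

The converted K_I feeds two medicinal-chemistry quality metrics:
ligand efficiency LE = -RT ln(K_I)/N (kcal mol^-1 per heavy atom; positive
for sub-molar binders) and lipophilic ligand efficiency
LLE = -log10(K_I) - clogP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FragmentRecord",
    "ConversionConstants",
    "WARHEAD_KINACT",
    "cr_to_occupancy",
    "occupancy_to_kobs",
    "kobs_to_ki",
    "ligand_efficiency",
    "lipophilic_efficiency",
    "clogp_from_structure",
    "convert_table",
]

# class-median covalent bond-formation rates by warhead chemistry (s^-1)
WARHEAD_KINACT = {
    "chloroacetamide": 0.0092,
    "acrylamide": 0.0025,
}


@dataclass(frozen=True)
class ConversionConstants:
    """Screen conditions and thermodynamic constants for the conversion.

    t: incubation time (s); I: fragment dose (M); R in kcal mol^-1 K^-1;
    T in K. Defaults are the standard single-dose cysteine-screen conditions
    (2 h at 25 uM) and room temperature.
    """

    t: float = 7200.0
    I: float = 2.5e-5
    R: float = 1.987e-3
    T: float = 298.15

    def __post_init__(self) -> None:
        for name in ("t", "I", "R", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class FragmentRecord:
    """One fragment-site competition observation with fragment metadata."""

    fragment: str
    analyte: str
    cr: float
    warhead: str = "custom"
    k_inact: Optional[float] = None  # required when warhead == "custom"
    heavy_atoms: Optional[int] = None
    clogp: Optional[float] = None
    structure: Optional[str] = None  # SMILES, used only if clogp is absent

    def __post_init__(self) -> None:
        if self.cr <= 0:
            raise ValueError(f"CR must be > 0, got {self.cr}")
        if self.heavy_atoms is not None and self.heavy_atoms < 1:
            raise ValueError("heavy_atoms must be >= 1")

    def class_kinact(self, overrides: Optional[dict] = None) -> float:
        table = dict(WARHEAD_KINACT)
        if overrides:
            table.update(overrides)
        if self.k_inact is not None:
            return self.k_inact
        if self.warhead in table:
            return table[self.warhead]
        raise KeyError(
            f"fragment {self.fragment!r}: unknown warhead class {self.warhead!r} "
            "and no per-record k_inact supplied"
        )


def cr_to_occupancy(cr: float) -> float:
    """occupancy = 1 - 1/CR (DMSO/treated orientation); in (-inf, 1)."""
    if cr <= 0:
        raise ValueError(f"CR must be > 0, got {cr}")
    return 1.0 - 1.0 / cr


def occupancy_to_kobs(occ: float, t: float) -> float:
    """k_obs = -ln(1 - occ)/t for occ strictly inside (0, 1)."""
    if not 0.0 < occ < 1.0:
        raise ValueError(f"occupancy must lie in (0, 1), got {occ}")
    if t <= 0:
        raise ValueError("t must be > 0")
    return -math.log1p(-occ) / t


def kobs_to_ki(k_obs: float, I: float, k_inact: float) -> tuple[float, str]:
    """Invert k_obs = k_inact I/(K_I + I) for K_I.

    Returns (K_I, "ok"), or ([I] as an upper bound, "reactivity-limited")
    when k_obs >= k_inact, where no finite positive K_I exists.
    """
    if k_obs <= 0 or I <= 0 or k_inact <= 0:
        raise ValueError("k_obs, I and k_inact must all be > 0")
    if k_obs >= k_inact:
        return I, "reactivity-limited"
    return k_inact * I / k_obs - I, "ok"


def ligand_efficiency(
    K_I: float, n_atoms: int, constants: ConversionConstants = ConversionConstants()
) -> float:
    """LE = -RT ln(K_I [M]) / N (kcal mol^-1 per heavy atom).

    Positive for sub-molar binders; halving K_I at fixed N adds exactly
    RT ln2 / N.
    """
    if K_I <= 0:
        raise ValueError("K_I must be > 0")
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    return -constants.R * constants.T * math.log(K_I) / n_atoms


def lipophilic_efficiency(K_I: float, clogp: float) -> float:
    """LLE = -log10(K_I [M]) - clogP (unitless)."""
    if K_I <= 0:
        raise ValueError("K_I must be > 0")
    return -math.log10(K_I) - clogp


def clogp_from_structure(smiles: str) -> float:
    """Crippen-type cLogP from a SMILES string (optional RDKit extra)."""
    try:
        from rdkit import Chem
        from rdkit.Chem import Crippen
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "computing cLogP from structures requires the 'chem' extra (rdkit)"
        ) from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return float(Crippen.MolLogP(mol))


def convert_record(
    rec: FragmentRecord,
    constants: ConversionConstants = ConversionConstants(),
    cr_cutoff: float = 2.0,
    warhead_kinact: Optional[dict] = None,
) -> dict:
    """Full CR -> occupancy -> k_obs -> K_I (-> LE/LLE) chain for one record."""
    out = {
        "fragment": rec.fragment,
        "analyte": rec.analyte,
        "warhead": rec.warhead,
        "cr": rec.cr,
        "occupancy": None,
        "k_obs": None,
        "k_inact": None,
        "K_I": None,
        "LE": None,
        "LLE": None,
        "status": "ok",
    }
    if rec.cr <= cr_cutoff:
        out["status"] = "below-cutoff"
        return out
    k_inact = rec.class_kinact(warhead_kinact)
    out["k_inact"] = k_inact
    occ = cr_to_occupancy(rec.cr)
    out["occupancy"] = occ
    k_obs = occupancy_to_kobs(occ, constants.t)
    out["k_obs"] = k_obs
    ki, status = kobs_to_ki(k_obs, constants.I, k_inact)
    out["K_I"] = ki
    out["status"] = status
    if rec.heavy_atoms is not None:
        out["LE"] = ligand_efficiency(ki, rec.heavy_atoms, constants)
    clogp = rec.clogp
    if clogp is None and rec.structure is not None:
        clogp = clogp_from_structure(rec.structure)
    if clogp is not None:
        out["LLE"] = lipophilic_efficiency(ki, clogp)
    return out


def convert_table(
    records,
    constants: ConversionConstants = ConversionConstants(),
    cr_cutoff: float = 2.0,
    warhead_kinact: Optional[dict] = None,
) -> pd.DataFrame:
    """Convert a list of FragmentRecord (or a tidy DataFrame) to K_I/LE/LLE.

    Records at or below the CR cutoff (default 2) are kept with status
    ``below-cutoff`` and no kinetic output; reactivity-limited records carry
    [I] as the K_I upper bound.
    """
    if isinstance(records, pd.DataFrame):
        records = [
            FragmentRecord(
                fragment=str(r.fragment),
                analyte=str(r.analyte),
                cr=float(r.cr),
                warhead=str(getattr(r, "warhead", "custom")),
                k_inact=_opt(getattr(r, "k_inact", None)),
                heavy_atoms=(int(r.heavy_atoms)
                             if _opt(getattr(r, "heavy_atoms", None)) is not None
                             else None),
                clogp=_opt(getattr(r, "clogp", None)),
                structure=(str(r.structure)
                           if _opt_str(getattr(r, "structure", None)) else None),
            )
            for r in records.itertuples()
        ]
    rows = []
    for rec in records:
        try:
            rows.append(convert_record(rec, constants=constants, cr_cutoff=cr_cutoff,
                                       warhead_kinact=warhead_kinact))
        except KeyError:
            # unknown warhead without a per-record k_inact: record-level error
            rows.append({"fragment": rec.fragment, "analyte": rec.analyte,
                         "warhead": rec.warhead, "cr": rec.cr, "occupancy": None,
                         "k_obs": None, "k_inact": None, "K_I": None,
                         "LE": None, "LLE": None, "status": "unknown-warhead"})
    return pd.DataFrame(rows)


def _opt(v):
    if v is None:
        return None
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(f) else f


def _opt_str(v) -> bool:
    return v is not None and isinstance(v, str) and v != ""
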