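"""Domain types, delimited-file readers/writers, unit conversions and dose arithmetic.

Canonical internal units are minutes, ng/mL (volumetric) or ng/g (gravimetric),
ng for amounts and mL for volumes; all conversions happen at ingest.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Route",
    "Tissue",
    "ConcUnits",
    "DoseRecord",
    "ConcProfile",
    "BLOOD_DENSITY_G_PER_ML",
    "administered_dose",
    "mass_to_volume_concentration",
    "read_profiles",
    "write_profiles",
    "read_dose_config",
    "write_dose_config",
]

#: Density used to convert gravimetric blood concentrations (ng/g) to
#: volumetric ones (ng/mL).
BLOOD_DENSITY_G_PER_ML = 1.056


class Route(str, enum.Enum):
    """Route of administration."""

    IV_BOLUS = "iv_bolus"
    IP = "ip"


class Tissue(str, enum.Enum):
    """Sampled organ/tissue labels."""

    BLOOD = "blood"
    KIDNEY = "kidney"
    LIVER = "liver"
    HEART = "heart"
    OMENTUM = "omentum"
    BRAIN = "brain"


class ConcUnits(str, enum.Enum):
    """Concentration units: volumetric (per mL of fluid) or gravimetric (per g of tissue)."""

    NG_PER_ML = "ng_per_mL"
    NG_PER_G = "ng_per_g"


def administered_dose(dose_rate_ug_per_kg: float, body_mass_kg: float) -> float:
    """Total administered dose in ng from a dose rate (µg/kg) and body mass (kg).

    Parameters
    ----------
    dose_rate_ug_per_kg
        Dose rate in µg per kg of body mass; must be positive.
    body_mass_kg
        Body mass in kg; must be positive.

    Returns
    -------
    float
        Dose amount in ng (= dose_rate × body_mass × 1000).
    """
    if dose_rate_ug_per_kg <= 0:
        raise ValueError(f"dose_rate must be positive, got {dose_rate_ug_per_kg}")
    if body_mass_kg <= 0:
        raise ValueError(f"body_mass must be positive, got {body_mass_kg}")
    return dose_rate_ug_per_kg * body_mass_kg * 1000.0


def mass_to_volume_concentration(
    c_ng_per_g: float | np.ndarray,
    density_g_per_ml: float = BLOOD_DENSITY_G_PER_ML,
) -> float | np.ndarray:
    """Convert a gravimetric concentration (ng/g) to a volumetric one (ng/mL).

    The default density is the standard whole-blood value of 1.056 g/mL.
    """
    if density_g_per_ml <= 0:
        raise ValueError(f"density must be positive, got {density_g_per_ml}")
    c = np.asarray(c_ng_per_g, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    out = c * density_g_per_ml
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DoseRecord:
    """Dose regimen for one experimental group.

    ``dose_amount_ng`` may be supplied explicitly (e.g. when the design document
    states the total dose); otherwise it is derived as
    ``dose_rate × body_mass × 1000``.
    """

    route: Route
    dose_rate_ug_per_kg: float
    body_mass_kg: float
    group_id: str
    species: str = ""
    chronic_pretreatment: bool = False
    dose_amount_ng: float | None = None

    def __post_init__(self) -> None:
        if self.dose_rate_ug_per_kg <= 0:
            raise ValueError("dose_rate must be positive")
        if self.body_mass_kg <= 0:
            raise ValueError("body_mass must be positive")
        if self.dose_amount_ng is None:
            object.__setattr__(
                self,
                "dose_amount_ng",
                administered_dose(self.dose_rate_ug_per_kg, self.body_mass_kg),
            )
        if self.dose_amount_ng <= 0:
            raise ValueError("dose_amount must be positive")
        if not isinstance(self.route, Route):
            object.__setattr__(self, "route", Route(self.route))


@dataclass(frozen=True)
class ConcProfile:
    """A mean concentration–time series for one (group, tissue).

    Times are minutes, strictly increasing, all non-negative.  Concentrations
    are non-negative, in ng/mL or ng/g as flagged by ``units``.  ``sd`` and
    ``n_animals`` carry the per-point dispersion and group size when known.
    """

    group_id: str
    tissue: Tissue
    times: np.ndarray
    concentrations: np.ndarray
    units: ConcUnits = ConcUnits.NG_PER_ML
    sd: np.ndarray | None = None
    n_animals: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if not isinstance(self.tissue, Tissue):
            object.__setattr__(self, "tissue", Tissue(self.tissue))
        if not isinstance(self.units, ConcUnits):
            object.__setattr__(self, "units", ConcUnits(self.units))
        if t.ndim != 1 or c.ndim != 1 or len(t) != len(c):
            raise ValueError("times and concentrations must be 1-D and equal length")
        if len(t) and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("times must be strictly increasing and non-negative")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if self.sd is not None:
            s = np.asarray(self.sd, dtype=float)
            if len(s) != len(t):
                raise ValueError("sd must match times in length")
            object.__setattr__(self, "sd", s)

    def __len__(self) -> int:
        return len(self.times)

    def to_volumetric(self, density_g_per_ml: float = BLOOD_DENSITY_G_PER_ML) -> "ConcProfile":
        """Return a copy with concentrations converted from ng/g to ng/mL."""
        if self.units is ConcUnits.NG_PER_ML:
            return self
        conc = mass_to_volume_concentration(self.concentrations, density_g_per_ml)
        sd = None if self.sd is None else self.sd * density_g_per_ml
        return replace(self, concentrations=conc, sd=sd, units=ConcUnits.NG_PER_ML)

    def scaled(self, k: float) -> "ConcProfile":
        """Return a copy with all concentrations (and sd) multiplied by ``k``."""
        sd = None if self.sd is None else self.sd * k
        return replace(self, concentrations=self.concentrations * k, sd=sd)


_PROFILE_COLUMNS = ["group_id", "species", "tissue", "time_min", "conc", "conc_units", "sd", "n"]


def read_profiles(path: str | Path) -> list[ConcProfile]:
    """Read concentration–time profiles from a delimited table.

    Expects columns ``group_id, tissue, time_min, conc, conc_units`` (plus
    optional ``species, sd, n``); comma or tab delimited, sniffed from the
    header line.  Returns one :class:`ConcProfile` per (group, tissue), rows
    sorted by time.
    """
    path = Path(path)
    sep = "\t" if "\t" in path.open().readline() else ","
    df = pd.read_csv(path, sep=sep)
    required = {"group_id", "tissue", "time_min", "conc", "conc_units"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    allowed = {t.value for t in Tissue}
    bad = set(df["tissue"].unique()) - allowed
    if bad:
        raise ValueError(
            f"unknown tissue labels {sorted(bad)}; allowed labels: {sorted(allowed)}"
        )
    if (df["conc"] < 0).any():
        row = df[df["conc"] < 0].iloc[0]
        raise ValueError(
            f"negative concentration at (group={row['group_id']}, "
            f"tissue={row['tissue']}, time={row['time_min']})"
        )
    dup = df.duplicated(subset=["group_id", "tissue", "time_min"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate rows for (group={row['group_id']}, tissue={row['tissue']}, "
            f"time={row['time_min']})"
        )

    profiles: list[ConcProfile] = []
    for (group, tissue), sub in df.groupby(["group_id", "tissue"], sort=True):
        sub = sub.sort_values("time_min")
        units = sub["conc_units"].unique()
        if len(units) != 1:
            raise ValueError(
                f"mixed concentration units {sorted(units)} within profile "
                f"(group={group}, tissue={tissue})"
            )
        sd = sub["sd"].to_numpy(float) if "sd" in sub and sub["sd"].notna().all() else None
        n = int(sub["n"].iloc[0]) if "n" in sub and sub["n"].notna().all() else None
        profiles.append(
            ConcProfile(
                group_id=str(group),
                tissue=Tissue(tissue),
                times=sub["time_min"].to_numpy(float),
                concentrations=sub["conc"].to_numpy(float),
                units=ConcUnits(units[0]),
                sd=sd,
                n_animals=n,
            )
        )
    return profiles


def write_profiles(profiles: Iterable[ConcProfile], path: str | Path, species: Mapping[str, str] | None = None) -> None:
    """Write profiles to CSV in the dialect :func:`read_profiles` reads.

    Bit-stable: floats are written with :func:`repr` precision so a
    read/write round-trip preserves numeric content exactly.
    """
    rows = []
    for p in profiles:
        for i, (t, c) in enumerate(zip(p.times, p.concentrations)):
            rows.append(
                {
                    "group_id": p.group_id,
                    "species": (species or {}).get(p.group_id, ""),
                    "tissue": p.tissue.value,
                    "time_min": t,
                    "conc": c,
                    "conc_units": p.units.value,
                    "sd": p.sd[i] if p.sd is not None else "",
                    "n": p.n_animals if p.n_animals is not None else "",
                }
            )
    df = pd.DataFrame(rows, columns=_PROFILE_COLUMNS)
    df.to_csv(path, index=False, float_format=None)


def read_dose_config(path: str | Path) -> dict[str, DoseRecord]:
    """Read per-group dose metadata from a YAML (or JSON) mapping.

    Each entry maps a group id to ``route, dose_rate_ug_per_kg, body_mass_kg``
    with optional ``dose_ng`` override, ``species`` and ``chronic_pretreatment``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    records = {}
    for group_id, entry in raw.items():
        records[group_id] = DoseRecord(
            route=Route(entry["route"]),
            dose_rate_ug_per_kg=float(entry["dose_rate_ug_per_kg"]),
            body_mass_kg=float(entry["body_mass_kg"]),
            dose_amount_ng=float(entry["dose_ng"]) if "dose_ng" in entry else None,
            species=entry.get("species", ""),
            group_id=str(group_id),
            chronic_pretreatment=bool(entry.get("chronic_pretreatment", False)),
        )
    return records


def write_dose_config(records: Mapping[str, DoseRecord], path: str | Path) -> None:
    """Write per-group dose metadata to YAML, inverse of :func:`read_dose_config`."""
    out = {}
    for group_id, r in records.items():
        out[group_id] = {
            "route": r.route.value,
            "dose_rate_ug_per_kg": r.dose_rate_ug_per_kg,
            "body_mass_kg": r.body_mass_kg,
            "dose_ng": r.dose_amount_ng,
            "species": r.species,
            "chronic_pretreatment": r.chronic_pretreatment,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)
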