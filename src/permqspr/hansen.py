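"""Hansen solubility parameter (HSP) arithmetic.

An HSP triplet (deltaD, deltaP, deltaH), all in MPa^0.5, decomposes a
material's cohesive energy density into dispersion, polar and
hydrogen-bonding contributions.  The vehicle-membrane interaction
distance

    Ra = sqrt(4*(dD_a - dD_b)^2 + (dP_a - dP_b)^2 + (dH_a - dH_b)^2)

is a scaled Euclidean metric: the smaller it is, the more alike solvent
and polymer, and the stronger the expected swelling/uptake interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["HSPTriplet", "hsp_distance", "total_parameter", "read_hsp_csv", "distance_table"]

_ROLES = ("vehicle", "membrane", "permeant")


@dataclass(frozen=True)
class HSPTriplet:
    """Partial solubility parameters of one material (MPa^0.5)."""

    dD: float
    dP: float
    dH: float
    label: str = ""
    role: str = "vehicle"

    def __post_init__(self) -> None:
        for name in ("dD", "dP", "dH"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")


def hsp_distance(a: HSPTriplet, b: HSPTriplet) -> float:
    """HSP interaction distance Ra between two materials (MPa^0.5)."""
    return math.sqrt(
        4.0 * (a.dD - b.dD) ** 2 + (a.dP - b.dP) ** 2 + (a.dH - b.dH) ** 2
    )


def total_parameter(t: HSPTriplet) -> float:
    """Total (Hildebrand-like) solubility parameter deltaT = |(dD,dP,dH)|."""
    return math.sqrt(t.dD**2 + t.dP**2 + t.dH**2)


def read_hsp_csv(path) -> dict[str, HSPTriplet]:
    """Read an HSP table (columns: label, role, dD, dP, dH) keyed by label."""
    df = pd.read_csv(path, comment="#")
    required = {"label", "role", "dD", "dP", "dH"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"HSP CSV missing columns: {sorted(missing)}")
    out = {}
    for rec in df.itertuples(index=False):
        out[str(rec.label)] = HSPTriplet(
            dD=float(rec.dD), dP=float(rec.dP), dH=float(rec.dH),
            label=str(rec.label), role=str(rec.role),
        )
    return out


def distance_table(
    triplets: dict[str, HSPTriplet],
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """HSP distances for (vehicle, membrane) label pairs."""
    rows = []
    for a, b in pairs:
        try:
            ta, tb = triplets[a], triplets[b]
        except KeyError as exc:
            raise KeyError(f"unknown HSP label {exc.args[0]!r}") from None
        rows.append({"a": a, "b": b, "hsp_distance": hsp_distance(ta, tb)})
    return pd.DataFrame(rows, columns=["a", "b", "hsp_distance"])
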