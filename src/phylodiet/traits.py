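"""Species trait tables: morphology and diet measurements plus derived transforms.

A trait table holds per-species means of standard length (SL, mm) and
intestinal length (IL, mm), the volumetric percentage of animal prey in the
diet, and a categorical adult intestinal-configuration state.  Derived
transforms follow standard comparative practice: log10 lengths, relative
intestinal length (IL/SL), and an arcsine transform of the diet percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TraitTable",
    "TraitValidationError",
    "read_traits",
    "write_traits",
    "derive",
    "duplicate_tip_traits",
    "arcsine_transform",
]

REQUIRED_COLUMNS = ("species", "sl_mm", "il_mm", "pct_animal")
OPTIONAL_COLUMNS = ("n", "config_state", "trophic_class")


class TraitValidationError(ValueError):
    """Raised when a trait table violates its invariants."""


@dataclass
class TraitTable:
    """Validated per-species trait measurements, indexed by species label."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise TraitValidationError(f"missing required columns: {missing}")
        problems = []
        dupes = df["species"][df["species"].duplicated()].tolist()
        if dupes:
            problems.append(f"duplicate species labels: {sorted(set(dupes))}")
        bad_len = df[(df["sl_mm"] <= 0) | (df["il_mm"] <= 0)]
        if len(bad_len):
            problems.append(
                f"nonpositive lengths in rows: {bad_len['species'].tolist()}"
            )
        bad_pct = df[(df["pct_animal"] < 0) | (df["pct_animal"] > 100)]
        if len(bad_pct):
            problems.append(
                f"pct_animal outside [0, 100] in rows: {bad_pct['species'].tolist()}"
            )
        if problems:
            raise TraitValidationError("; ".join(problems))
        self.data = df.reset_index(drop=True)

    @property
    def species(self) -> list[str]:
        return self.data["species"].tolist()

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> pd.Series:
        return pd.Series(
            self.data[name].to_numpy(), index=self.data["species"], name=name
        )


def read_traits(path: str) -> TraitTable:
    """Read and validate a species trait CSV.

    Required columns: species, sl_mm, il_mm, pct_animal.  Optional columns
    (n, config_state, trophic_class) are carried through when present.
    """
    df = pd.read_csv(path)
    return TraitTable(df)


def write_traits(traits: TraitTable, path: str) -> None:
    traits.data.to_csv(path, index=False)


def arcsine_transform(
    pct: np.ndarray | pd.Series, sqrt: bool = True, degrees: bool = False
) -> np.ndarray | pd.Series:
    """Arcsine transform of a percentage in [0, 100].

    With ``sqrt=True`` (default) this is the standard variance stabiliser
    arcsin(sqrt(p/100)); ``sqrt=False`` applies arcsin(p/100) directly, a
    convention some published analyses use.  Radians unless ``degrees``.
    """
    prop = pct / 100.0
    val = np.arcsin(np.sqrt(prop)) if sqrt else np.arcsin(prop)
    return np.degrees(val) if degrees else val


def derive(
    traits: TraitTable,
    arcsine_sqrt: bool = True,
    arcsine_degrees: bool = False,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Derived transforms, one row per species (indexed by species label).

    Columns: log_sl, log_il (log10 by default), asin_diet (radians), ril
    (relative intestinal length IL/SL).
    """
    df = traits.data
    if log_base == 10.0:
        log = np.log10
    else:
        log = lambda v: np.log(v) / math.log(log_base)  # noqa: E731
    out = pd.DataFrame(
        {
            "log_sl": log(df["sl_mm"].to_numpy(dtype=float)),
            "log_il": log(df["il_mm"].to_numpy(dtype=float)),
            "asin_diet": arcsine_transform(
                df["pct_animal"].to_numpy(dtype=float),
                sqrt=arcsine_sqrt,
                degrees=arcsine_degrees,
            ),
            "ril": df["il_mm"].to_numpy(dtype=float)
            / df["sl_mm"].to_numpy(dtype=float),
        },
        index=pd.Index(df["species"], name="species"),
    )
    return out


def duplicate_tip_traits(traits: TraitTable, tip_map: dict[str, str]) -> TraitTable:
    """Expand a species table onto tree tips via ``tip_map`` (tip -> species).

    Several tips may map to one species (e.g. two sequences of the same
    species placed separately in the tree); each tip receives that species'
    row.  The result is a TraitTable whose "species" column holds tip labels.
    """
    df = traits.data.set_index("species")
    missing = [t for t, sp in tip_map.items() if sp not in df.index]
    if missing:
        raise TraitValidationError(
            f"tips map to species absent from the trait table: {sorted(missing)}"
        )
    rows = df.loc[[tip_map[t] for t in tip_map]].reset_index(drop=True)
    rows.insert(0, "species", list(tip_map))
    return TraitTable(rows)
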