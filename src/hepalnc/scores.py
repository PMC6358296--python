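"""NAFLD activity score (NAS) used to adjudicate steatohepatitis on histology.

The NAS is the unweighted sum of three pathologist-assigned components:
steatosis (0-3), lobular inflammation (0-3), and hepatocyte ballooning (0-2),
giving a total of 0-8.  A total of >= 5 is read as steatohepatitis.  Scores
are taken as given integers; no image analysis happens here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

STEATOHEPATITIS_CUTOFF = 5

_RANGES = {"steatosis": (0, 3), "lobular_inflammation": (0, 3), "ballooning": (0, 2)}


@dataclass(frozen=True)
class NASComponents:
    steatosis: int
    lobular_inflammation: int
    ballooning: int

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            value = getattr(self, name)
            if not isinstance(value, int) or not lo <= value <= hi:
                raise ValidationError(f"{name} must be an integer in [{lo}, {hi}], got {value!r}")


def nafld_activity_score(c: NASComponents) -> tuple[int, bool]:
    """Total NAS (0-8) and whether it meets the steatohepatitis cutoff (>= 5)."""
    total = c.steatosis + c.lobular_inflammation + c.ballooning
    return total, total >= STEATOHEPATITIS_CUTOFF


def score_table(df: pd.DataFrame) -> pd.DataFrame:
    """Batch scoring: add ``nas_total`` and ``steatohepatitis`` columns.

    Expects integer columns ``steatosis``, ``lobular_inflammation`` and
    ``ballooning``; any identifier columns are passed through.
    """
    out = df.copy()
    totals, flags = [], []
    for _, row in df.iterrows():
        total, flag = nafld_activity_score(
            NASComponents(
                steatosis=int(row["steatosis"]),
                lobular_inflammation=int(row["lobular_inflammation"]),
                ballooning=int(row["ballooning"]),
            )
        )
        totals.append(total)
        flags.append(flag)
    out["nas_total"] = totals
    out["steatohepatitis"] = flags
    return out
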