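"""Presentation-layer rendering: half-up percentage rounding and tidy CSVs.

All estimation keeps full precision; rounding happens only here, half-up at a
configurable number of decimals (default 1), matching the convention of the
printed drainage/prevalence tables.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .cohort import NODE_FIELDS
from .inference import IntervalEstimate

__all__ = ["round_half_up", "pct", "drainage_frame", "prevalence_frame", "format_interval"]


def round_half_up(value: float, dp: int = 1) -> float:
    """Decimal round-half-up (2.25 -> 2.3 at 1 dp, unlike banker's rounding)."""
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def pct(probability: float, dp: int = 1) -> float:
    """Probability -> percentage rounded half-up at ``dp`` decimals."""
    return round_half_up(100.0 * probability, dp)


def format_interval(est: IntervalEstimate, dp: int = 1) -> str:
    return f"{pct(est.mean, dp):.{dp}f} ({pct(est.lower, dp):.{dp}f}, {pct(est.upper, dp):.{dp}f})"


def drainage_frame(estimates: dict, dp: int = 1) -> pd.DataFrame:
    """Tidy frame from a drainage_table mapping ((field, region, method) -> est)."""
    rows = []
    for (name, region, method), est in estimates.items():
        rows.append(
            {
                "node_field": name,
                "region": "all" if region is None else region,
                "method": method,
                "n": est.n_success,
                "N": est.n_total,
                "mean_pct": pct(est.mean, dp),
                "lower_pct": pct(est.lower, dp),
                "upper_pct": pct(est.upper, dp),
                "degenerate": est.degenerate,
            }
        )
    df = pd.DataFrame(rows)
    order = {f: i for i, f in enumerate(NODE_FIELDS)}
    return df.sort_values(
        ["region", "node_field", "method"],
        key=lambda s: s.map(order).fillna(s) if s.name == "node_field" else s,
        kind="stable",
    ).reset_index(drop=True)


def prevalence_frame(estimates: dict, dp: int = 1) -> pd.DataFrame:
    """Tidy frame from a prevalence_table mapping ((region, method) -> est)."""
    rows = []
    for (region, method), est in estimates.items():
        rows.append(
            {
                "region": region,
                "method": method,
                "n": est.n_success,
                "N": est.n_total,
                "mean_pct": pct(est.mean, dp),
                "lower_pct": pct(est.lower, dp),
                "upper_pct": pct(est.upper, dp),
            }
        )
    return pd.DataFrame(rows).sort_values(["region", "method"], kind="stable").reset_index(drop=True)
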