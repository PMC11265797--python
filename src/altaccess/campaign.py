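"""Sampling-campaign bookkeeping.

A campaign is a set of blocks, each describing how many conditions,
replicates and windows were run and for how long per window.  The total
production time is the fully factorised sum; printed totals in reports are
typically rounded to the nearest microsecond (or to one decimal for
sub-10-us trial budgets), so both roundings are offered explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import yaml

from .errors import ValidationError

__all__ = [
    "CampaignBlock",
    "CampaignPlan",
    "campaign_total_time",
    "plan_from_yaml",
    "plan_to_yaml",
]

Rounding = Literal["none", "nearest_us", "one_decimal_us"]


@dataclass(frozen=True)
class CampaignBlock:
    label: str
    n_conditions: int
    n_replicates: int
    n_windows: int
    per_window_durations: tuple[float, ...]  # ns

    def __post_init__(self) -> None:
        for name in ("n_conditions", "n_replicates", "n_windows"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be >= 1 in block {self.label!r}")
        durations = tuple(float(d) for d in self.per_window_durations)
        if not durations:
            raise ValidationError(f"block {self.label!r} has an empty duration list")
        if any(d <= 0 for d in durations):
            raise ValidationError(f"block {self.label!r} has non-positive durations")
        object.__setattr__(self, "per_window_durations", durations)

    @property
    def total_ns(self) -> float:
        return (
            self.n_conditions
            * self.n_replicates
            * self.n_windows
            * sum(self.per_window_durations)
        )


@dataclass(frozen=True)
class CampaignPlan:
    name: str
    blocks: tuple[CampaignBlock, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if not self.blocks:
            raise ValidationError("campaign plan has no blocks")

    def block_totals_us(self) -> dict[str, float]:
        return {b.label: b.total_ns / 1000.0 for b in self.blocks}


def campaign_total_time(plan: CampaignPlan, rounding: Rounding = "none") -> float:
    """Total production sampling of a plan in microseconds.

    ``rounding`` controls how the result is presented: ``nearest_us`` for
    integer-microsecond claims, ``one_decimal_us`` for trial budgets quoted
    to one decimal.
    """
    total_us = sum(b.total_ns for b in plan.blocks) / 1000.0
    if rounding == "none":
        return total_us
    if rounding == "nearest_us":
        return float(round(total_us))
    if rounding == "one_decimal_us":
        return round(total_us, 1)
    raise ValidationError(f"unknown rounding mode {rounding!r}")


def plan_from_yaml(path: str | Path) -> CampaignPlan:
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    return plan_from_dict(raw)


def plan_from_dict(raw: dict) -> CampaignPlan:
    try:
        blocks = tuple(
            CampaignBlock(
                label=str(b["label"]),
                n_conditions=int(b.get("n_conditions", 1)),
                n_replicates=int(b.get("n_replicates", 1)),
                n_windows=int(b.get("n_windows", 1)),
                per_window_durations=tuple(float(d) for d in b["per_window_durations"]),
            )
            for b in raw["blocks"]
        )
        return CampaignPlan(name=str(raw.get("name", "campaign")), blocks=blocks)
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed campaign plan: {exc}") from exc


def plan_to_yaml(plan: CampaignPlan, path: str | Path) -> Path:
    raw = {
        "name": plan.name,
        "blocks": [
            {
                "label": b.label,
                "n_conditions": b.n_conditions,
                "n_replicates": b.n_replicates,
                "n_windows": b.n_windows,
                "per_window_durations": list(b.per_window_durations),
            }
            for b in plan.blocks
        ],
    }
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
    return path
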