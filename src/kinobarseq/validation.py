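"""Agreement between pooled Bar-seq calls and individual spotting assays.

Selected (kinase, yeast gene) pairs from the suppressor, non-modifier and
enhancer groups are retested one strain at a time by serial-dilution
spotting; a record notes whether the spot assay confirmed the pooled call.
Consistency is summarised per kinase within each group as
100 × confirmed / tested, and per group as the *unweighted* mean of the
per-kinase percentages over the kinases actually tested in that group —
not the pooled fraction, so kinases with many tested strains do not
dominate the group figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

GROUPS = ("suppressor", "non_modifier", "enhancer")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding, as used for reported percentages."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SpotAssayRecord:
    """One individually retested (kinase, yeast gene) pair."""

    kinase: str
    yeast_gene: str
    group: str
    confirmed: bool

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


class ConsistencyReport:
    """Per-kinase and per-group spot-assay agreement.

    ``per_kinase`` has one row per (kinase, group) with confirmed, tested
    and the exact percent; ``group_average(group)`` is the unweighted mean
    of that group's per-kinase percents.  Kinases not tested in a group
    simply have no row and are excluded from the mean.  Rounding (half-up,
    one decimal) is applied only at reporting time.
    """

    def __init__(self, per_kinase: pd.DataFrame):
        if per_kinase.empty:
            raise ValueError("no spot-assay records")
        bad = per_kinase[per_kinase["tested"] <= 0]
        if not bad.empty:
            raise ValueError("every (kinase, group) cell needs tested > 0")
        per_kinase = per_kinase.copy()
        per_kinase["percent"] = 100.0 * per_kinase["confirmed"] / per_kinase["tested"]
        self.per_kinase = per_kinase[["kinase", "group", "confirmed", "tested", "percent"]]

    @classmethod
    def from_records(
        cls, records: Iterable[SpotAssayRecord] | pd.DataFrame
    ) -> "ConsistencyReport":
        """Build from per-strain records (confirmed as bool or 0/1)."""
        if isinstance(records, pd.DataFrame):
            df = records.copy()
        else:
            df = pd.DataFrame([r.__dict__ for r in records])
        if df.empty:
            raise ValueError("no spot-assay records")
        df["confirmed"] = df["confirmed"].astype(int)
        agg = (
            df.groupby(["kinase", "group"], sort=False)
            .agg(confirmed=("confirmed", "sum"), tested=("confirmed", "size"))
            .reset_index()
        )
        return cls(agg)

    @classmethod
    def from_counts(
        cls, counts: Mapping[tuple[str, str], tuple[int, int]]
    ) -> "ConsistencyReport":
        """Build from (kinase, group) → (confirmed, tested) fractions."""
        rows = [
            {"kinase": k, "group": g, "confirmed": c, "tested": t}
            for (k, g), (c, t) in counts.items()
        ]
        return cls(pd.DataFrame(rows))

    def percent(self, kinase: str, group: str) -> float:
        """Reported per-kinase agreement (one decimal, half-up)."""
        sel = self.per_kinase[
            (self.per_kinase["kinase"] == kinase) & (self.per_kinase["group"] == group)
        ]
        if sel.empty:
            raise KeyError(f"kinase {kinase!r} was not tested in group {group!r}")
        return round_half_up(float(sel["percent"].iloc[0]))

    def group_average(self, group: str) -> float:
        """Reported group agreement: unweighted mean over tested kinases."""
        sel = self.per_kinase[self.per_kinase["group"] == group]
        if sel.empty:
            raise KeyError(f"no kinase was tested in group {group!r}")
        return round_half_up(float(sel["percent"].mean()))

    def summary(self) -> pd.DataFrame:
        """Report table: per-kinase rows with the group average attached."""
        out = self.per_kinase.copy()
        out["percent"] = out["percent"].map(round_half_up)
        out["group_average"] = out["group"].map(self.group_average)
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


def consistency(records: Iterable[SpotAssayRecord] | pd.DataFrame) -> ConsistencyReport:
    """Spot-assay agreement report from individual retest records."""
    return ConsistencyReport.from_records(records)


def load_spot_records(path: str | Path) -> pd.DataFrame:
    """Read a spot-assay TSV with columns kinase, yeast_gene, group, confirmed."""
    df = pd.read_csv(path, sep="\t")
    required = ["kinase", "yeast_gene", "group", "confirmed"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"spot-assay table {path} is missing columns: {missing}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown groups {sorted(bad)}; expected one of {GROUPS}")
    return df
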